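"""Ground-truth linear motions: weighted PCA of superposed collections.

The principal components of the positional covariance of a superposed
conformational collection are interpreted as the main linear motions
explaining its conformational diversity.  Each component is an ``L x 3``
field of per-residue displacement vectors, normalised so that the squared
displacement norms sum to L, which makes errors comparable across proteins
of different sizes.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "MotionSet",
    "extract_principal_components",
    "normalize_component",
    "variance_contribution",
    "collectivity",
]


class DegenerateMotionError(ValueError):
    pass


class InsufficientDataError(ValueError):
    pass


@dataclass
class MotionSet:
    """A set of K per-residue displacement fields (``vectors``: L x K x 3).

    Ground-truth sets carry the PCA eigenvalues (sorted descending);
    predicted sets do not.  ``is_normalised`` records whether each component
    satisfies sum_i ||x_ik||^2 = L.
    """

    vectors: np.ndarray
    eigenvalues: Optional[np.ndarray] = None
    is_normalised: bool = False
    source: str = "ground_truth"
    protein_id: str = ""

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim == 2:
            self.vectors = self.vectors[:, None, :]
        if self.vectors.ndim != 3 or self.vectors.shape[2] != 3:
            raise ValueError(f"vectors must be L x K x 3, got {self.vectors.shape}")
        if self.eigenvalues is not None:
            self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)

    @property
    def n_residues(self) -> int:
        return self.vectors.shape[0]

    @property
    def n_components(self) -> int:
        return self.vectors.shape[1]

    def component(self, k: int) -> np.ndarray:
        return self.vectors[:, k, :]

    # -- plain-text serialisation ------------------------------------------
    def to_table(self, path) -> None:
        """One row per residue: 1-based index then K (x, y, z) triplets."""
        L, K, _ = self.vectors.shape
        header = {
            "K": K, "L": L, "normalised": self.is_normalised,
            "source": self.source, "protein_id": self.protein_id,
            "eigenvalues": (None if self.eigenvalues is None
                            else [float(v) for v in self.eigenvalues]),
        }
        with open(path, "w") as fh:
            fh.write("# " + json.dumps(header) + "\n")
            cols = ["residue"] + [f"{a}{k + 1}" for k in range(K) for a in "xyz"]
            fh.write("\t".join(cols) + "\n")
            flat = self.vectors.reshape(L, 3 * K if K else 0)
            for i in range(L):
                row = [str(i + 1)] + [f"{v:.10g}" for v in self.vectors[i].ravel()]
                fh.write("\t".join(row) + "\n")

    @classmethod
    def from_table(cls, path) -> "MotionSet":
        with open(path) as fh:
            header = json.loads(fh.readline().lstrip("# "))
            fh.readline()  # column names
            data = np.loadtxt(fh)
        data = np.atleast_2d(data)
        K, L = header["K"], header["L"]
        vectors = data[:, 1:].reshape(L, K, 3)
        eig = header.get("eigenvalues")
        return cls(vectors=vectors,
                   eigenvalues=None if eig is None else np.asarray(eig),
                   is_normalised=header.get("normalised", False),
                   source=header.get("source", "ground_truth"),
                   protein_id=header.get("protein_id", ""))


def normalize_component(vectors: np.ndarray) -> np.ndarray:
    """Scale an L x 3 displacement field so that sum_i ||x_i||^2 = L."""
    vectors = np.asarray(vectors, dtype=float)
    L = vectors.shape[0]
    total = float(np.sum(vectors ** 2))
    if total <= 0.0:
        raise DegenerateMotionError("cannot normalise an all-zero motion")
    return vectors * np.sqrt(L / total)


def variance_contribution(eigenvalues: np.ndarray, k: int) -> float:
    """Fraction of total positional variance carried by component k
    (its normalised eigenvalue lambda_k / sum_l lambda_l)."""
    eig = np.asarray(eigenvalues, dtype=float)
    if np.any(eig < 0):
        raise ValueError("eigenvalues must be non-negative")
    total = eig.sum()
    if total <= 0:
        raise DegenerateMotionError("all-zero eigenvalue spectrum")
    return float(eig[k] / total)


def collectivity(vectors: np.ndarray, per_coordinate: bool = False) -> float:
    """Exponential-entropy collectivity kappa of an L x 3 motion.

    The squared per-atom displacement norms are renormalised to sum to one
    and kappa = (1/L) exp(entropy) is computed on that distribution, so that
    kappa = 1 when all atomic displacements are identical and kappa = 1/L
    when a single atom moves.  ``per_coordinate=True`` switches to the
    literal per-coordinate sum (entropy over the 3L squared entries), whose
    upper bound for isotropic motions is 3 rather than 1.
    """
    vectors = np.asarray(vectors, dtype=float)
    L = vectors.shape[0]
    if per_coordinate:
        p = vectors.ravel() ** 2
    else:
        p = np.sum(vectors ** 2, axis=1)
    total = p.sum()
    if total <= 0:
        raise DegenerateMotionError("all-zero motion has no collectivity")
    p = p / total
    nz = p[p > 0]
    entropy = -float(np.sum(nz * np.log(nz)))
    return float(np.exp(entropy) / L)


def extract_principal_components(collection, K: int = 3) -> MotionSet:
    """Extract the K top principal components of a superposed collection.

    Residue coordinates are multiplied by the square root of their
    confidence weight before the decomposition (uncertain residues count
    less), each conformation's unresolved residues are imputed at the
    residue's resolved mean (zero deviation), and the returned displacement
    fields are un-weighted and normalised to sum ||x_i||^2 = L.  Eigenvalues
    are the sample variances along each component, sorted descending.
    """
    coords = np.asarray(collection.coords, dtype=float)
    mask = np.asarray(collection.mask, dtype=bool)
    w = np.asarray(collection.weights, dtype=float)
    M, L, _ = coords.shape
    if M < 2:
        raise InsufficientDataError("need at least 2 conformations for PCA")

    # impute unresolved residues at their resolved mean position
    counts = mask.sum(axis=0)
    safe = np.where(counts > 0, counts, 1)
    mean_pos = (coords * mask[:, :, None]).sum(axis=0) / safe[:, None]
    filled = np.where(mask[:, :, None], coords, mean_pos[None, :, :])

    center = filled.mean(axis=0)
    dev = (filled - center[None, :, :]) * np.sqrt(w)[None, :, None]
    flat = dev.reshape(M, 3 * L)
    u, s, vt = np.linalg.svd(flat, full_matrices=False)
    eig = s ** 2 / max(M - 1, 1)

    K_eff = int(min(K, M - 1, 3 * L))
    vectors = np.empty((L, K_eff, 3))
    sw = np.sqrt(w)
    for k in range(K_eff):
        comp = vt[k].reshape(L, 3) / sw[:, None]
        # fix the arbitrary eigenvector sign: largest-magnitude entry positive
        idx = np.unravel_index(np.argmax(np.abs(comp)), comp.shape)
        if comp[idx] < 0:
            comp = -comp
        vectors[:, k, :] = normalize_component(comp)
    return MotionSet(vectors=vectors, eigenvalues=eig[:K_eff],
                     is_normalised=True, source="ground_truth",
                     protein_id=getattr(collection, "id", ""))
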