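"""Synthetic conformational collections with planted linear motions.

The generator emulates the statistical structure assumed of experimental
collections — conformations scattered around a base Cα trace along a few
orthogonal displacement fields, plus isotropic coordinate noise, observed
in random rigid frames and with optional unresolved residues.  It exists so
that extraction, alignment, training and orientation can all be exercised
end to end with no downloads, and so that the expected spectra and
components are known exactly.

To keep the planted parameters identifiable at small M, the per-component
amplitude series are decorrelated (centred, orthogonalised and rescaled to
their exact target sample variance) before being applied: the planted
components then coincide with the population *and* realised principal axes,
so recovery error measures the method, not coefficient sampling noise.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .collections import ConformationalCollection
from .model import EmbeddingMatrix
from .motions import MotionSet, normalize_component

__all__ = ["FixtureSpec", "make_synthetic_collection", "make_surrogate_embedding",
           "make_dataset"]

# fixed mixing used for informative surrogate embeddings; shared across
# proteins so a single linear map can decode every sample
_MIXING_ROOT = 719245301


@dataclass
class FixtureSpec:
    """Parameters of one synthetic collection.

    ``amplitudes`` are per-component displacement standard deviations in Å
    (strictly decreasing; a >= 1.5x separation avoids eigenvector mixing);
    ``noise_sd`` is the isotropic per-coordinate noise in Å; ``d`` the
    surrogate embedding width; ``informative`` controls whether embeddings
    carry the planted displacements (learnable) or are pure noise (the
    random-input negative control).
    """

    L: int = 60
    M: int = 10
    amplitudes: tuple = (2.0, 1.0)
    noise_sd: float = 0.1
    missing_rate: float = 0.0
    d: int = 32
    informative: bool = True
    seed: int = 0

    def __post_init__(self):
        amps = tuple(self.amplitudes)
        if any(a2 >= a1 for a1, a2 in zip(amps, amps[1:])):
            raise ValueError("amplitudes must be strictly decreasing")
        if not 0 <= self.missing_rate < 0.5:
            raise ValueError("missing_rate must be in [0, 0.5)")
        self.amplitudes = amps

    @property
    def K_true(self) -> int:
        return len(self.amplitudes)


def _substream(seed: int, label: str) -> np.random.Generator:
    """Independent named random substream derived from one seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed,
                               spawn_key=(zlib.crc32(label.encode()),)))


def _base_trace(L: int, rng: np.random.Generator) -> np.ndarray:
    """Smooth self-avoiding Cα trace with ~3.8 Å spacing (noisy helix)."""
    radius = rng.uniform(4.0, 8.0)
    rise = rng.uniform(1.2, 2.2)
    step = 3.8
    # angular step so that consecutive points are `step` apart
    chord = np.sqrt(max(step ** 2 - rise ** 2, 0.25))
    dtheta = 2.0 * np.arcsin(min(chord / (2.0 * radius), 0.999))
    t = np.arange(L) * dtheta
    base = np.stack([radius * np.cos(t), radius * np.sin(t),
                     np.arange(L) * rise], axis=1)
    # gentle smooth perturbation that keeps spacing within tolerance
    phase = rng.uniform(0, 2 * np.pi, size=3)
    wobble = 0.15 * np.sin(np.arange(L)[:, None] / 7.0 + phase[None, :])
    return base + wobble


def _rigid_modes(base: np.ndarray) -> np.ndarray:
    """Orthonormal basis (6, 3L) of rigid-body displacement fields of a
    centred structure: 3 translations and 3 infinitesimal rotations."""
    L = base.shape[0]
    centred = base - base.mean(axis=0)
    modes = []
    for j in range(3):
        t = np.zeros((L, 3))
        t[:, j] = 1.0
        modes.append(t.ravel())
        axis = np.zeros(3)
        axis[j] = 1.0
        modes.append(np.cross(axis[None, :], centred).ravel())
    q, _ = np.linalg.qr(np.stack(modes, axis=1))
    return q.T


def _planted_components(L: int, K: int, base: np.ndarray,
                        rng: np.random.Generator) -> np.ndarray:
    """K mutually orthogonal normalised displacement fields, (L, K, 3).

    Two design constraints make the fields behave like real extracted
    motions.  First, white noise along the chain is smoothed with a
    Gaussian kernel (width ~ L/12 residues) so the planted motions are
    collective, domain-like deformations rather than per-residue jitter —
    protein principal components are long-wavelength, and several
    consumers (collectivity-based filters, angular-velocity orientation)
    are only well-conditioned for such fields.  Second, the fields are
    projected out of the rigid-body subspace of the base trace (Eckart
    conditions: zero net translation and zero angular momentum), so
    least-squares superposition leaves the planted deformations intact and
    they are exact fixed points of motion extraction.
    """
    sigma = max(L / 12.0, 2.0)
    half = int(3 * sigma)
    kernel = np.exp(-0.5 * (np.arange(-half, half + 1) / sigma) ** 2)
    kernel /= kernel.sum()
    raw = rng.standard_normal((L + 2 * half, K * 3))
    smooth = np.empty((L, K * 3))
    for c in range(K * 3):
        smooth[:, c] = np.convolve(raw[:, c], kernel, mode="valid")
    flat = smooth.reshape(L, K, 3).transpose(1, 0, 2).reshape(K, 3 * L).T
    rigid = _rigid_modes(base)
    flat -= rigid.T @ (rigid @ flat)
    q, _ = np.linalg.qr(flat)

    # A deformed reference has rigid-rotation modes that differ from the
    # base's by curl fields e_j x V_k of the planted components; remove
    # those too (fixed-point iteration) so the planted set is insensitive,
    # to first order, to which conformation serves as reference.
    for _ in range(30):
        curls = []
        for k in range(q.shape[1]):
            v = q[:, k].reshape(L, 3)
            for j in range(3):
                e = np.zeros(3)
                e[j] = 1.0
                curls.append(np.cross(np.tile(e, (L, 1)), v).ravel())
        span, _ = np.linalg.qr(np.concatenate([rigid, np.stack(curls)]).T)
        new_q = q - span @ (span.T @ q)
        new_q, _ = np.linalg.qr(new_q)
        if np.linalg.norm(new_q - q) < 1e-12:
            q = new_q
            break
        q = new_q

    comps = np.empty((L, K, 3))
    for k in range(K):
        comps[:, k, :] = normalize_component(q[:, k].reshape(L, 3))
    return comps


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    a = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(a)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def make_synthetic_collection(spec: FixtureSpec, collection_id=None
                              ) -> tuple[ConformationalCollection, MotionSet]:
    """Generate a collection with planted linear motions.

    Conformation m = base + sum_k a_km V_k + noise, observed after a random
    rigid transform (so superposition is genuinely exercised).  Amplitude
    series a_k are decorrelated and rescaled so the sample variance along
    V_k equals amplitudes[k]^2 * L exactly (see module docstring).  Returns
    the un-superposed collection together with the planted, normalised
    MotionSet (eigenvalues = amplitudes^2 * L, descending).
    """
    L, M, K = spec.L, spec.M, spec.K_true
    rng_structure = _substream(spec.seed, "structure")
    rng_motion = _substream(spec.seed, "motion")
    rng_noise = _substream(spec.seed, "noise")
    rng_mask = _substream(spec.seed, "mask")

    base = _base_trace(L, rng_structure)
    comps = _planted_components(L, K, base, rng_motion)

    # decorrelated amplitude draws with exact sample variance
    a = rng_motion.standard_normal((M, K))
    a -= a.mean(axis=0, keepdims=True)
    q, r = np.linalg.qr(a)
    q *= np.sign(np.diag(r))
    a = q * (np.asarray(spec.amplitudes) * np.sqrt(max(M - 1, 1)))[None, :]

    coords = base[None, :, :] + np.einsum("mk,lka->mla", a, comps)
    coords += spec.noise_sd * rng_noise.standard_normal(coords.shape)

    for m in range(M):
        rot = _random_rotation(rng_structure)
        shift = rng_structure.uniform(-10, 10, size=3)
        coords[m] = coords[m] @ rot.T + shift

    mask = np.ones((M, L), dtype=bool)
    if spec.missing_rate > 0:
        mask = rng_mask.random((M, L)) >= spec.missing_rate
        mask[:, rng_mask.integers(L)] = True   # anchor one always-resolved residue
        for m in range(M):                      # each conformation needs >= 3
            if mask[m].sum() < 3:
                mask[m, rng_mask.choice(L, size=3, replace=False)] = True
    coords = coords * mask[:, :, None]

    if collection_id is None:
        collection_id = f"synthetic_{spec.seed}"
    aa_pool = "ACDEFGHIKLMNPQRSTVWY"
    sequence = "".join(rng_structure.choice(list(aa_pool), size=L))
    collection = ConformationalCollection(
        id=collection_id, sequence=sequence, coords=coords, mask=mask,
        weights=mask.mean(axis=0),
        reference_index=int(np.argmax(mask.sum(axis=1))),
        member_ids=[f"{collection_id}_m{m}" for m in range(M)],
    )
    planted = MotionSet(
        vectors=comps,
        eigenvalues=np.asarray(spec.amplitudes, dtype=float) ** 2 * L,
        is_normalised=True, source="ground_truth", protein_id=collection_id,
    )
    return collection, planted


def make_surrogate_embedding(spec: FixtureSpec, planted: MotionSet
                             ) -> EmbeddingMatrix:
    """Surrogate per-residue embedding, L x d.

    ``informative=False``: i.i.d. standard normal entries — the
    random-input negative control.  ``informative=True``: the first
    3 * K_true columns carry the planted per-residue displacements passed
    through a fixed random linear mixing (shared across proteins) plus a
    small noise floor; remaining columns are noise.  A linear decoder can
    therefore recover the motions, which is what the learning smoke tests
    rely on.
    """
    rng = _substream(spec.seed, "embedding")
    L, d = spec.L, spec.d
    values = rng.standard_normal((L, d))
    if spec.informative:
        K = planted.n_components
        sig_dim = 3 * K
        if sig_dim > d:
            raise ValueError("embedding width too small for informative signal")
        mix_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=_MIXING_ROOT, spawn_key=(sig_dim,)))
        mixing = mix_rng.standard_normal((sig_dim, sig_dim)) / np.sqrt(sig_dim)
        signal = planted.vectors.reshape(L, sig_dim) @ mixing
        values[:, :sig_dim] = signal + 0.05 * rng.standard_normal((L, sig_dim))
    return EmbeddingMatrix(protein_id=planted.protein_id or f"synthetic_{spec.seed}",
                           values=values)


def make_dataset(n_proteins: int,
                 l_range=(30, 200), m_range=(5, 50),
                 amplitudes=(2.0, 1.0), noise_range=(0.05, 0.3),
                 missing_rate: float = 0.0, d: int = 32,
                 informative: bool = True, K: int | None = None,
                 split=(0.7, 0.15, 0.15), augment_refs: int = 1,
                 seed: int = 0) -> dict:
    """Full train/val/test bundles of synthetic proteins.

    Per-protein specs are sampled from the given ranges; the split is
    random and disjoint by protein; with ``augment_refs`` > 1 each training
    collection contributes up to that many samples, one per alternative
    reference conformation, all sharing the same embedding (the
    one-sequence-to-many-motions augmentation).  Each sample is a dict with
    keys ``embedding``, ``motions``, ``weights``, ``protein_id``.
    """
    from .collections import select_references, superpose
    from .motions import extract_principal_components

    if abs(sum(split) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    rng = _substream(seed, "dataset")
    n_val = int(round(split[1] * n_proteins))
    n_test = int(round(split[2] * n_proteins))
    order = rng.permutation(n_proteins)
    groups = {
        "train": set(order[: n_proteins - n_val - n_test]),
        "val": set(order[n_proteins - n_val - n_test: n_proteins - n_test]),
        "test": set(order[n_proteins - n_test:]),
    }

    n_comp = len(amplitudes) if K is None else K
    out = {"train": [], "val": [], "test": [], "collections": []}
    for p in range(n_proteins):
        spec = FixtureSpec(
            L=int(rng.integers(l_range[0], l_range[1] + 1)),
            M=int(rng.integers(m_range[0], m_range[1] + 1)),
            amplitudes=tuple(amplitudes),
            noise_sd=float(rng.uniform(*noise_range)),
            missing_rate=missing_rate, d=d, informative=informative,
            seed=int(rng.integers(2 ** 31)),
        )
        collection, planted = make_synthetic_collection(spec, f"prot{p:04d}")
        embedding = make_surrogate_embedding(spec, planted)
        out["collections"].append(collection)
        group = next(g for g, members in groups.items() if p in members)
        n_refs = augment_refs if group == "train" else 1
        refs = select_references(collection, n_refs)
        for ref in refs:
            sup = superpose(collection, ref)
            motions = extract_principal_components(sup, K=n_comp)
            out[group].append({
                "embedding": embedding,
                "motions": motions,
                "weights": collection.weights,
                "protein_id": collection.id,
            })
    return out
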