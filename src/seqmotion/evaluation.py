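"""Scoring predicted motions against ground truth.

Per-protein scores: the K x K matrix of pairwise NSSE under per-pair
optimal rotation and scaling, its best-matching pair, the RMSIP overlap of
the two K-dimensional motion subspaces (predictions orthogonalised by
Gram-Schmidt first), and the matched-subspace procedure that globally
aligns the two ordered subspaces for interpretable pairwise similarities.
Cohort scores: success rates (fraction of proteins whose best NSSE beats a
cutoff, 0.6 by default) with bootstrap uncertainty, and the random-
prediction NSSE baseline.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .alignment import DegenerateMotionError, optimal_rotation, pair_nsse

__all__ = [
    "EvaluationReport",
    "SuccessSummary",
    "best_match_nsse",
    "success_rate",
    "rmsip",
    "matched_subspace_report",
    "random_baseline",
]


@dataclass
class EvaluationReport:
    """Per-protein comparison of predicted and ground-truth motion sets.

    ``nsse_matrix[k, l]`` scores predicted component k against ground-truth
    component l; degenerate ground-truth components give NaN rows excluded
    from the minimum.
    """

    protein_id: str
    nsse_matrix: np.ndarray
    best_pair: tuple
    best_nsse: float
    rmsip: float = float("nan")
    matched_pair_products: Optional[np.ndarray] = None
    matched_pair_nsse: Optional[np.ndarray] = None
    matched_correlations: Optional[np.ndarray] = None
    collectivities: Optional[np.ndarray] = None

    def to_dict(self) -> dict:
        def arr(a):
            return None if a is None else np.asarray(a).tolist()
        return {
            "protein_id": self.protein_id,
            "nsse_matrix": arr(self.nsse_matrix),
            "best_pair": list(self.best_pair),
            "best_nsse": float(self.best_nsse),
            "rmsip": float(self.rmsip),
            "matched_pair_products": arr(self.matched_pair_products),
            "matched_pair_nsse": arr(self.matched_pair_nsse),
            "matched_correlations": arr(self.matched_correlations),
            "collectivities": arr(self.collectivities),
        }


@dataclass
class SuccessSummary:
    cutoff: float
    success_rate: float
    n_proteins: int
    bootstrap_mean: float
    bootstrap_iqr: tuple
    bootstrap_central95: tuple
    n_boot: int
    sample_size: int


def _vectors(motions) -> np.ndarray:
    v = getattr(motions, "vectors", motions)
    v = np.asarray(v, dtype=float)
    if v.ndim == 2:
        v = v[:, None, :]
    return v


def best_match_nsse(gt, pred, weights=None, protein_id: str = "") -> EvaluationReport:
    """All K x K pairwise NSSE under per-pair optimal rotation and scaling.

    The best pair is the matrix minimum (ties to the lowest pred then gt
    index).  Rows/columns involving a degenerate (all-zero) ground-truth
    component are NaN and excluded.
    """
    g = _vectors(gt)
    p = _vectors(pred)
    if g.shape[0] != p.shape[0]:
        raise ValueError("residue count mismatch between gt and pred")
    Kp, Kg = p.shape[1], g.shape[1]
    matrix = np.full((Kp, Kg), np.nan)
    for k in range(Kp):
        for l in range(Kg):
            try:
                matrix[k, l] = pair_nsse(g[:, l, :], p[:, k, :], weights)
            except DegenerateMotionError:
                warnings.warn(f"degenerate ground-truth component {l}; "
                              "excluded from best-match search", RuntimeWarning)
    if np.all(np.isnan(matrix)):
        raise DegenerateMotionError("no valid ground-truth component")
    flat_best = np.nanargmin(matrix)
    best_pair = tuple(int(v) for v in np.unravel_index(flat_best, matrix.shape))
    from .motions import collectivity
    coll = np.array([collectivity(g[:, l, :]) if np.any(g[:, l, :]) else np.nan
                     for l in range(Kg)])
    return EvaluationReport(
        protein_id=protein_id, nsse_matrix=matrix, best_pair=best_pair,
        best_nsse=float(matrix[best_pair]), collectivities=coll,
    )


def success_rate(reports, cutoff: float = 0.6, n_boot: int = 1000,
                 sample_size: int | None = None, replace: bool = True,
                 seed: int = 0) -> SuccessSummary:
    """Fraction of proteins with best-match NSSE below the cutoff.

    Uncertainty comes from ``n_boot`` bootstrap samples of
    ``ceil(N^(2/3))`` proteins drawn with replacement (about 100 proteins
    for a cohort of ~1100); the summary reports the bootstrap mean,
    interquartile range and central 95% range.
    """
    if not 0 < cutoff <= 1:
        raise ValueError("cutoff must be in (0, 1]")
    values = np.array([r.best_nsse if hasattr(r, "best_nsse") else float(r)
                       for r in reports], dtype=float)
    if values.size == 0:
        raise ValueError("empty report list")
    n = values.size
    rate = float(np.mean(values < cutoff))
    if sample_size is None:
        sample_size = int(math.ceil(n ** (2.0 / 3.0)))
    rng = np.random.default_rng(seed)
    if replace:
        idx = rng.integers(n, size=(n_boot, sample_size))
        rates = (values[idx] < cutoff).mean(axis=1)
    else:
        if sample_size > n:
            raise ValueError("sample_size > N without replacement")
        rates = np.array([
            (values[rng.choice(n, size=sample_size, replace=False)] < cutoff).mean()
            for _ in range(n_boot)])
    q25, q75 = np.quantile(rates, [0.25, 0.75])
    lo, hi = np.quantile(rates, [0.025, 0.975])
    return SuccessSummary(
        cutoff=cutoff, success_rate=rate, n_proteins=n,
        bootstrap_mean=float(rates.mean()),
        bootstrap_iqr=(float(q25), float(q75)),
        bootstrap_central95=(float(lo), float(hi)),
        n_boot=n_boot, sample_size=sample_size,
    )


def _gram_schmidt(flat: np.ndarray, order, drop_tol: float = 1e-8):
    """Orthonormalise rows of ``flat`` in the given order; drop dependent rows.

    Returns (orthonormal rows, kept original indices).
    """
    basis, kept = [], []
    for idx in order:
        v = flat[idx].copy()
        norm0 = np.linalg.norm(v)
        if norm0 <= 0:
            warnings.warn(f"zero predicted component {idx} dropped from "
                          "Gram-Schmidt", RuntimeWarning)
            continue
        for b in basis:
            v -= (b @ v) * b
        norm = np.linalg.norm(v)
        if norm <= drop_tol * norm0:
            warnings.warn(f"linearly dependent predicted component {idx} "
                          "dropped from Gram-Schmidt", RuntimeWarning)
            continue
        basis.append(v / norm)
        kept.append(idx)
    return np.array(basis), kept


def rmsip(gt, pred, order=None) -> float:
    """Root mean square inner product of the two K-motion subspaces.

    Predictions are orthogonalised by Gram-Schmidt (component index order
    unless ``order`` is given); ground-truth components, orthogonal by
    construction, are normalised.  When D <= K predicted components survive
    orthogonalisation the average runs over D, keeping the score in [0, 1].
    """
    g = _vectors(gt)
    p = _vectors(pred)
    L = g.shape[0]
    gf = g.transpose(1, 0, 2).reshape(g.shape[1], 3 * L)
    pf = p.transpose(1, 0, 2).reshape(p.shape[1], 3 * L)
    if order is None:
        order = range(pf.shape[0])
    basis, kept = _gram_schmidt(pf, order)
    if len(kept) == 0:
        return 0.0
    gnorm = gf / np.linalg.norm(gf, axis=1, keepdims=True)
    inner = gnorm @ basis.T
    denom = min(gf.shape[0], len(kept))
    return float(np.sqrt(np.sum(inner ** 2) / denom))


def matched_subspace_report(gt, pred, weights=None, protein_id: str = ""
                            ) -> EvaluationReport:
    """Globally matched and aligned subspace comparison.

    Four steps: (1) all-pairs NSSE under per-pair optimal rotation and
    scaling; (2) Gram-Schmidt orthogonalisation of the predictions ordered
    from best- to worst-matching; (3) one global rotation of the matched,
    ordered ground-truth components onto the ordered orthogonalised
    predictions; (4) pairwise normalised inner products, pairwise NSSE
    under optimal scaling only, and pairwise Pearson correlations of the
    aligned flattened vectors.  The ``rmsip`` field reports the
    orthogonalisation-order-invariant subspace overlap (identical to
    ``rmsip()`` up to round-off).
    """
    from .alignment import optimal_scaling, sse_max, weighted_sse

    report = best_match_nsse(gt, pred, weights, protein_id=protein_id)
    g = _vectors(gt)
    p = _vectors(pred)
    L, Kp, Kg = g.shape[0], p.shape[1], g.shape[1]
    matrix = report.nsse_matrix

    # greedy bijective matching by ascending NSSE
    pairs = sorted(
        ((matrix[k, l], k, l) for k in range(Kp) for l in range(Kg)
         if not np.isnan(matrix[k, l])))
    used_p, used_g, matching = set(), set(), []
    for val, k, l in pairs:
        if k in used_p or l in used_g:
            continue
        matching.append((k, l))
        used_p.add(k)
        used_g.add(l)

    pred_order = [k for k, _ in matching]
    pf = p.transpose(1, 0, 2).reshape(Kp, 3 * L)
    basis, kept = _gram_schmidt(pf, pred_order)
    report.rmsip = rmsip(g, p, order=pred_order)
    if len(kept) == 0:
        return report

    gt_order = [l for k, l in matching if k in kept]
    ortho = basis.reshape(len(kept), L, 3)
    g_matched = g[:, gt_order, :].copy()
    # single global rotation of the ordered ground truth onto the
    # orthogonalised predictions
    r = optimal_rotation(g_matched, ortho.transpose(1, 0, 2), weights)
    g_rot = np.einsum("ab,ikb->ika", r, g_matched)

    D = len(kept)
    products = np.zeros((D, D))
    nsse_mat = np.zeros((D, D))
    corr = np.zeros((D, D))
    for a in range(D):          # predicted (orthogonalised), in loss order
        pa = ortho[a]
        for b in range(D):      # matched ground truth, same ordering
            gb = g_rot[:, b, :]
            products[a, b] = float(
                (gb.ravel() @ pa.ravel())
                / (np.linalg.norm(gb) * np.linalg.norm(pa)))
            s = optimal_scaling(gb, pa, weights)
            nsse_mat[a, b] = weighted_sse(gb, pa, weights, s) / sse_max(gb, weights)
            corr[a, b] = float(np.corrcoef(gb.ravel(), pa.ravel())[0, 1])
    report.matched_pair_products = products
    report.matched_pair_nsse = nsse_mat
    report.matched_correlations = corr
    return report


def random_baseline(gt_component: np.ndarray, n_rand: int = 1000,
                    seed: int = 0) -> np.ndarray:
    """NSSE sample of standard-normal random predictions.

    Each of ``n_rand`` draws is an independent L x 3 standard-normal
    prediction scored against the normalised ground-truth component under
    optimal rotation and scaling with unit weights (maximum-confidence
    protein).  Uses the closed form NSSE = 1 - ||M||_*^2 / (||g||^2 ||p||^2)
    with M the cross-covariance, batched over draws.
    """
    g = np.asarray(gt_component, dtype=float)
    L = g.shape[0]
    rng = np.random.default_rng(seed)
    preds = rng.standard_normal((n_rand, L, 3))
    m = np.einsum("nia,ib->nab", preds, g)
    s = np.linalg.svd(m, compute_uv=False)
    g2 = float(np.sum(g ** 2))
    p2 = np.einsum("nia,nia->n", preds, preds)
    vals = 1.0 - s.sum(axis=1) ** 2 / (g2 * p2)
    return np.clip(vals, 0.0, 1.0)


def write_report_json(report: EvaluationReport, path) -> None:
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=1)


def write_summary_table(reports, path) -> None:
    """One row per protein: id, best NSSE, RMSIP, collectivity of the
    best-matched ground-truth component."""
    with open(path, "w") as fh:
        fh.write("protein_id\tbest_nsse\trmsip\tbest_gt_collectivity\n")
        for r in reports:
            kappa = (float("nan") if r.collectivities is None
                     else r.collectivities[r.best_pair[1]])
            fh.write(f"{r.protein_id}\t{r.best_nsse:.6g}\t{r.rmsip:.6g}\t"
                     f"{kappa:.6g}\n")
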