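"""Rotation-, permutation- and scaling-invariant comparison of motion sets.

A *motion set* is an ``L x K x 3`` tensor of per-residue 3D displacement
vectors.  Because a predictor working from sequence embeddings alone has no
notion of a global 3D frame, predicted motions may come in an arbitrary
orientation, in any component order, and at an arbitrary scale.  The training
loss therefore minimises, over the full orthogonal group O(3) (reflections,
i.e. pseudo-rotations, allowed), all K! component permutations and signed
per-component scalings, a weighted sum-of-squares error between the
transformed ground truth and the prediction:

    loss = (1/L) * min_{R,S,P} sum_i w_i || R (P X_i^GT)^T - (S X_i)^T ||_F^2

The transformation is applied to the *ground truth*, not the prediction, so
that gradients with respect to the prediction stay well-behaved; ``R``,
``P`` and ``S`` are recomputed on every forward evaluation and treated as
constants for differentiation.

Per-pair evaluation errors (SSE, SSE_max, NSSE) follow the same algebra with
K = 1.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AlignmentResult",
    "optimal_rotation",
    "best_permutation_and_rotation",
    "optimal_scaling",
    "weighted_sse",
    "sse_max",
    "nsse",
    "training_loss",
    "pair_nsse",
]

_EPS = 1e-300


class DegenerateMotionError(ValueError):
    """Raised when a motion tensor is identically zero where it may not be."""


@dataclass
class AlignmentResult:
    """Optimal transformation aligning a ground-truth motion set on a prediction.

    ``permutation[k]`` is the index of the ground-truth component matched to
    predicted component ``k``.  ``rotation`` is a 3x3 orthogonal matrix with
    determinant +1 or -1 (a pseudo-rotation combines a rotation with an
    inversion).  ``scalings`` holds the signed per-component coefficients
    S_kk applied to the prediction.
    """

    permutation: tuple[int, ...]
    rotation: np.ndarray
    scalings: np.ndarray
    sse_per_component: np.ndarray
    nsse_per_component: np.ndarray
    loss: float
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "permutation": list(self.permutation),
            "rotation": [float(v) for v in self.rotation.ravel()],
            "det": float(np.linalg.det(self.rotation)),
            "scalings": [float(s) for s in self.scalings],
            "sse": [float(s) for s in self.sse_per_component],
            "nsse": [float(s) for s in self.nsse_per_component],
            "loss": float(self.loss),
        }


def _as_lk3(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim == 2:
        x = x[:, None, :]
    if x.ndim != 3 or x.shape[2] != 3:
        raise ValueError(f"expected an L x K x 3 array, got shape {x.shape}")
    return x


def _weights(weights, L: int) -> np.ndarray:
    if weights is None:
        return np.ones(L)
    w = np.asarray(weights, dtype=float)
    if w.shape != (L,):
        raise ValueError(f"weights must have shape ({L},), got {w.shape}")
    return w


def optimal_rotation(gt: np.ndarray, pred: np.ndarray, weights=None,
                     allow_reflection: bool = True) -> np.ndarray:
    """Orthogonal matrix R minimising sum_i w_i ||R gt_i - pred_i||^2.

    Solves the (weighted) orthogonal Procrustes problem over O(3) by SVD of
    the cross-covariance; no determinant-sign correction is applied by
    default, so the optimum may be a pseudo-rotation with det(R) = -1.  Pass
    ``allow_reflection=False`` to constrain the search to SO(3).

    ``gt`` and ``pred`` may be ``L x 3`` or ``L x K x 3`` (all components
    share the single rotation).
    """
    gt = _as_lk3(gt)
    pred = _as_lk3(pred)
    if gt.shape != pred.shape:
        raise ValueError(f"shape mismatch: {gt.shape} vs {pred.shape}")
    w = _weights(weights, gt.shape[0])
    # cross-covariance  M = sum_{i,k} w_i pred_{ik} gt_{ik}^T
    m = np.einsum("i,ika,ikb->ab", w, pred, gt)
    u, s, vt = np.linalg.svd(m)
    r = u @ vt
    if not allow_reflection and np.linalg.det(r) < 0:
        d = np.ones(3)
        d[-1] = -1.0
        r = u @ np.diag(d) @ vt
    return r


def optimal_scaling(gt_aligned: np.ndarray, pred: np.ndarray, weights=None) -> float:
    """Closed-form signed least-squares scaling of the prediction.

    Returns s minimising sum_i w_i || gt_i - s pred_i ||^2, i.e.

        s = sum_i w_i gt_i . pred_i  /  sum_i w_i ||pred_i||^2

    The coefficient is signed (a sign flip of the prediction is absorbed
    here) and is zero when the prediction is orthogonal to the aligned
    ground truth.  A zero-norm prediction yields s = 0 with a warning.
    """
    gt_aligned = np.asarray(gt_aligned, dtype=float)
    pred = np.asarray(pred, dtype=float)
    w = _weights(weights, gt_aligned.shape[0])
    denom = np.einsum("i,ia,ia->", w, pred, pred)
    if denom <= _EPS:
        warnings.warn("zero-norm prediction: scaling coefficient set to 0",
                      RuntimeWarning, stacklevel=2)
        return 0.0
    num = np.einsum("i,ia,ia->", w, gt_aligned, pred)
    return float(num / denom)


def weighted_sse(gt_aligned: np.ndarray, pred: np.ndarray, weights=None,
                 s: float = 1.0) -> float:
    """Weighted sum-of-squares error (1/L) sum_i w_i ||gt_i - s pred_i||^2."""
    gt_aligned = np.asarray(gt_aligned, dtype=float)
    pred = np.asarray(pred, dtype=float)
    w = _weights(weights, gt_aligned.shape[0])
    diff = gt_aligned - s * pred
    return float(np.einsum("i,ia,ia->", w, diff, diff) / gt_aligned.shape[0])


def sse_max(gt_aligned: np.ndarray, weights=None) -> float:
    """Null-prediction error (1/L) sum_i w_i ||gt_i||^2.

    Equals 1 for a component normalised to sum ||x_i||^2 = L under unit
    weights; it shrinks as confidence weights decrease.
    """
    gt_aligned = np.asarray(gt_aligned, dtype=float)
    w = _weights(weights, gt_aligned.shape[0])
    return float(np.einsum("i,ia,ia->", w, gt_aligned, gt_aligned)
                 / gt_aligned.shape[0])


def nsse(sse: float, sse_max_value: float) -> float:
    """Normalised error SSE / SSE_max; 0 = perfect, 1 = orthogonal or null."""
    if sse_max_value <= 0:
        raise DegenerateMotionError("SSE_max is zero: degenerate ground truth")
    return float(sse / sse_max_value)


def pair_nsse(gt_comp: np.ndarray, pred_comp: np.ndarray, weights=None,
              allow_reflection: bool = True) -> float:
    """NSSE of a single predicted component against a single ground-truth one
    under per-pair optimal rotation and optimal signed scaling.

    Uses the closed form NSSE = 1 - (nuclear norm of the weighted
    cross-covariance)^2 / (sum w ||gt||^2 * sum w ||pred||^2), which follows
    from substituting the Procrustes rotation and the least-squares scaling
    into the error.
    """
    gt_comp = np.asarray(gt_comp, dtype=float)
    pred_comp = np.asarray(pred_comp, dtype=float)
    w = _weights(weights, gt_comp.shape[0])
    g2 = np.einsum("i,ia,ia->", w, gt_comp, gt_comp)
    p2 = np.einsum("i,ia,ia->", w, pred_comp, pred_comp)
    if g2 <= 0:
        raise DegenerateMotionError("degenerate (zero) ground-truth component")
    if p2 <= 0:
        return 1.0
    m = np.einsum("i,ia,ib->ab", w, pred_comp, gt_comp)
    s = np.linalg.svd(m, compute_uv=False)
    if not allow_reflection:
        # restrict to SO(3): the trace maximum flips the sign of the
        # smallest singular value when det < 0
        if np.linalg.det(m) < 0:
            s = s.copy()
            s[-1] *= -1.0
    val = 1.0 - (s.sum()) ** 2 / (g2 * p2)
    return float(min(max(val, 0.0), 1.0)) if allow_reflection else float(val)


def _normalised_components(pred: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Predicted components scaled to unit weighted norm (degenerate ones kept)."""
    norms = np.sqrt(np.einsum("i,ika,ika->k", w, pred, pred))
    safe = np.where(norms > 1e-12, norms, 1.0)
    return pred / safe[None, :, None], norms


def best_permutation_and_rotation(gt: np.ndarray, pred: np.ndarray, weights=None,
                                  allow_reflection: bool = True,
                                  allow_permutation: bool = True,
                                  allow_sign_flip: bool = True,
                                  ) -> tuple[tuple[int, ...], np.ndarray]:
    """Jointly optimal component permutation and Procrustes rotation.

    All K! permutations are enumerated (K <= 6).  For each candidate the
    rotation step operates on predicted components normalised to unit
    weighted norm, with both component signs enumerated, so that the
    selected (P, R) — and hence the loss — is exactly invariant to
    rescaling or flipping individual predicted components (the scaling
    matrix S absorbs magnitude and sign afterwards).  Candidates are ranked
    by the final per-component-scaled loss; ties break on the
    lexicographically smallest permutation.
    """
    perm, rot, _ = _search(gt, pred, weights, allow_reflection,
                           allow_permutation, allow_sign_flip)
    return perm, rot


def _search(gt, pred, weights, allow_reflection, allow_permutation,
            allow_sign_flip):
    gt = _as_lk3(gt)
    pred = _as_lk3(pred)
    if gt.shape != pred.shape:
        raise ValueError(f"shape mismatch: {gt.shape} vs {pred.shape}")
    L, K, _ = gt.shape
    if K > 6:
        raise ValueError("factorial permutation enumeration limited to K <= 6")
    w = _weights(weights, L)

    pred_hat, pred_norms = _normalised_components(pred, w)
    pred_sq = np.einsum("i,ika,ika->k", w, pred, pred)
    perms = (list(itertools.permutations(range(K))) if allow_permutation
             else [tuple(range(K))])
    signs = (list(itertools.product((1.0, -1.0), repeat=K)) if allow_sign_flip
             else [(1.0,) * K])

    best = None  # (loss, perm, rotation)
    for perm in perms:
        g = gt[:, perm, :]
        g_sq = np.einsum("i,ika,ika->k", w, g, g)
        # per-component cross-covariances with unit-norm predictions
        m_k = np.einsum("i,ika,ikb->kab", w, pred_hat, g)
        for sg in signs:
            m = np.einsum("k,kab->ab", np.asarray(sg), m_k)
            u, _, vt = np.linalg.svd(m)
            r = u @ vt
            if not allow_reflection and np.linalg.det(r) < 0:
                d = np.diag([1.0, 1.0, -1.0])
                r = u @ d @ vt
            g_rot = np.einsum("ab,ikb->ika", r, g)
            num = np.einsum("i,ika,ika->k", w, g_rot, pred)
            s_opt = np.where(pred_sq > _EPS, num / np.where(pred_sq > _EPS, pred_sq, 1.0), 0.0)
            if not allow_sign_flip:
                s_opt = np.maximum(s_opt, 0.0)
            # loss = (1/L) sum_k [ sum w ||g||^2 - 2 s num + s^2 sum w ||p||^2 ]
            loss = float(np.sum(g_sq - 2.0 * s_opt * num + s_opt ** 2 * pred_sq) / L)
            if best is None or loss < best[0] - 1e-15:
                best = (loss, perm, r)
    return best[1], best[2], best[0]


def training_loss(gt: np.ndarray, pred: np.ndarray, weights=None,
                  allow_reflection: bool = True,
                  allow_permutation: bool = True,
                  allow_sign_flip: bool = True,
                  ) -> tuple[float, AlignmentResult]:
    """Invariant weighted aligned sum-of-squares loss between motion sets.

    Two-step protocol: (1) joint exhaustive permutation + orthogonal
    Procrustes rotation of the ground truth; (2) per-component closed-form
    signed scaling of the prediction.  The three ``allow_*`` toggles expose
    the ablation variants (constrain det(R) = +1, fix P = I, constrain
    S_kk >= 0); each constraint can only increase the loss.

    Returns the scalar loss (1/L-scaled) and the full transformation.  When
    used inside a training loop the returned rotation, permutation and
    scalings are treated as constants of the forward pass: the gradient of
    the loss with respect to the prediction is
    ``(2/L) w_i S_kk (S_kk x_ik - x_ik^GT-trans)``.
    """
    gt = _as_lk3(gt)
    pred = _as_lk3(pred)
    L, K, _ = gt.shape
    w = _weights(weights, L)
    perm, rot, _ = _search(gt, pred, weights, allow_reflection,
                           allow_permutation, allow_sign_flip)
    g = np.einsum("ab,ikb->ika", rot, gt[:, perm, :])
    pred_sq = np.einsum("i,ika,ika->k", w, pred, pred)
    degenerate = bool(np.any(pred_sq <= _EPS))
    num = np.einsum("i,ika,ika->k", w, g, pred)
    scal = np.where(pred_sq > _EPS, num / np.where(pred_sq > _EPS, pred_sq, 1.0), 0.0)
    if not allow_sign_flip:
        scal = np.maximum(scal, 0.0)
    diff = g - scal[None, :, None] * pred
    sse_k = np.einsum("i,ika,ika->k", w, diff, diff) / L
    max_k = np.einsum("i,ika,ika->k", w, g, g) / L
    nsse_k = np.where(max_k > 0, sse_k / np.where(max_k > 0, max_k, 1.0), np.nan)
    loss = float(sse_k.sum())
    result = AlignmentResult(
        permutation=perm,
        rotation=rot,
        scalings=scal,
        sse_per_component=sse_k,
        nsse_per_component=nsse_k,
        loss=loss,
        degenerate=degenerate,
    )
    return loss, result


def loss_gradient(gt_aligned: np.ndarray, pred: np.ndarray, weights,
                  scalings: np.ndarray) -> np.ndarray:
    """Gradient of the loss w.r.t. the prediction with (P, R, S) frozen.

    ``gt_aligned`` is the permuted-and-rotated ground truth ``L x K x 3``.
    """
    L = gt_aligned.shape[0]
    w = _weights(weights, L)
    s = np.asarray(scalings, dtype=float)
    return (2.0 / L) * w[:, None, None] * s[None, :, None] * (
        s[None, :, None] * pred - gt_aligned)
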