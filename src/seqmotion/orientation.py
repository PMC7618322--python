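"""Orienting predicted motions onto a 3D conformation by zeroing angular velocity.

A principal component extracted from a superposed collection inherits, from
the optimality of the least-squares superposition, the rotational
constraint that the summed cross products of the reference positions with
the displacement vectors vanish (the conformation has zero total angular
velocity under the motion).  A predicted motion arrives in an arbitrary
frame; to anchor it on a target conformation C we look for the rotation(s)
R with

    sum_i C_i x (R x_i) = 0 .

Writing R through a unit quaternion q turns the three components of this
constraint into three quadratic forms q^T Q_a q = 0 on the unit 3-sphere —
three quadrics in projective 3-space intersect in at most eight points, and
q, -q give the same rotation, hence at most four solutions.  We solve the
system numerically with a vectorised multi-start damped Gauss-Newton and
merge near-duplicate solutions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "OrientationSolution",
    "angular_velocity_residual",
    "solve_orienting_rotations",
    "orient_prediction",
    "deform_along",
    "write_trajectory_pdb",
]


def _quad_basis() -> np.ndarray:
    """B[c, d] with R_{cd}(q) = q^T B[c,d] q for homogeneous quaternion q."""
    B = np.zeros((3, 3, 4, 4))
    w, x, y, z = 0, 1, 2, 3

    def diag(c, d, signs):
        for i, s in enumerate(signs):
            B[c, d, i, i] = s

    def off(c, d, i, j, s):
        B[c, d, i, j] += s
        B[c, d, j, i] += s

    diag(0, 0, (1, 1, -1, -1))
    diag(1, 1, (1, -1, 1, -1))
    diag(2, 2, (1, -1, -1, 1))
    off(0, 1, x, y, 1); off(0, 1, w, z, -1)
    off(0, 2, x, z, 1); off(0, 2, w, y, 1)
    off(1, 0, x, y, 1); off(1, 0, w, z, 1)
    off(1, 2, y, z, 1); off(1, 2, w, x, -1)
    off(2, 0, x, z, 1); off(2, 0, w, y, -1)
    off(2, 1, y, z, 1); off(2, 1, w, x, 1)
    return B


_B = _quad_basis()
_EPSILON = np.zeros((3, 3, 3))
for _a, _b, _c in [(0, 1, 2), (1, 2, 0), (2, 0, 1)]:
    _EPSILON[_a, _b, _c] = 1.0
    _EPSILON[_a, _c, _b] = -1.0


def quaternion_to_matrix(q: np.ndarray) -> np.ndarray:
    """Proper rotation matrix of a (not necessarily unit) quaternion."""
    q = np.asarray(q, dtype=float)
    q = q / np.linalg.norm(q, axis=-1, keepdims=True)
    return np.einsum("...i,cdij,...j->...cd", q, _B, q)


@dataclass
class OrientationSolution:
    """Candidate rotations zeroing the angular-velocity residual.

    ``rotations`` (det +1 each) are sorted by ascending ``residual_norms``
    (Å² units of the cross-product sum).  ``exact[i]`` marks residuals
    below the tolerance 1e-6 * ||C||_F * ||x||_F; when the motion does not
    satisfy the constraint in any frame (e.g. noisy predictions), the best
    local minima are returned with ``exact`` False.  ``multiplicities``
    counts the near-duplicate numerical solutions merged into each
    candidate.
    """

    rotations: list
    residual_norms: np.ndarray
    exact: np.ndarray
    multiplicities: np.ndarray

    @property
    def n_solutions(self) -> int:
        return len(self.rotations)


def angular_velocity_residual(conformation: np.ndarray, motion: np.ndarray,
                              weights=None) -> np.ndarray:
    """sum_i [w_i] C_i x x_i, the total angular velocity (Å² units)."""
    conformation = np.asarray(conformation, dtype=float)
    motion = np.asarray(motion, dtype=float)
    cross = np.cross(conformation, motion)
    if weights is not None:
        cross = cross * np.asarray(weights, dtype=float)[:, None]
    return cross.sum(axis=0)


def _quadrics(conformation: np.ndarray, motion: np.ndarray,
              weights=None) -> np.ndarray:
    """The three 4x4 symmetric forms Q_a with f_a(q) = q^T Q_a q."""
    C = np.asarray(conformation, dtype=float)
    X = np.asarray(motion, dtype=float)
    if weights is not None:
        C = C * np.asarray(weights, dtype=float)[:, None]
    G = C.T @ X                                   # G[b, d] = sum_i C_ib x_id
    T = np.einsum("abc,bd->acd", _EPSILON, G)     # T[a, c, d]
    return np.einsum("acd,cdij->aij", T, _B)


def _solve_quadrics(Q: np.ndarray, n_starts: int, seed: int,
                    max_iter: int = 120) -> np.ndarray:
    """Multi-start damped Gauss-Newton roots of {q^T Q_a q = 0, |q| = 1}.

    Returns the final (n_starts, 4) quaternions (normalised); callers
    filter by residual.
    """
    nq = Q.shape[0]
    rng = np.random.default_rng(seed)
    q = rng.standard_normal((n_starts, 4))
    q[0] = (1.0, 0.0, 0.0, 0.0)
    q /= np.linalg.norm(q, axis=1, keepdims=True)

    lam = np.full(n_starts, 1e-3)

    def residuals(qq):
        f = np.einsum("ni,aij,nj->na", qq, Q, qq)
        c = (np.einsum("ni,ni->n", qq, qq) - 1.0)[:, None]
        return np.concatenate([f, c], axis=1)

    def jacobian(qq):
        jf = 2.0 * np.einsum("aij,nj->nai", Q, qq)
        jc = 2.0 * qq[:, None, :]
        return np.concatenate([jf, jc], axis=1)

    F = residuals(q)
    cost = np.einsum("nr,nr->n", F, F)
    eye = np.eye(4)
    for _ in range(max_iter):
        J = jacobian(q)
        g = np.einsum("nri,nr->ni", J, F)
        H = np.einsum("nri,nrj->nij", J, J)
        A = H + lam[:, None, None] * eye[None, :, :]
        try:
            delta = np.linalg.solve(A, -g[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            A = H + (lam[:, None, None] + 1e-8) * eye[None, :, :]
            delta = np.linalg.solve(A, -g[:, :, None])[:, :, 0]
        q_new = q + delta
        F_new = residuals(q_new)
        cost_new = np.einsum("nr,nr->n", F_new, F_new)
        better = cost_new < cost
        q = np.where(better[:, None], q_new, q)
        F = np.where(better[:, None], F_new, F)
        cost = np.where(better, cost_new, cost)
        lam = np.where(better, lam * 0.3, lam * 5.0)
        lam = np.clip(lam, 1e-14, 1e6)
        if np.all(cost < 1e-30):
            break
    return q / np.linalg.norm(q, axis=1, keepdims=True)


def _cluster(quats: np.ndarray, residuals: np.ndarray, tol: float = 5e-4):
    """Greedy merge of quaternions equal up to sign within ``tol``."""
    order = np.argsort(residuals)
    reps, res, mult = [], [], []
    for idx in order:
        q = quats[idx]
        matched = False
        for j, r in enumerate(reps):
            if min(np.linalg.norm(q - r), np.linalg.norm(q + r)) < tol:
                mult[j] += 1
                matched = True
                break
        if not matched:
            reps.append(q)
            res.append(residuals[idx])
            mult.append(1)
    return np.array(reps), np.array(res), np.array(mult)


def solve_orienting_rotations(conformation: np.ndarray, motion: np.ndarray,
                              weights=None, n_starts: int = 64, seed: int = 0,
                              tol_factor: float = 1e-6,
                              max_solutions: int = 4) -> OrientationSolution:
    """All rotations (det +1) zeroing the angular-velocity residual.

    The conformation must be centred.  Solutions with cross-product
    residual norm below ``tol_factor * ||C||_F * ||x||_F`` are flagged
    exact; when none reach the tolerance the best local minima are
    returned non-exact (the caller decides what to do with them).  At most
    ``max_solutions`` candidates are reported, ordered by residual.
    """
    C = np.asarray(conformation, dtype=float)
    X = np.asarray(motion, dtype=float)
    if not np.any(X):
        raise ValueError("cannot orient an all-zero motion")
    scale = np.linalg.norm(C) * np.linalg.norm(X)
    Q = _quadrics(C, X, weights)
    quats = _solve_quadrics(Q, n_starts, seed)
    f = np.einsum("ni,aij,nj->na", quats, Q, quats)
    res = np.linalg.norm(f, axis=1)
    reps, res_c, mult = _cluster(quats, res)
    tol = tol_factor * scale
    exact = res_c <= tol
    if exact.any():
        keep = np.flatnonzero(exact)[:max_solutions]
    else:
        keep = np.arange(min(max_solutions, len(reps)))
    rotations = [quaternion_to_matrix(reps[i]) for i in keep]
    return OrientationSolution(
        rotations=rotations,
        residual_norms=res_c[keep],
        exact=exact[keep],
        multiplicities=mult[keep],
    )


@dataclass
class OrientedCandidate:
    vectors: np.ndarray      # (L, 3) rotated motion
    rotation: np.ndarray
    residual_norm: float
    exact: bool


def orient_prediction(conformation: np.ndarray, motion_set,
                      weights=None, shared_rotation: bool = False,
                      n_starts: int = 64, seed: int = 0) -> list:
    """Orient each predicted component onto a centred target conformation.

    By default each component gets its own rotation (the constraint is
    stated per motion tensor); ``shared_rotation=True`` instead solves a
    single rotation minimising the stacked residual of all K components.
    Returns, per component, the list of candidates ordered by residual;
    no candidate is silently selected.
    """
    from .motions import MotionSet

    C = np.asarray(conformation, dtype=float)
    vectors = motion_set.vectors if isinstance(motion_set, MotionSet) \
        else np.asarray(motion_set, dtype=float)
    if vectors.ndim == 2:
        vectors = vectors[:, None, :]
    K = vectors.shape[1]

    if shared_rotation:
        Qs = np.concatenate([_quadrics(C, vectors[:, k, :], weights)
                             for k in range(K)], axis=0)
        quats = _solve_quadrics(Qs, n_starts, seed)
        f = np.einsum("ni,aij,nj->na", quats, Qs, quats)
        res = np.linalg.norm(f, axis=1)
        reps, res_c, mult = _cluster(quats, res)
        scale = np.linalg.norm(C) * np.linalg.norm(vectors)
        order = np.argsort(res_c)[:4]
        out = []
        for k in range(K):
            out.append([
                OrientedCandidate(
                    vectors=vectors[:, k, :] @ quaternion_to_matrix(reps[i]).T,
                    rotation=quaternion_to_matrix(reps[i]),
                    residual_norm=float(res_c[i]),
                    exact=bool(res_c[i] <= 1e-6 * scale))
                for i in order
            ])
        return out

    out = []
    for k in range(K):
        sol = solve_orienting_rotations(C, vectors[:, k, :], weights=weights,
                                        n_starts=n_starts, seed=seed + k)
        out.append([
            OrientedCandidate(vectors=vectors[:, k, :] @ r.T, rotation=r,
                              residual_norm=float(rn), exact=bool(ex))
            for r, rn, ex in zip(sol.rotations, sol.residual_norms, sol.exact)
        ])
    return out


def deform_along(conformation: np.ndarray, oriented_motion: np.ndarray,
                 amplitudes=None) -> np.ndarray:
    """Trajectory of conformations C + a * x for each amplitude a.

    Defaults to 10 evenly spaced amplitudes in [-1, 1] Å-per-unit-motion.
    Returns an (n_frames, L, 3) array.
    """
    conformation = np.asarray(conformation, dtype=float)
    motion = np.asarray(oriented_motion, dtype=float)
    if amplitudes is None:
        amplitudes = np.linspace(-1.0, 1.0, 10)
    amplitudes = np.asarray(amplitudes, dtype=float)
    return conformation[None, :, :] + amplitudes[:, None, None] * motion[None, :, :]


def write_trajectory_pdb(trajectory: np.ndarray, sequence: str, path) -> None:
    """Write a deformation trajectory as a multi-model Cα-only PDB file."""
    import gemmi

    from .collections import ONE_TO_THREE

    st = gemmi.Structure()
    st.name = "trajectory"
    for f, frame in enumerate(np.asarray(trajectory, dtype=float)):
        model = gemmi.Model(str(f + 1))
        chain = gemmi.Chain("A")
        for i, xyz in enumerate(frame):
            res = gemmi.Residue()
            res.name = ONE_TO_THREE.get(sequence[i] if i < len(sequence) else "G",
                                        "GLY")
            res.seqid = gemmi.SeqId(i + 1, " ")
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            atom.occ = 1.0
            atom.pos = gemmi.Position(*xyz)
            res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
        st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))
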