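"""Unit tests for the invariant loss algebra: Procrustes rotation over O(3),
permutation enumeration, closed-form scaling and the SSE/NSSE chain."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from seqmotion.alignment import (best_permutation_and_rotation, nsse,
                                 optimal_rotation, optimal_scaling, pair_nsse,
                                 sse_max, training_loss, weighted_sse)
from seqmotion.motions import normalize_component

from conftest import random_motion_set, random_orthogonal


def residual(gt, pred, w, r):
    diff = np.einsum("ab,ikb->ika", r, gt) - pred
    return float(np.einsum("i,ika,ika->", w, diff, diff))


class TestOptimalRotation:
    def test_identity_for_equal_inputs(self, rng):
        gt = random_motion_set(rng, 25, 3)
        r = optimal_rotation(gt, gt)
        assert np.allclose(r, np.eye(3), atol=1e-10)

    def test_recovers_planted_rotation(self, rng):
        gt = random_motion_set(rng, 25, 3)
        r0 = random_orthogonal(rng)
        pred = np.einsum("ab,ikb->ika", r0, gt)
        r = optimal_rotation(gt, pred)
        assert np.allclose(r, r0, atol=1e-8)
        w = np.ones(25)
        assert residual(gt, pred, w, r) < 1e-16

    def test_orthogonality_and_det(self, rng):
        gt = random_motion_set(rng, 10, 2)
        pred = random_motion_set(rng, 10, 2, normalised=False)
        r = optimal_rotation(gt, pred)
        assert np.allclose(r.T @ r, np.eye(3), atol=1e-10)
        assert abs(abs(np.linalg.det(r)) - 1) < 1e-10

    def test_beats_random_orthogonal_matrices(self, rng):
        """Monte-Carlo oracle: the Procrustes solution attains a residual no
        larger than any of 20 000 random orthogonal matrices."""
        for _ in range(5):
            gt = random_motion_set(rng, 20, 3)
            pred = random_motion_set(rng, 20, 3, normalised=False)
            w = rng.uniform(0.2, 1.0, 20)
            r = optimal_rotation(gt, pred, w)
            base = residual(gt, pred, w, r)
            qs, rs = np.linalg.qr(rng.standard_normal((20000, 3, 3)))
            qs = qs * np.sign(np.einsum("nii->ni", rs))[:, None, :]
            flip = rng.random(20000) < 0.5
            qs[flip, :, 0] *= -1
            # residual is linear in R through the cross-covariance trace
            m = np.einsum("i,ika,ikb->ab", w, pred, gt)
            const = np.einsum("i,ika,ika->", w, gt, gt) + \
                np.einsum("i,ika,ika->", w, pred, pred)
            res_all = const - 2 * np.einsum("nab,ab->n", qs, m)
            assert base <= res_all.min() + 1e-9

    def test_reflection_allowed_beats_proper_only(self, rng):
        gt = random_motion_set(rng, 15, 1)
        # mirror image: optimal alignment needs det(R) = -1
        pred = gt.copy()
        pred[:, :, 0] *= -1
        r = optimal_rotation(gt, pred)
        assert np.linalg.det(r) < 0
        assert residual(gt, pred, np.ones(15), r) < 1e-16


class TestPermutation:
    def test_cyclic_permutation_recovered(self, rng):
        gt = random_motion_set(rng, 18, 3)
        pred = gt[:, [1, 2, 0], :]
        perm, rot = best_permutation_and_rotation(gt, pred)
        assert perm == (1, 2, 0)
        loss, _ = training_loss(gt, pred)
        assert loss < 1e-12

    def test_swapped_pairing_beats_identity(self, rng):
        """Constructed counterexample where only the swapped pairing reaches
        zero residual."""
        gt = random_motion_set(rng, 12, 2)
        pred = gt[:, [1, 0], :]
        perm, _ = best_permutation_and_rotation(gt, pred)
        assert perm == (1, 0)
        loss_best, _ = training_loss(gt, pred)
        loss_id, _ = training_loss(gt, pred, allow_permutation=False)
        assert loss_best < 1e-12 < loss_id

    def test_k_mismatch_raises(self, rng):
        gt = random_motion_set(rng, 10, 3)
        pred = random_motion_set(rng, 10, 2)
        with pytest.raises(ValueError):
            best_permutation_and_rotation(gt, pred)


class TestScaling:
    def test_closed_form_half(self, rng):
        gt = normalize_component(rng.standard_normal((30, 3)))
        assert optimal_scaling(gt, 2.0 * gt) == pytest.approx(0.5, abs=1e-12)

    def test_orthogonal_gives_zero(self, rng):
        gt = np.zeros((20, 3))
        gt[:10] = rng.standard_normal((10, 3))
        pred = np.zeros((20, 3))
        pred[10:] = rng.standard_normal((10, 3))
        assert optimal_scaling(gt, pred) == 0.0

    def test_matches_numeric_1d_minimisation(self, rng):
        """Eq.-3 closed form agrees with golden-section minimisation of the
        SSE over the scaling coefficient."""
        for _ in range(10):
            L = int(rng.integers(10, 40))
            gt = rng.standard_normal((L, 3))
            pred = rng.standard_normal((L, 3))
            w = rng.uniform(0.1, 1.0, L)
            s = optimal_scaling(gt, pred, w)
            res = minimize_scalar(lambda c: weighted_sse(gt, pred, w, c),
                                  bounds=(-10, 10), method="bounded",
                                  options={"xatol": 1e-10})
            assert s == pytest.approx(res.x, abs=1e-6)

    def test_zero_prediction_flags_degeneracy(self, rng):
        gt = rng.standard_normal((10, 3))
        with pytest.warns(RuntimeWarning):
            assert optimal_scaling(gt, np.zeros((10, 3))) == 0.0


class TestSSE:
    def test_colinear_prediction_zero_error(self, rng):
        gt = normalize_component(rng.standard_normal((50, 3)))
        pred = -3.7 * gt
        s = optimal_scaling(gt, pred)
        assert weighted_sse(gt, pred, s=s) == pytest.approx(0.0, abs=1e-12)

    def test_null_scaling_gives_sse_max(self, rng):
        gt = rng.standard_normal((25, 3))
        pred = rng.standard_normal((25, 3))
        w = rng.uniform(0.1, 1.0, 25)
        assert weighted_sse(gt, pred, w, s=0.0) == pytest.approx(
            sse_max(gt, w), abs=1e-12)

    def test_matches_naive_loop(self, rng):
        gt = rng.standard_normal((15, 3))
        pred = rng.standard_normal((15, 3))
        w = rng.uniform(0.1, 1.0, 15)
        s = 0.7
        acc = sum(w[i] * np.sum((gt[i] - s * pred[i]) ** 2) for i in range(15))
        assert weighted_sse(gt, pred, w, s) == pytest.approx(acc / 15, rel=1e-12)

    def test_sse_max_unit_for_normalised_unit_weights(self, rng):
        gt = normalize_component(rng.standard_normal((64, 3)))
        assert sse_max(gt) == pytest.approx(1.0, abs=1e-12)
        assert sse_max(gt, 0.5 * np.ones(64)) == pytest.approx(0.5, abs=1e-12)

    def test_nsse_range_and_errors(self, rng):
        assert nsse(0.0, 1.0) == 0.0
        with pytest.raises(Exception):
            nsse(0.1, 0.0)
        for _ in range(10):
            gt = normalize_component(rng.standard_normal((30, 3)))
            pred = rng.standard_normal((30, 3))
            w = rng.uniform(0.1, 1.0, 30)
            v = pair_nsse(gt, pred, w)
            assert 0.0 <= v <= 1.0 + 1e-9


class TestTrainingLoss:
    def test_full_invariance_zero_loss(self, rng):
        gt = random_motion_set(rng, 30, 3)
        r0 = random_orthogonal(rng)
        d = np.array([2.0, -0.5, 3.3])
        pred = np.einsum("ab,ikb->ika", r0, gt[:, [2, 0, 1], :]) * d[None, :, None]
        loss, res = training_loss(gt, pred)
        assert loss == pytest.approx(0.0, abs=1e-12)
        assert sorted(res.permutation) == [0, 1, 2]

    def test_orthogonal_prediction_full_loss(self, rng):
        """Disjoint-support prediction: zero cross-covariance, so every
        scaling is zero and the loss is the summed null-prediction error."""
        L = 40
        gt = np.zeros((L, 2, 3))
        gt[:20] = rng.standard_normal((20, 2, 3))
        pred = np.zeros((L, 2, 3))
        pred[20:] = rng.standard_normal((20, 2, 3))
        w = rng.uniform(0.2, 1.0, L)
        loss, res = training_loss(gt, pred, w)
        expected = np.einsum("i,ika,ika->", w, gt, gt) / L
        assert loss == pytest.approx(expected, rel=1e-10)
        assert np.allclose(res.scalings, 0.0)
        assert np.allclose(res.nsse_per_component, 1.0)

    @pytest.mark.parametrize("trial", range(8))
    def test_invariance_suite(self, rng, trial):
        """Loss unchanged under O(3) transforms of the ground truth,
        component permutations, and per-component non-zero scalings of the
        prediction."""
        rng = np.random.default_rng(991 + trial)
        L, K = int(rng.integers(10, 40)), 3
        gt = random_motion_set(rng, L, K)
        pred = rng.standard_normal((L, K, 3))
        w = rng.uniform(0.1, 1.0, L)
        base, _ = training_loss(gt, pred, w)
        q = random_orthogonal(rng)
        lq, _ = training_loss(np.einsum("ab,ikb->ika", q, gt), pred, w)
        assert lq == pytest.approx(base, abs=1e-8)
        perm = rng.permutation(K)
        lp, _ = training_loss(gt[:, perm, :], pred, w)
        assert lp == pytest.approx(base, abs=1e-8)
        d = rng.uniform(0.2, 5.0, K) * rng.choice([-1.0, 1.0], K)
        ld, _ = training_loss(gt, pred * d[None, :, None], w)
        assert ld == pytest.approx(base, abs=1e-8)

    def test_ablation_toggles_never_decrease_loss(self, rng):
        """Disabling reflection, permutation or sign flips constrains the
        minimisation, so the loss can only increase or stay equal."""
        for _ in range(10):
            L = int(rng.integers(10, 30))
            gt = random_motion_set(rng, L, 3)
            pred = rng.standard_normal((L, 3, 3))
            w = rng.uniform(0.1, 1.0, L)
            base, _ = training_loss(gt, pred, w)
            for kw in ({"allow_reflection": False},
                       {"allow_permutation": False},
                       {"allow_sign_flip": False}):
                constrained, _ = training_loss(gt, pred, w, **kw)
                assert constrained >= base - 1e-10

    def test_loss_matches_direct_objective(self, rng):
        """Substituting the returned (P, R, S) into the defining objective
        reproduces the returned loss value."""
        for _ in range(5):
            L = int(rng.integers(10, 30))
            gt = random_motion_set(rng, L, 3)
            pred = rng.standard_normal((L, 3, 3))
            w = rng.uniform(0.1, 1.0, L)
            loss, res = training_loss(gt, pred, w)
            g = np.einsum("ab,ikb->ika", res.rotation, gt[:, res.permutation, :])
            direct = np.einsum(
                "i,ika,ika->", w,
                g - res.scalings[None, :, None] * pred,
                g - res.scalings[None, :, None] * pred) / L
            assert loss == pytest.approx(direct, abs=1e-10)

    def test_noise_monotonicity(self, rng):
        gt = random_motion_set(rng, 30, 3)
        base, _ = training_loss(gt, gt)
        noisy, _ = training_loss(gt, gt + 0.3 * rng.standard_normal(gt.shape))
        assert base <= noisy
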