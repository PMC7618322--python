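"""Unit tests for collection I/O, weighted superposition, reference
selection and the inclusion filters."""

import numpy as np
import pytest

from seqmotion import FixtureSpec, make_synthetic_collection
from seqmotion.collections import (AlignmentError, ConformationalCollection,
                                   FormatError, RankError, filter_collection,
                                   max_pairwise_rmsd, pairwise_rmsd,
                                   read_bundle, read_collection,
                                   select_references, superpose, write_bundle,
                                   write_member_cif, write_member_pdb)
from seqmotion.motions import extract_principal_components

from conftest import random_orthogonal


def helix(L, rng=None):
    t = np.arange(L) * 0.6
    return np.stack([5 * np.cos(t), 5 * np.sin(t), 1.9 * np.arange(L)], axis=1)


def make_collection(coords, mask=None, ref=0):
    M, L, _ = coords.shape
    if mask is None:
        mask = np.ones((M, L), dtype=bool)
    return ConformationalCollection(
        id="test", sequence="A" * L, coords=coords, mask=mask,
        weights=mask.mean(axis=0), reference_index=ref)


class TestReadCollection:
    def test_two_copies_of_one_file(self, tmp_path):
        coll = make_collection(helix(20)[None].repeat(2, axis=0))
        path = tmp_path / "member.cif"
        write_member_cif(coll, 0, path)
        read = read_collection([path, path], ["A", "A"])
        assert read.n_conformations == 2
        assert np.allclose(read.weights, 1.0)
        assert max_pairwise_rmsd(read) == pytest.approx(0.0, abs=1e-6)

    def test_unresolved_residue_weight(self, tmp_path):
        """Residue unresolved in 1 of 3 conformations gets weight 2/3."""
        coords = helix(15)[None].repeat(3, axis=0)
        mask = np.ones((3, 15), dtype=bool)
        mask[2, 5] = False
        coll = make_collection(coords, mask)
        paths = []
        for m in range(3):
            p = tmp_path / f"m{m}.cif"
            write_member_cif(coll, m, p)
            paths.append(p)
        read = read_collection(paths, ["A"] * 3)
        assert read.n_residues == 15
        assert read.weights[5] == pytest.approx(2 / 3)
        assert np.allclose(np.delete(read.weights, 5), 1.0)

    def test_mmcif_round_trip(self, tmp_path):
        spec = FixtureSpec(L=30, M=4, amplitudes=(1.5,), noise_sd=0.1, seed=2)
        coll, _ = make_synthetic_collection(spec)
        paths = []
        for m in range(4):
            p = tmp_path / f"m{m}.cif"
            write_member_cif(coll, m, p)
            paths.append(p)
        read = read_collection(paths, ["A"] * 4)
        assert np.max(np.abs(read.coords - coll.coords)) < 1e-3

    def test_pdb_round_trip(self, tmp_path):
        coll = make_collection(helix(10)[None])
        path = tmp_path / "member.pdb"
        write_member_pdb(coll, 0, path)
        read = read_collection([path], ["A"])
        assert np.max(np.abs(read.coords - coll.coords)) < 1e-3

    def test_altloc_highest_occupancy_kept(self, tmp_path):
        pdb = "\n".join([
            "ATOM      1  CA AGLY A   1       0.000   0.000   0.000  0.40 10.00           C",
            "ATOM      2  CA BGLY A   1       9.000   9.000   9.000  0.60 10.00           C",
            "ATOM      3  CA  GLY A   2       3.800   0.000   0.000  1.00 10.00           C",
            "ATOM      4  CA  GLY A   3       7.600   0.000   0.000  1.00 10.00           C",
            "END",
        ]) + "\n"
        path = tmp_path / "altloc.pdb"
        path.write_text(pdb)
        read = read_collection([path], ["A"])
        assert np.allclose(read.coords[0, 0], [9.0, 9.0, 9.0])

    def test_unparseable_file_raises(self, tmp_path):
        bad = tmp_path / "bad.cif"
        bad.write_text("this is not a structure\n")
        with pytest.raises((FormatError, AlignmentError)):
            read_collection([bad], ["A"])

    def test_missing_chain_raises(self, tmp_path):
        coll = make_collection(helix(10)[None])
        path = tmp_path / "m.cif"
        write_member_cif(coll, 0, path)
        with pytest.raises(FormatError):
            read_collection([path], ["Z"])


class TestSuperpose:
    def test_exact_recovery_of_rigid_copy(self, rng):
        base = helix(25)
        r0 = random_orthogonal(rng, reflections=False)
        coords = np.stack([base, base @ r0.T + np.array([5.0, -3.0, 8.0])])
        sup = superpose(make_collection(coords))
        assert np.max(np.abs(sup.coords[1] - sup.coords[0])) < 1e-8

    def test_centroids_at_origin(self, small_collection):
        coll, _ = small_collection
        sup = superpose(coll)
        for m in range(sup.n_conformations):
            w = sup.weights * sup.mask[m]
            c = np.einsum("i,ia->a", w, sup.coords[m]) / w.sum()
            assert np.linalg.norm(c) < 1e-8

    def test_idempotent(self, small_collection):
        coll, _ = small_collection
        once = superpose(coll)
        twice = superpose(once)
        assert np.max(np.abs(twice.coords - once.coords)) < 1e-8

    def test_kabsch_optimality_cross_product(self, small_collection):
        """Sum of cross products of reference with each superposed member is
        the null vector (rotation stationarity)."""
        coll, _ = small_collection
        sup = superpose(coll)
        ref = sup.coords[sup.reference_index]
        for m in range(sup.n_conformations):
            res = np.cross(ref, sup.coords[m]).sum(axis=0)
            assert np.linalg.norm(res) < 1e-6

    def test_cross_covariance_symmetric(self, small_collection):
        coll, _ = small_collection
        sup = superpose(coll)
        ref = sup.coords[sup.reference_index]
        w = sup.weights
        for m in range(sup.n_conformations):
            h = np.einsum("i,ia,ib->ab", w, ref, sup.coords[m])
            assert np.max(np.abs(h - h.T)) < 1e-8 * max(np.abs(h).max(), 1.0)

    def test_beats_random_rotations(self, rng, small_collection):
        """Weighted RMSD after superposition is no worse than under 10 000
        random rotations of the same conformation."""
        coll, _ = small_collection
        sup = superpose(coll)
        ref = sup.coords[sup.reference_index]
        w = sup.weights
        m = 1 if sup.reference_index != 1 else 2
        conf = sup.coords[m]
        best = np.einsum("i,ia,ia->", w, conf - ref, conf - ref)
        qs, rs = np.linalg.qr(rng.standard_normal((10000, 3, 3)))
        qs = qs * np.sign(np.einsum("nii->ni", rs))[:, None, :]
        dets = np.linalg.det(qs)
        qs[dets < 0, :, 0] *= -1
        cross = np.einsum("i,ia,ib->ab", w, ref, conf)
        const = np.einsum("i,ia,ia->", w, ref, ref) + \
            np.einsum("i,ia,ia->", w, conf, conf)
        res_all = const - 2 * np.einsum("nab,ab->n", qs, cross)
        assert best <= res_all.min() + 1e-9

    def test_collinear_reference_raises(self):
        coords = np.zeros((2, 10, 3))
        coords[:, :, 0] = np.arange(10)
        coords[1, :, 0] += 0.5
        with pytest.raises(RankError):
            superpose(make_collection(coords))


class TestSelectReferences:
    def test_single_reference_is_default(self, small_collection):
        coll, _ = small_collection
        assert select_references(coll, 1) == [coll.reference_index]

    def test_exhaustive_argmax_chain(self, small_collection):
        coll, _ = small_collection
        refs = select_references(coll, 3)
        assert len(refs) == len(set(refs)) == 3
        table = {(i, j): pairwise_rmsd(coll, i, j)
                 for i in range(coll.n_conformations)
                 for j in range(coll.n_conformations)}
        for prev, nxt in zip(refs, refs[1:]):
            candidates = [m for m in range(coll.n_conformations)
                          if m not in refs[: refs.index(nxt)]]
            best = max(candidates, key=lambda m: table[(prev, m)])
            assert table[(prev, nxt)] == pytest.approx(table[(prev, best)])

    def test_capped_at_member_count(self, small_collection):
        coll, _ = small_collection
        refs = select_references(coll, 50)
        assert len(refs) == coll.n_conformations
        assert len(set(refs)) == coll.n_conformations


class TestFilters:
    def _motions(self, coll):
        return extract_principal_components(superpose(coll), K=3)

    def test_too_few_conformations(self):
        spec = FixtureSpec(L=40, M=4, amplitudes=(2.0,), noise_sd=0.05, seed=1)
        coll, _ = make_synthetic_collection(spec)
        report = filter_collection(coll, self._motions(coll))
        assert "min_conformations" in report.failed_criteria
        assert not report.passed

    def test_too_short(self):
        spec = FixtureSpec(L=25, M=6, amplitudes=(2.0,), noise_sd=0.05, seed=1)
        coll, _ = make_synthetic_collection(spec)
        report = filter_collection(coll, self._motions(coll))
        assert "min_length" in report.failed_criteria

    def test_low_diversity_fails_rmsd(self):
        spec = FixtureSpec(L=40, M=6, amplitudes=(0.2,), noise_sd=0.01, seed=1)
        coll, _ = make_synthetic_collection(spec)
        report = filter_collection(coll, self._motions(coll))
        assert "min_rmsd" in report.failed_criteria

    def test_passing_fixture(self):
        """Collective planted motion built to satisfy every criterion."""
        spec = FixtureSpec(L=60, M=8, amplitudes=(3.0,), noise_sd=0.05, seed=5)
        coll, _ = make_synthetic_collection(spec)
        report = filter_collection(coll, self._motions(coll))
        assert report.passed, report.failed_criteria
        assert report.max_pairwise_rmsd >= 2.0
        assert report.pc1_variance_fraction >= 0.8
        assert report.effective_size >= 12

    def test_passed_iff_no_failures(self):
        spec = FixtureSpec(L=25, M=4, amplitudes=(0.2,), noise_sd=0.01, seed=1)
        coll, _ = make_synthetic_collection(spec)
        report = filter_collection(coll, self._motions(coll))
        assert (report.passed) == (not report.failed_criteria)
        assert not report.passed


class TestBundle:
    def test_round_trip(self, tmp_path, small_collection):
        coll, _ = small_collection
        write_bundle(coll, tmp_path / "bundle")
        back = read_bundle(tmp_path / "bundle")
        assert back.id == coll.id
        assert back.sequence == coll.sequence
        assert np.allclose(back.coords, coll.coords)
        assert np.array_equal(back.mask, coll.mask)
        assert np.allclose(back.weights, coll.weights)
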