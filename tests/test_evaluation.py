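"""Evaluation geometry: superposition, LRMSD, CAPRI classes, hit stats,
interface definitions and benchmark arithmetic."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from softdock.errors import SoftDockError
from softdock.evaluation import (
    BenchmarkSummary,
    CapriClass,
    ComplexEval,
    benchmark_summary,
    capri_class,
    hit_stats,
    interface_residues,
    kabsch_superpose,
    lrmsd,
    prediction_accuracy,
    relative_interface_area,
    ub_rmsd,
)
from softdock.fixtures import PSEUDO_REFERENCE_AREAS
from softdock.structure import RigidTransform, apply_transform

from conftest import make_structure


def _kabsch_oracle(P, Q):
    """Independent SVD superposition (no shared code with the package)."""
    P, Q = np.asarray(P, float), np.asarray(Q, float)
    pc, qc = P.mean(0), Q.mean(0)
    H = (P - pc).T @ (Q - qc)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1, 1, d]) @ U.T
    moved = (P - pc) @ R.T + qc
    return float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))


class TestKabsch:
    def test_identical_sets(self):
        P = np.random.default_rng(0).normal(size=(6, 3))
        xform, rmsd = kabsch_superpose(P, P)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(xform.rotation, np.eye(3), atol=1e-8)

    def test_recovers_known_rotation(self):
        rng = np.random.default_rng(7)
        P = rng.normal(size=(10, 3))
        R = Rotation.random(rng=rng).as_matrix()
        Q = P @ R.T + [1.0, -2.0, 3.0]
        xform, rmsd = kabsch_superpose(P, Q)
        assert rmsd < 1e-9
        assert np.abs(xform.rotation - R).max() < 1e-6

    def test_mirror_image_keeps_positive_rmsd(self):
        rng = np.random.default_rng(11)
        P = rng.normal(size=(8, 3))  # chiral (non-planar) set
        Q = P * [1, 1, -1]
        _, rmsd = kabsch_superpose(P, Q)
        assert rmsd > 0.1
        assert rmsd == pytest.approx(_kabsch_oracle(P, Q), abs=1e-9)

    def test_collinear_rejected(self):
        P = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], float)
        with pytest.raises(SoftDockError, match="collinear"):
            kabsch_superpose(P, P + 1.0)

    def test_size_mismatch_rejected(self):
        with pytest.raises(SoftDockError):
            kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))


class TestLrmsd:
    @pytest.fixture
    def complex_pair(self):
        rng = np.random.default_rng(5)
        rec = make_structure(rng.normal(size=(8, 3)) * 4, chain="A")
        lig = make_structure(rng.normal(size=(5, 3)) * 3 + [12, 0, 0], chain="B")
        return rec, lig

    def test_native_prediction_scores_zero(self, complex_pair):
        rec, lig = complex_pair
        assert lrmsd(rec, lig, rec, lig) == pytest.approx(0.0, abs=1e-9)

    def test_pure_ligand_translation(self, complex_pair):
        rec, lig = complex_pair
        moved = apply_transform(lig, RigidTransform(np.eye(3), np.array([0.0, 0.0, 7.0])))
        assert lrmsd(rec, lig, rec, moved) == pytest.approx(7.0, abs=1e-9)

    def test_global_rigid_motion_removed_by_superposition(self, complex_pair):
        rec, lig = complex_pair
        rng = np.random.default_rng(9)
        x = RigidTransform(Rotation.random(rng=rng).as_matrix(), rng.normal(size=3) * 20)
        assert lrmsd(rec, lig, apply_transform(rec, x), apply_transform(lig, x)) == pytest.approx(
            0.0, abs=1e-8
        )

    def test_no_common_ligand_atoms_rejected(self, complex_pair):
        rec, lig = complex_pair
        other = make_structure([(0, 0, 0), (3, 0, 0)], chain="Z")
        with pytest.raises(SoftDockError):
            lrmsd(rec, lig, rec, other)


class TestCapriClass:
    @pytest.mark.parametrize(
        "l,expected",
        [
            (0.0, CapriClass.HIGH),
            (2.5, CapriClass.HIGH),
            (2.5000001, CapriClass.MEDIUM),
            (5.0, CapriClass.MEDIUM),
            (9.99, CapriClass.ACCEPTABLE),
            (10.0, CapriClass.ACCEPTABLE),
            (10.000001, CapriClass.INCORRECT),
        ],
    )
    def test_inclusive_boundaries(self, l, expected):
        assert capri_class(l) is expected

    def test_negative_rejected(self):
        with pytest.raises(SoftDockError):
            capri_class(-0.1)

    def test_class_weakly_decreases_with_lrmsd(self):
        order = [CapriClass.HIGH, CapriClass.MEDIUM, CapriClass.ACCEPTABLE, CapriClass.INCORRECT]
        ranks = [order.index(capri_class(l)) for l in np.linspace(0, 12, 60)]
        assert ranks == sorted(ranks)


class TestHitStats:
    def test_hand_enumerated_example(self):
        ev = hit_stats([12, 9.5, 11, 9.5, 8], cutoff=10.0)
        assert ev.hit_count == 3
        assert ev.first_rank == 2
        assert ev.first_rmsd == 9.5
        assert ev.best_rmsd == 8
        assert ev.best_rank == 5

    def test_no_hits_renders_dashes(self):
        ev = hit_stats([15.0, 20.0], complex_id="1bgx")
        assert ev.hit_count == 0
        row = ev.as_row()
        assert (row["FirstRMSD"], row["FirstRank"], row["BestRMSD"], row["BestRank"]) == (
            "-", "-", "-", "-"
        )

    def test_stricter_cutoff_reanalysis(self):
        rmsds = [12, 9.5, 11, 9.5, 8, 4.9, 3.0]
        loose = hit_stats(rmsds, cutoff=10.0)
        strict = hit_stats(rmsds, cutoff=5.0)
        assert strict.hit_count == 2
        assert strict.hit_count <= loose.hit_count

    def test_top_n_truncation(self):
        ev = hit_stats([20.0, 20.0, 1.0], top_n=2)
        assert ev.hit_count == 0

    def test_invariant_enforced(self):
        with pytest.raises(SoftDockError):
            ComplexEval("x", 0, 1, 5.0, 1, 5.0)


class TestInterfaceResidues:
    refs = PSEUDO_REFERENCE_AREAS

    def test_boundary_4p9_both_interface(self):
        a = make_structure([(0, 0, 0)], chain="A")
        b = make_structure([(4.9, 0, 0)], chain="B")
        ir, il = interface_residues(a, b, reference_areas=self.refs)
        assert ir == {("A", 1, "")} and il == {("B", 1, "")}

    def test_boundary_5p0_strictly_excluded(self):
        a = make_structure([(0, 0, 0)], chain="A")
        b = make_structure([(5.0, 0, 0)], chain="B")
        ir, il = interface_residues(a, b, reference_areas=self.refs)
        assert ir == set() and il == set()

    def test_buried_residue_excluded_despite_proximity(self):
        # caged central atom 3 A from the partner fails the surface rule
        shell = 2.5 * Rotation.random(60, rng=0).apply([1.0, 0.0, 0.0])
        a = make_structure([(0, 0, 0), *shell], chain="A")
        b = make_structure([(3.0, 0, 0.2)], chain="B")
        ir, _ = interface_residues(a, b, reference_areas=self.refs)
        assert ("A", 1, "") not in ir


class TestPredictionAccuracy:
    def test_fraction(self):
        pred = {("A", i, "") for i in range(10)}
        true = {("A", i, "") for i in range(3)} | {("A", 99, "")}
        assert prediction_accuracy(pred, true) == pytest.approx(0.30)

    def test_subset_is_perfect(self):
        pred = {("A", 1, "")}
        assert prediction_accuracy(pred, pred | {("A", 2, "")}) == 1.0

    def test_disjoint_is_zero(self):
        assert prediction_accuracy({("A", 1, "")}, {("B", 1, "")}) == 0.0

    def test_empty_prediction_absent(self):
        assert prediction_accuracy(set(), {("A", 1, "")}) is None


class TestUbRmsd:
    def test_identical_monomers(self):
        s = make_structure(np.random.default_rng(0).normal(size=(6, 3)) * 5)
        assert ub_rmsd(s, s) == pytest.approx(0.0, abs=1e-9)

    def test_single_displaced_atom_matches_oracle(self):
        rng = np.random.default_rng(3)
        coords = rng.normal(size=(30, 3)) * 8
        moved = coords.copy()
        moved[4] += [3.0, 0.0, 0.0]
        a = make_structure(coords)
        b = make_structure(moved)
        assert ub_rmsd(a, b) == pytest.approx(_kabsch_oracle(coords, moved), abs=1e-9)
        # superposition can only reduce the naive sqrt(9/n) bound
        assert ub_rmsd(a, b) <= math.sqrt(9.0 / 30) + 1e-9

    def test_no_correspondence_rejected(self):
        a = make_structure([(0, 0, 0), (3, 0, 0), (0, 3, 0)], chain="A")
        b = make_structure([(0, 0, 0), (3, 0, 0), (0, 3, 0)], chain="B")
        with pytest.raises(SoftDockError):
            ub_rmsd(a, b)


class TestRelativeInterfaceArea:
    def test_distant_molecules_bury_nothing(self):
        a = make_structure([(0, 0, 0)], chain="A")
        b = make_structure([(100.0, 0, 0)], chain="B")
        assert relative_interface_area(a, b) == pytest.approx(0.0, abs=1e-6)

    def test_contact_pair_matches_dense_sampling_oracle(self):
        rng = np.random.default_rng(8)
        a = make_structure(rng.normal(size=(6, 3)) * 2.0, chain="A")
        b = make_structure(rng.normal(size=(6, 3)) * 2.0 + [5.5, 0, 0], chain="B")
        val = relative_interface_area(a, b)
        assert 0.0 < val < 1.0

        def mc_area(coords, radii, n=4000):
            total = 0.0
            for i in range(len(coords)):
                pts = rng.normal(size=(n, 3))
                pts /= np.linalg.norm(pts, axis=1)[:, None]
                sphere = coords[i] + radii[i] * pts
                buried = np.zeros(n, bool)
                for j in range(len(coords)):
                    if j != i:
                        buried |= np.sum((sphere - coords[j]) ** 2, 1) < radii[j] ** 2
                total += 4 * math.pi * radii[i] ** 2 * (~buried).mean()
            return total

        ca, cb = a.coords, b.coords
        ra = a.radii + 1.4
        cab = np.vstack([ca, cb])
        rab = np.concatenate([ra, b.radii + 1.4])
        a_r, a_l, a_c = mc_area(ca, ra), mc_area(cb, b.radii + 1.4), mc_area(cab, rab)
        oracle = 0.5 * (a_r + a_l - a_c) / a_c
        assert val == pytest.approx(oracle, rel=0.15, abs=0.01)


class TestBenchmarkSummary:
    def test_all_failures_mean_absent(self):
        s = benchmark_summary([0, 0, 0])
        assert s == BenchmarkSummary(0, 0, None)

    def test_published_style_mean(self):
        assert BenchmarkSummary.from_counts(56, 3442).mean_hits == 61.5

    def test_accepts_complex_evals(self):
        evals = [hit_stats([5.0]), hit_stats([15.0])]
        s = benchmark_summary(evals)
        assert s.n_success == 1 and s.total_hits == 1

    def test_permutation_invariant_and_additive(self):
        rng = np.random.default_rng(1)
        counts = list(rng.integers(0, 50, size=20))
        a = benchmark_summary(counts)
        b = benchmark_summary(list(reversed(counts)))
        assert a == b
        left, right = benchmark_summary(counts[:10]), benchmark_summary(counts[10:])
        assert a.total_hits == left.total_hits + right.total_hits
        assert a.n_success == left.n_success + right.n_success
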