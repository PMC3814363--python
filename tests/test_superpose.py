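"""Kabsch engine and iterative-core superposition."""

import numpy as np
import pytest

from p4ring.superpose import (displacement_of_equivalent,
                              iterative_core_superpose, kabsch,
                              rotation_angle_deg, seed_alignment)
from p4ring.synthetic import (PerturbationTruth, RingSpec, ca_trace,
                              make_ring, perturb, random_rotation,
                              rotation_about, two_domain_pair)


class TestKabsch:
    def test_identity_on_equal_inputs(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]])
        tf, rmsd = kabsch(pts, pts)
        assert rmsd < 1e-12
        np.testing.assert_allclose(tf.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(tf.translation, 0.0, atol=1e-12)

    def test_recovers_constructed_transform(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(30, 3))
        R = rotation_about([0, 0, 1], 90.0)
        t = np.array([1.0, 2.0, 3.0])
        tf, rmsd = kabsch(A, A @ R.T + t)
        assert rmsd < 1e-8
        np.testing.assert_allclose(tf.rotation, R, atol=1e-8)
        np.testing.assert_allclose(tf.translation, t, atol=1e-8)

    def test_optimal_against_random_rigid_transforms(self):
        rng = np.random.default_rng(1)
        A = rng.normal(size=(50, 3))
        B = A + rng.normal(0, 0.3, size=(50, 3))
        _, best = kabsch(A, B)
        for _ in range(1000):
            R = random_rotation(rng)
            t = rng.normal(0, 2, 3)
            rmsd = np.sqrt(np.mean(np.sum((A @ R.T + t - B) ** 2, axis=1)))
            assert best <= rmsd + 1e-12

    def test_invariant_to_common_pre_rotation(self):
        rng = np.random.default_rng(2)
        A = rng.normal(size=(40, 3))
        B = A + rng.normal(0, 0.5, size=(40, 3))
        _, rmsd0 = kabsch(A, B)
        Q = random_rotation(rng)
        _, rmsd1 = kabsch(A @ Q.T, B @ Q.T)
        assert rmsd1 == pytest.approx(rmsd0, abs=1e-8)

    def test_reflection_corrected(self):
        rng = np.random.default_rng(3)
        A = rng.normal(size=(20, 3))
        B = A.copy()
        B[:, 2] = -B[:, 2]  # mirror image
        tf, _ = kabsch(A, B)
        assert np.linalg.det(tf.rotation) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("pts", [
        np.array([[0, 0, 0], [1, 0, 0]]),              # too few
        np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0.0]]),  # collinear
        np.zeros((5, 3)),                               # coincident
    ])
    def test_degenerate_inputs_raise(self, pts):
        with pytest.raises(ValueError):
            kabsch(pts, pts)

    def test_weighted_fit_favors_heavy_points(self):
        A = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]])
        B = A.copy()
        B[3] += [5, 0, 0]  # outlier
        w = np.array([1.0, 1.0, 1.0, 1e-9])
        tf, rmsd = kabsch(A, B, weights=w)
        assert rmsd < 1e-4


class TestSeedAlignment:
    def test_index_mode_pairs_by_rank(self):
        a, b = ca_trace(50, seed=1), ca_trace(50, seed=2)
        aln = seed_alignment(a, b, mode="index")
        assert len(aln) == 50

    def test_sequence_mode_hand_alignment(self):
        # ACDEFG vs ACEFG: the unmatched D is gapped, 5 aligned columns
        names = {"A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY"}
        from p4ring.model import Atom, Chain, Residue, StructureModel

        def chain_of(seq, cid):
            residues = []
            rng = np.random.default_rng(4)
            for i, letter in enumerate(seq):
                pos = np.array([3.8 * i, 0.0, 0.0]) + rng.normal(0, 0.5, 3)
                residues.append(Residue(i + 1, names[letter],
                                        atoms=[Atom("CA", "C", pos)]))
            return StructureModel(seq, [Chain(cid, residues)])

        aln = seed_alignment(chain_of("ACDEFG", "A"), chain_of("ACEFG", "B"),
                             mode="sequence")
        assert len(aln) == 5
        paired_a = [ra.one_letter for ra, _ in aln.pairs]
        assert "D" not in paired_a
        assert [rb.one_letter for _, rb in aln.pairs] == list("ACEFG")

    def test_identical_sequences_equal_index_pairing(self):
        a, b = ca_trace(40, seed=5), ca_trace(40, seed=5)
        seq = seed_alignment(a, b, mode="sequence")
        idx = seed_alignment(a, b, mode="index")
        assert [(ra.number, rb.number) for ra, rb in seq.pairs] == \
               [(ra.number, rb.number) for ra, rb in idx.pairs]


class TestIterativeCore:
    def test_self_superposition_is_identity(self, trace60):
        sup = iterative_core_superpose(trace60, trace60)
        assert sup.fraction_equivalent == 1.0
        assert sup.rmsd_core < 1e-10
        assert sup.identity_pct == 100.0
        np.testing.assert_allclose(sup.transform.rotation, np.eye(3), atol=1e-8)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_planted_60_40_split_recovered_exactly(self, seed):
        a, b = two_domain_pair(n_core=60, n_displaced=40, displacement=20.0,
                               seed=seed)
        sup = iterative_core_superpose(a, b)
        assert sup.fraction_equivalent == pytest.approx(0.60)
        assert sup.rmsd_core < 1e-8
        assert all(ra.number <= 60 for ra, _ in sup.core_pairs)
        assert sup.rmsd_all > sup.rmsd_core

    def test_core_rmsd_bounded_by_all_rmsd(self, trace60):
        moved = perturb(trace60, PerturbationTruth(noise_sigma=1.0), seed=9)
        sup = iterative_core_superpose(trace60, moved)
        assert sup.rmsd_core <= sup.rmsd_all + 1e-12

    def test_no_conserved_core_raises(self):
        # two unrelated traces well beyond any 3.8 Å equivalence
        a = ca_trace(30, seed=21)
        b = perturb(ca_trace(30, seed=22), PerturbationTruth(noise_sigma=30.0), seed=1)
        with pytest.raises(ValueError, match="core"):
            iterative_core_superpose(a, b)

    @pytest.mark.parametrize("sigma", [0.3, 1.0])
    def test_noise_recovery_rotation_within_2_degrees(self, sigma):
        ring = make_ring(RingSpec(n_subunits=6, ring_radius=25.0,
                                  subunit_template=ca_trace(30, seed=7)))
        rng = np.random.default_rng(50)
        for s in range(3):
            R = random_rotation(rng)
            t = rng.normal(0, 10, 3)
            moved = perturb(ring, PerturbationTruth(R, t, noise_sigma=sigma), seed=s)
            sup = iterative_core_superpose(ring, moved)
            assert rotation_angle_deg(sup.transform.rotation, R) < 2.0


class TestDisplacement:
    def test_same_atom_identity_superposition_zero(self, trace60):
        sup = iterative_core_superpose(trace60, trace60)
        res = trace60.chain("A").residue(10)
        assert displacement_of_equivalent(res, res, "CA", "CA", sup) == pytest.approx(0.0, abs=1e-9)

    def test_constructed_offset_measured_exactly(self):
        a, b = two_domain_pair(seed=3)
        # move one core residue's CA in b by 8.5 Å and re-measure
        target = b.chain("A").residue(30)
        target.atoms[0].coords = target.atoms[0].coords + np.array([0.0, 0.0, 8.5])
        core_a = [r for r in a.chain("A").residues if r.number != 30 and r.number <= 60]
        core_b = [r for r in b.chain("A").residues if r.number != 30 and r.number <= 60]
        from p4ring.superpose import AlignmentPair
        sup = iterative_core_superpose(a, b, AlignmentPair(list(zip(core_a, core_b))))
        assert sup.rmsd_core < 1e-8
        d = displacement_of_equivalent(a.chain("A").residue(30), target, "CA", "CA", sup)
        assert d == pytest.approx(8.5, abs=1e-6)

    def test_missing_atom_raises(self, trace60):
        sup = iterative_core_superpose(trace60, trace60)
        res = trace60.chain("A").residue(5)
        with pytest.raises(KeyError, match="NZ"):
            displacement_of_equivalent(res, res, "NZ", "CA", sup)
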