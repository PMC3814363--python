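"""Distance matrices, neighbor joining and Newick round-trips."""

import numpy as np
import pytest

from p4ring.phylo import (DistanceMatrix, build_matrix, from_newick, nj_tree,
                          structural_distance, to_newick)
from p4ring.superpose import SuperpositionResult, RigidTransform, iterative_core_superpose, seed_alignment
from p4ring.synthetic import (PerturbationTruth, ca_trace,
                              make_additive_matrix, perturb,
                              random_additive_tree, random_rotation)


def _sup(rmsd_core, n_eq, n_min):
    return SuperpositionResult(
        transform=RigidTransform.identity(), rmsd_core=rmsd_core,
        rmsd_all=rmsd_core, n_equivalent=n_eq, n_min=n_min,
        iterations=1, identity_pct=50.0)


class TestStructuralDistance:
    def test_identical_structures_distance_zero(self):
        assert structural_distance(_sup(0.0, 100, 100)) == 0.0

    def test_penalized_rmsd_formula(self):
        # rmsd 2.0 at 50% equivalenced → distance 4.0
        assert structural_distance(_sup(2.0, 50, 100)) == pytest.approx(4.0)

    def test_unknown_metric_rejected(self):
        with pytest.raises(ValueError):
            structural_distance(_sup(1.0, 10, 10), metric="dali")

    def test_directional_symmetry_on_random_pairs(self):
        rng = np.random.default_rng(3)
        for s in range(5):
            a = ca_trace(40, seed=s)
            b = perturb(a, PerturbationTruth(random_rotation(rng),
                                             rng.normal(0, 5, 3),
                                             noise_sigma=0.8), seed=s)
            d_ab = structural_distance(iterative_core_superpose(
                a, b, seed_alignment(a, b, "index")))
            d_ba = structural_distance(iterative_core_superpose(
                b, a, seed_alignment(b, a, "index")))
            assert d_ab == pytest.approx(d_ba, abs=1e-6)


class TestDistanceMatrixType:
    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["a", "b"], np.array([[0, 1], [2, 0.0]]))

    def test_nonzero_diagonal_rejected(self):
        with pytest.raises(ValueError, match="diagonal"):
            DistanceMatrix(["a", "b"], np.array([[1, 1], [1, 0.0]]))

    def test_tsv_roundtrip(self, tmp_path):
        m = make_additive_matrix("((A:1,B:2):1,(C:3,D:1):2);")
        path = tmp_path / "m.tsv"
        m.to_tsv(path)
        back = DistanceMatrix.from_tsv(path)
        assert back.labels == m.labels
        np.testing.assert_allclose(back.d, m.d, atol=1e-6)


class TestNJ:
    def test_three_taxon_closed_form(self):
        m = DistanceMatrix(["A", "B", "C"],
                           np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0.0]]))
        tree = nj_tree(m)
        lengths = {t.name: t.length for t in tree.root.tips()}
        assert lengths == {"A": pytest.approx(1.0), "B": pytest.approx(1.0),
                           "C": pytest.approx(3.0)}

    def test_exact_recovery_of_known_tree(self):
        m = make_additive_matrix("((A:1,B:2):1,(C:3,D:1):2);")
        tree = nj_tree(m)
        td = tree.tip_distances()
        idx = [td.labels.index(l) for l in m.labels]
        np.testing.assert_allclose(td.d[np.ix_(idx, idx)], m.d, atol=1e-9)
        # topology: {A,B}|{C,D} is the single non-trivial split
        assert tree.is_monophyletic({"A", "B"})
        assert not tree.is_monophyletic({"A", "C"})

    def test_exact_recovery_50_random_additive_matrices(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = int(rng.integers(5, 11))
            m = make_additive_matrix(random_additive_tree(n, rng))
            td = nj_tree(m).tip_distances()
            idx = [td.labels.index(l) for l in m.labels]
            np.testing.assert_allclose(td.d[np.ix_(idx, idx)], m.d, atol=1e-6)

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(13)
        m = make_additive_matrix(random_additive_tree(7, rng))
        perm = rng.permutation(len(m.labels))
        m2 = DistanceMatrix([m.labels[i] for i in perm],
                            m.d[np.ix_(perm, perm)], m.metric)
        t1, t2 = nj_tree(m), nj_tree(m2)
        assert t1.bipartitions() == t2.bipartitions()
        d1, d2 = t1.tip_distances(), t2.tip_distances()
        idx = [d2.labels.index(l) for l in d1.labels]
        np.testing.assert_allclose(d1.d, d2.d[np.ix_(idx, idx)], atol=1e-9)

    def test_negative_branches_clamped_and_logged(self):
        # strongly non-additive matrix forces a negative NJ branch estimate
        m = DistanceMatrix(["a", "b", "c", "d"],
                           np.array([[0, 1, 9, 9], [1, 0, 9, 1],
                                     [9, 9, 0, 9], [9, 1, 9, 0.0]]))
        tree = nj_tree(m)
        assert all((t.length or 0) >= 0 for t in tree.root.traverse())
        assert tree.clamped_deficit > 0

    def test_fewer_than_three_labels_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["a", "b"], np.array([[0, 1], [1, 0.0]])))

    def test_agrees_with_skbio_nj_topology(self):
        # independent implementation cross-check on a random additive matrix
        import skbio
        from skbio.tree import nj as skbio_nj
        rng = np.random.default_rng(17)
        m = make_additive_matrix(random_additive_tree(8, rng))
        ours = nj_tree(m)
        theirs = skbio_nj(skbio.DistanceMatrix(m.d, ids=m.labels))
        td = theirs.tip_tip_distances()
        order = list(td.ids)
        idx = [order.index(l) for l in m.labels]
        np.testing.assert_allclose(np.asarray(td.data)[np.ix_(idx, idx)],
                                   ours.tip_distances().d, atol=1e-6)


class TestBuildMatrix:
    def test_three_copies_zero_matrix(self):
        base = ca_trace(40, seed=2)
        m = build_matrix([("x", base), ("y", base), ("z", base)],
                         seed_mode="index")
        np.testing.assert_allclose(m.d, 0.0, atol=1e-9)

    def test_distances_increase_with_noise(self):
        base = ca_trace(50, seed=6)
        entries = [("ref", base)]
        for i, sigma in enumerate([0.3, 0.7, 1.2]):
            entries.append((f"n{sigma}", perturb(
                base, PerturbationTruth(noise_sigma=sigma), seed=i)))
        m = build_matrix(entries, seed_mode="index")
        d_ref = [m[("ref", lab)] for lab, _ in entries[1:]]
        assert d_ref == sorted(d_ref)
        assert d_ref[0] > 0

    def test_pair_without_core_names_the_pair(self):
        a = ca_trace(30, seed=31)
        b = ca_trace(30, seed=32)
        c = perturb(ca_trace(30, seed=33), PerturbationTruth(noise_sigma=40.0), seed=0)
        with pytest.raises(ValueError, match="far"):
            build_matrix([("far", c), ("a", a), ("b", b)], seed_mode="index")


class TestNewick:
    def test_three_taxon_serialization(self):
        m = DistanceMatrix(["A", "B", "C"],
                           np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0.0]]))
        assert to_newick(nj_tree(m)) == "(A:1,B:1,C:3);"

    def test_roundtrip_topology_and_lengths(self):
        rng = np.random.default_rng(23)
        tree = nj_tree(make_additive_matrix(random_additive_tree(7, rng)))
        back = from_newick(to_newick(tree))
        assert back.bipartitions() == tree.bipartitions()
        d1, d2 = tree.tip_distances(), back.tip_distances()
        idx = [d2.labels.index(l) for l in d1.labels]
        np.testing.assert_allclose(d1.d, d2.d[np.ix_(idx, idx)], rtol=1e-4)

    def test_single_cherry_rejected(self):
        with pytest.raises(ValueError, match="leaves"):
            from_newick("(A:1,B:1);")
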