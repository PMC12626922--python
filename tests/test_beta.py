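import itertools

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.distance import anosim as skbio_anosim
from skbio.stats.distance import permanova as skbio_permanova

from rhizonet import (
    abund_jaccard,
    anosim,
    distance_matrix,
    pcoa,
    permanova,
    unweighted_unifrac,
)
from rhizonet.io import read_newick
from ._oracles import brute_anosim_r, brute_permanova_f, brute_unifrac

FOUR_LEAF = "((A:1,B:1):1,(C:1,D:1):1);"


class TestAbundJaccard:
    def test_identity_and_disjoint(self):
        assert abund_jaccard([1, 2, 3], [1, 2, 3]) == 0.0
        assert abund_jaccard([1, 0, 2], [0, 3, 0]) == 1.0

    def test_hand_example(self):
        assert abund_jaccard([2, 0, 1], [1, 1, 1]) == pytest.approx(0.5)

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            abund_jaccard([0, 0], [0, 0])

    def test_range_and_symmetry(self, rng):
        for _ in range(50):
            x = rng.integers(0, 20, 10)
            y = rng.integers(0, 20, 10)
            if x.sum() == 0 and y.sum() == 0:
                continue
            d = abund_jaccard(x, y)
            assert 0 <= d <= 1
            assert d == pytest.approx(abund_jaccard(y, x))

    def test_chao_variant_identity_and_disjoint(self):
        assert abund_jaccard([3, 2, 1], [3, 2, 1], variant="chao") == pytest.approx(0.0)
        assert abund_jaccard([3, 0], [0, 5], variant="chao") == 1.0


class TestUnweightedUnifrac:
    def test_identical_sets_are_zero(self):
        tree = read_newick(FOUR_LEAF)
        assert unweighted_unifrac(tree, {"A", "B"}, {"A", "B"}) == 0.0

    def test_fully_distinct_clades(self):
        tree = read_newick(FOUR_LEAF)
        assert unweighted_unifrac(tree, {"A", "B"}, {"C", "D"}) == pytest.approx(1.0)

    def test_partial_overlap_worked_value(self):
        # unique = branches to C and its stem = 2; total below root = 6
        tree = read_newick(FOUR_LEAF)
        assert unweighted_unifrac(tree, {"A", "B"}, {"A", "B", "C"}) == pytest.approx(1 / 3)

    def test_matches_brute_force_branch_tally(self, rng):
        tree_str = "(((A:2,B:1):1,(C:1,D:3):2):1,(E:1,F:2):3);"
        tree = read_newick(tree_str)
        leaves = list("ABCDEF")
        for _ in range(30):
            a = {l for l in leaves if rng.random() < 0.5}
            b = {l for l in leaves if rng.random() < 0.5}
            if not a or not b:
                continue
            assert unweighted_unifrac(tree, a, b) == pytest.approx(
                brute_unifrac(tree_str, a, b)
            )

    def test_missing_taxon_strict_vs_lenient(self):
        tree = read_newick(FOUR_LEAF)
        with pytest.raises(ValueError, match="absent"):
            unweighted_unifrac(tree, {"A", "Z"}, {"B"})
        with pytest.warns(UserWarning, match="pruning"):
            d = unweighted_unifrac(tree, {"A", "Z"}, {"B"}, mode="lenient")
        assert 0 <= d <= 1

    def test_agrees_with_skbio_when_all_taxa_present(self):
        # conventions coincide when the union covers every leaf
        from skbio.diversity.beta import unweighted_unifrac as skbio_uu

        tree = read_newick(FOUR_LEAF)
        ours = unweighted_unifrac(tree, {"A", "B", "C"}, {"C", "D"})
        theirs = skbio_uu(
            [1, 1, 1, 0], [0, 0, 1, 1], taxa=list("ABCD"), tree=tree
        )
        assert ours == pytest.approx(theirs)


class TestPCoA:
    def test_collinear_points_single_axis(self):
        D = DistanceMatrix(
            [[0, 1, 2], [1, 0, 1], [2, 1, 0]], ["a", "b", "c"]
        )
        res = pcoa(D)
        assert res.coordinates.shape[1] == 1
        d_ab = abs(res.coordinates.iloc[0, 0] - res.coordinates.iloc[1, 0])
        assert d_ab == pytest.approx(1.0)

    def test_unit_square_two_equal_leading_eigenvalues(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        D = DistanceMatrix(squareform(pdist(pts)), list("abcd"))
        res = pcoa(D)
        assert res.eigenvalues[0] == pytest.approx(res.eigenvalues[1])

    def test_euclidean_distances_reconstructed(self, rng):
        pts = rng.normal(size=(8, 3))
        D = squareform(pdist(pts))
        res = pcoa(DistanceMatrix(D, [str(i) for i in range(8)]))
        coords = res.coordinates.to_numpy()
        rec = squareform(pdist(coords))
        assert np.allclose(rec, D, atol=1e-8)

    def test_matches_skbio_eigenvalues(self, rng):
        from skbio.stats.ordination import pcoa as skbio_pcoa

        pts = rng.normal(size=(7, 4))
        dm = DistanceMatrix(squareform(pdist(pts)), [str(i) for i in range(7)])
        ours = pcoa(dm)
        theirs = skbio_pcoa(dm, number_of_dimensions=0)
        np.testing.assert_allclose(
            ours.eigenvalues[:4], theirs.eigvals.to_numpy()[:4], atol=1e-8
        )

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            pcoa(DistanceMatrix([[0, 1], [1, 0]], ["a", "b"]))


def _four_sample_dm():
    # within-group distance 1, cross-group distance 2
    D = np.full((4, 4), 2.0)
    np.fill_diagonal(D, 0.0)
    D[0, 1] = D[1, 0] = 1.0
    D[2, 3] = D[3, 2] = 1.0
    return DistanceMatrix(D, ["a", "b", "c", "d"])


class TestPermanova:
    def test_worked_pseudo_f(self):
        res = permanova(_four_sample_dm(), ["g1", "g1", "g2", "g2"], n_perm=99, seed=0)
        assert res.statistic == pytest.approx(7.0)

    def test_statistic_matches_brute_force(self, rng):
        pts = rng.normal(size=(9, 3))
        D = squareform(pdist(pts))
        dm = DistanceMatrix(D, [str(i) for i in range(9)])
        labels = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        res = permanova(dm, labels, n_perm=9, seed=0)
        assert res.statistic == pytest.approx(brute_permanova_f(D, labels), abs=1e-10)

    def test_statistic_matches_skbio(self, rng):
        pts = rng.normal(size=(10, 3))
        dm = DistanceMatrix(squareform(pdist(pts)), [str(i) for i in range(10)])
        labels = ["a"] * 5 + ["b"] * 5
        ours = permanova(dm, labels, n_perm=9, seed=0)
        theirs = skbio_permanova(dm, labels, permutations=9)
        assert ours.statistic == pytest.approx(theirs["test statistic"])

    def test_p_value_never_zero_and_floor(self):
        res = permanova(_four_sample_dm(), ["g1", "g1", "g2", "g2"], n_perm=999, seed=1)
        assert res.p_value >= 1 / 1000
        assert 0 < res.p_value <= 1

    def test_exhaustive_agrees_with_monte_carlo(self, rng):
        pts = rng.normal(size=(8, 2))
        pts[:4] += 1.5
        dm = DistanceMatrix(squareform(pdist(pts)), [str(i) for i in range(8)])
        labels = ["a"] * 4 + ["b"] * 4
        exact = permanova(dm, labels, exhaustive=True)
        mc = permanova(dm, labels, n_perm=20000, seed=3)
        assert mc.p_value == pytest.approx(exact.p_value, abs=0.02)

    def test_null_calibration(self, rng):
        # random labels vs structureless distances: p roughly uniform
        ps = []
        for _ in range(60):
            pts = rng.normal(size=(12, 3))
            dm = DistanceMatrix(squareform(pdist(pts)), [str(i) for i in range(12)])
            labels = rng.permutation(["a"] * 6 + ["b"] * 6)
            ps.append(permanova(dm, labels, n_perm=199, seed=int(rng.integers(2**31))).p_value)
        assert 0.2 < np.mean(ps) < 0.8

    def test_singleton_group_rejected(self):
        with pytest.raises(ValueError, match="singleton"):
            permanova(_four_sample_dm(), ["g1", "g2", "g2", "g2"], n_perm=9, seed=0)


class TestAnosim:
    def test_perfect_separation_gives_r_one(self):
        res = anosim(_four_sample_dm(), ["g1", "g1", "g2", "g2"], n_perm=99, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_statistic_matches_brute_force(self, rng):
        pts = rng.normal(size=(8, 3))
        D = squareform(pdist(pts))
        dm = DistanceMatrix(D, [str(i) for i in range(8)])
        labels = ["a"] * 4 + ["b"] * 4
        res = anosim(dm, labels, n_perm=9, seed=0)
        assert res.statistic == pytest.approx(brute_anosim_r(D, labels), abs=1e-10)

    def test_statistic_matches_skbio(self, rng):
        pts = rng.normal(size=(10, 2))
        dm = DistanceMatrix(squareform(pdist(pts)), [str(i) for i in range(10)])
        labels = ["a"] * 5 + ["b"] * 5
        ours = anosim(dm, labels, n_perm=9, seed=0)
        theirs = skbio_anosim(dm, labels, permutations=9)
        assert ours.statistic == pytest.approx(theirs["test statistic"])

    def test_null_mean_r_near_zero(self, rng):
        rs = []
        for _ in range(40):
            pts = rng.normal(size=(10, 3))
            dm = DistanceMatrix(squareform(pdist(pts)), [str(i) for i in range(10)])
            labels = rng.permutation(["a"] * 5 + ["b"] * 5)
            rs.append(anosim(dm, labels, n_perm=9, seed=0).statistic)
        assert abs(np.mean(rs)) < 0.15


class TestDistanceMatrixBuilder:
    def test_properties_on_feature_table(self, small_table):
        dm = distance_matrix(small_table, metric="abund_jaccard")
        D = dm.data
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0)
        assert ((D >= 0) & (D <= 1)).all()

    def test_unifrac_requires_tree(self, small_table):
        with pytest.raises(ValueError, match="tree"):
            distance_matrix(small_table, metric="unifrac")
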