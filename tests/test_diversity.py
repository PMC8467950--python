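import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.spatial import procrustes
from scipy.spatial.distance import pdist, squareform

from guildflow import (
    CountTable,
    DistanceMatrix,
    PhyloTree,
    compare_groups,
    group_dissimilarity,
    nmds,
    permanova,
    shannon,
    simulate_tree,
    weighted_unifrac,
)

from ._oracles import permanova_exhaustive_p, permanova_f


class TestShannon:
    def test_uniform_counts_give_log_richness(self):
        t = CountTable(["s"], [f"f{i}" for i in range(8)], np.full((1, 8), 7))
        assert shannon(t, 2).iloc[0] == pytest.approx(3.0, abs=1e-12)

    def test_single_feature_zero_entropy(self):
        t = CountTable(["s"], ["a", "b"], np.array([[9, 0]]))
        assert shannon(t).iloc[0] == 0.0

    def test_hand_computed_value(self):
        t = CountTable(["s"], ["a", "b", "c"], np.array([[1, 1, 2]]))
        assert shannon(t, 2).iloc[0] == pytest.approx(1.5, abs=1e-12)

    @given(st.lists(st.integers(min_value=1, max_value=50), min_size=2, max_size=8))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_maximal_at_uniform(self, counts):
        k = len(counts)
        t = CountTable(["s", "u"], [f"f{i}" for i in range(k)], np.vstack([counts, np.full(k, 10)]))
        h = shannon(t, 2)
        assert h.iloc[0] <= h.iloc[1] + 1e-9


class TestWeightedUnifrac:
    def test_two_leaf_hand_values(self):
        tree = PhyloTree.from_newick("(a:1,b:1);")
        t = CountTable(["A", "B"], ["a", "b"], np.array([[10, 0], [0, 5]]))
        assert weighted_unifrac(t, tree).d[0, 1] == pytest.approx(2.0, abs=1e-12)
        assert weighted_unifrac(t, tree, "normalized").d[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_three_leaf_hand_value(self):
        # branches: a:1 |1-0|, b:2 |0-0|, (ab):1 |1-0|, c:3 |0-1| -> 1+0+1+3
        tree = PhyloTree.from_newick("((a:1,b:2):1,c:3);")
        t = CountTable(["A", "B"], ["a", "b", "c"], np.array([[7, 0, 0], [0, 0, 3]]))
        assert weighted_unifrac(t, tree).d[0, 1] == pytest.approx(5.0, abs=1e-12)

    def test_identical_samples_zero(self):
        tree = PhyloTree.from_newick("(a:1,b:1);")
        t = CountTable(["A", "B"], ["a", "b"], np.array([[3, 4], [3, 4]]))
        assert weighted_unifrac(t, tree).d[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_metric_axioms_random_instances(self):
        rng = np.random.default_rng(0)
        tree = simulate_tree(12, seed=4)
        ids = tree.leaf_names
        counts = rng.integers(0, 40, size=(6, 12))
        counts[counts.sum(axis=1) == 0, 0] = 1
        t = CountTable([f"s{i}" for i in range(6)], ids, counts)
        d = weighted_unifrac(t, tree).d
        assert np.allclose(d, d.T)
        assert (d >= 0).all()
        for i in range(6):
            for j in range(6):
                for k in range(6):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-9

    def test_scaling_invariance(self):
        tree = simulate_tree(5, seed=1)
        rng = np.random.default_rng(2)
        counts = rng.integers(1, 30, size=(3, 5))
        t1 = CountTable(["x", "y", "z"], tree.leaf_names, counts)
        scaled = counts.copy()
        scaled[0] *= 7  # relative profile unchanged
        t2 = CountTable(["x", "y", "z"], tree.leaf_names, scaled)
        np.testing.assert_allclose(weighted_unifrac(t1, tree).d, weighted_unifrac(t2, tree).d, atol=1e-12)

    def test_missing_feature_rejected(self):
        tree = PhyloTree.from_newick("(a:1,b:1);")
        t = CountTable(["A"], ["a", "zzz"], np.array([[1, 1]]))
        with pytest.raises(ValueError, match="zzz"):
            weighted_unifrac(t, tree)


class TestNmds:
    def test_recovers_planar_configuration(self):
        rng = np.random.default_rng(42)
        X = rng.normal(size=(10, 2))
        d = DistanceMatrix([f"p{i}" for i in range(10)], squareform(pdist(X)))
        res = nmds(d, k=2, seed=0)
        assert res.stress < 0.01
        _, _, disparity = procrustes(X, res.coordinates.to_numpy())
        assert disparity < 1e-2

    def test_equilateral_triangle(self):
        d = DistanceMatrix(["a", "b", "c"], np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], float))
        assert nmds(d, k=2, seed=0).stress < 1e-3

    def test_too_few_items(self):
        d = DistanceMatrix(["a", "b"], np.array([[0, 1], [1, 0]], float))
        with pytest.raises(ValueError):
            nmds(d, k=2)


class TestPermanova:
    def test_perfect_separation_exhaustive(self):
        d = np.ones((6, 6)) - np.eye(6)
        d[:3, :3] = 0
        d[3:, 3:] = 0
        np.fill_diagonal(d, 0)
        res = permanova(DistanceMatrix([f"i{i}" for i in range(6)], d), ["x"] * 3 + ["y"] * 3)
        assert np.isinf(res.pseudo_f)
        assert res.exhaustive
        assert res.p_value == pytest.approx(1 / 10)

    def test_exhaustive_matches_independent_enumeration(self, tiny_counts):
        from .conftest import random_distance_matrix

        rng = np.random.default_rng(9)
        labels = np.array(["a", "a", "b", "b"])
        for _ in range(5):
            d = random_distance_matrix(rng, 4)
            res = permanova(d, labels)
            assert res.exhaustive
            assert res.p_value == pytest.approx(permanova_exhaustive_p(d, labels), abs=1e-12)
            assert res.pseudo_f == pytest.approx(permanova_f(d, labels), rel=1e-12)

    def test_sampled_p_converges_to_exhaustive(self):
        from .conftest import random_distance_matrix

        rng = np.random.default_rng(17)
        labels = np.array(["a", "a", "b", "b"])
        d = random_distance_matrix(rng, 4)
        exact = permanova(d, labels).p_value
        sampled = permanova(d, labels, n_perm=9999, seed=1, exhaustive_cap=0).p_value
        assert sampled == pytest.approx(exact, abs=0.03)

    def test_statistic_matches_skbio(self):
        from skbio.stats.distance import DistanceMatrix as SkbioDM
        from skbio.stats.distance import permanova as skbio_permanova
        from .conftest import random_distance_matrix

        rng = np.random.default_rng(3)
        d = random_distance_matrix(rng, 12)
        labels = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        ours = permanova(d, labels, n_perm=99, seed=0, exhaustive_cap=0)
        theirs = skbio_permanova(SkbioDM(d), grouping=labels, permutations=99)
        assert ours.pseudo_f == pytest.approx(theirs["test statistic"], rel=1e-9)

    def test_residual_dof_zero_rejected(self):
        d = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], float)
        with pytest.raises(ValueError, match="degrees of freedom"):
            permanova(d, ["a", "b", "c"])


class TestCompareGroups:
    def test_identical_groups_not_significant(self):
        vals = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        groups = ["a"] * 3 + ["b"] * 3
        _, _, pairwise = compare_groups(vals, groups)
        assert (pairwise["p_adj"] > 0.99).all()

    def test_separated_groups_detected(self):
        vals = [1, 2, 3, 101, 102, 103, 201, 202, 203]
        groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        h, p, _ = compare_groups(vals, groups)
        # hand formula: H = 12/(9*10) * 3*(2^2+5^2+8^2 deviations) ... = 7.2
        assert h == pytest.approx(7.2, abs=1e-9)
        assert p < 0.05

    def test_dunn_z_matches_ranksum_normal_approx(self):
        rng = np.random.default_rng(11)
        x = rng.normal(0, 1, 8)
        y = rng.normal(1, 1, 8)
        _, _, pairwise = compare_groups(np.concatenate([x, y]), ["x"] * 8 + ["y"] * 8)
        n1 = n2 = 8
        N = 16
        ranks = stats.rankdata(np.concatenate([x, y]))
        w = ranks[:8].sum()
        z_rs = (w - n1 * (N + 1) / 2) / np.sqrt(n1 * n2 * (N + 1) / 12.0)
        assert abs(pairwise["z"].iloc[0]) == pytest.approx(abs(z_rs), rel=1e-9)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            compare_groups([1, 2, 3], ["a", "a", "b"])


class TestGroupDissimilarity:
    def _dm(self):
        rng = np.random.default_rng(0)
        from .conftest import random_distance_matrix

        return DistanceMatrix([f"s{i}" for i in range(7)], random_distance_matrix(rng, 7))

    def test_pair_count(self):
        labels = ["a"] * 3 + ["b"] * 4
        assert len(group_dissimilarity(self._dm(), labels, "a", "b")) == 12

    def test_same_group_rejected(self):
        with pytest.raises(ValueError, match="must differ"):
            group_dissimilarity(self._dm(), ["a"] * 7, "a", "a")

    def test_identical_samples_zero(self):
        d = DistanceMatrix(["s1", "s2"], np.zeros((2, 2)))
        out = group_dissimilarity(d, ["a", "b"], "a", "b")
        assert (out == 0).all()

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown group"):
            group_dissimilarity(self._dm(), ["a"] * 7, "a", "zzz")
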