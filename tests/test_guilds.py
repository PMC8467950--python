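import numpy as np
import pytest
from scipy import stats

from guildflow import (
    DistanceMatrix,
    SimConfig,
    coabundance_distance,
    delineate_guilds,
    simulate_community,
    to_relative,
    ward_linkage,
    within_subject_correlation,
)
from guildflow.core_io import AbundanceTable

from ._oracles import naive_ward_heights, within_subject_r


class TestWithinSubjectCorrelation:
    def test_single_subject_equals_plain_pearson(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=12), rng.normal(size=12)
        r = within_subject_correlation(x, y, np.zeros(12))
        assert r == pytest.approx(stats.pearsonr(x, y)[0], abs=1e-12)

    def test_subject_offsets_do_not_mask_linearity(self):
        x = np.array([1.0, 2, 3, 11, 12, 13, 21, 22, 23])
        y = 2 * x + np.repeat([5.0, -40.0, 100.0], 3)
        subjects = np.repeat(["m1", "m2", "m3"], 3)
        assert within_subject_correlation(x, y, subjects) == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_residual_correlation(self):
        x = np.array([1.0, 2, 3, 4, 5, 6])
        y = np.array([3.0, 1, 2, 6, 4, 5])
        subjects = np.repeat(["a", "b"], 3)
        assert within_subject_correlation(x, y, subjects) == pytest.approx(-0.5, abs=1e-12)

    def test_matches_centering_oracle_on_random_data(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n_sub = rng.integers(2, 6)
            reps = rng.integers(2, 5)
            subjects = np.repeat(np.arange(n_sub), reps)
            x = rng.normal(size=subjects.size)
            y = rng.normal(size=subjects.size)
            assert within_subject_correlation(x, y, subjects) == pytest.approx(
                within_subject_r(x, y, subjects), abs=1e-12
            )

    def test_zero_variance_returns_nan(self):
        x = np.array([1.0, 1, 1, 2, 2, 2])  # constant within each subject
        y = np.array([1.0, 2, 3, 4, 5, 6])
        assert np.isnan(within_subject_correlation(x, y, np.repeat(["a", "b"], 3)))


class TestCoabundanceDistance:
    def _table(self, values):
        n, p = values.shape
        rows = values / values.sum(axis=1, keepdims=True)
        return AbundanceTable([f"s{i}" for i in range(n)], [f"f{j}" for j in range(p)], rows, scale="relative")

    def test_entries_in_range_and_symmetric(self):
        rng = np.random.default_rng(2)
        a = self._table(rng.uniform(0.1, 1, size=(12, 6)))
        d = coabundance_distance(a, np.repeat(np.arange(4), 3))
        assert (d.d >= 0).all() and (d.d <= 2).all()
        assert np.allclose(d.d, d.d.T)
        assert np.all(np.diag(d.d) == 0)

    def test_anticorrelated_pair_distance_two(self):
        x = np.linspace(0.2, 0.4, 9)
        vals = np.column_stack([x, 0.9 - x])  # perfectly anti-correlated
        a = AbundanceTable([f"s{i}" for i in range(9)], ["u", "v", "w"], np.column_stack([vals, 0.1 * np.ones(9)]), scale="raw")
        d = coabundance_distance(a, np.repeat(np.arange(3), 3))
        assert d.d[0, 1] == pytest.approx(2.0, abs=1e-9)

    def test_constant_feature_gets_unit_distance_with_warning(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(0.1, 1, size=(9, 3))
        vals[:, 2] = 0.5
        a = AbundanceTable([f"s{i}" for i in range(9)], ["a", "b", "c"], vals, scale="raw")
        with pytest.warns(UserWarning, match="zero within-subject variance"):
            d = coabundance_distance(a, np.repeat(np.arange(3), 3))
        assert d.d[2, 0] == pytest.approx(1.0)
        assert d.d[2, 1] == pytest.approx(1.0)


class TestWardLinkage:
    def test_closest_pair_merges_first(self):
        d = np.array(
            [[0, 0.0, 0.9, 0.8], [0.0, 0, 0.7, 0.9], [0.9, 0.7, 0, 0.6], [0.8, 0.9, 0.6, 0]], float
        )
        dendro = ward_linkage(DistanceMatrix(["a", "b", "c", "d"], d))
        assert set(dendro.linkage[0, :2].astype(int)) == {0, 1}

    def test_two_tight_pairs_form_root_children(self):
        d = np.full((4, 4), 1.0)
        d[0, 1] = d[1, 0] = 0.1
        d[2, 3] = d[3, 2] = 0.1
        np.fill_diagonal(d, 0)
        dendro = ward_linkage(DistanceMatrix(["a", "b", "c", "d"], d))
        first_two = {frozenset(dendro.linkage[0, :2].astype(int)), frozenset(dendro.linkage[1, :2].astype(int))}
        assert first_two == {frozenset({0, 1}), frozenset({2, 3})}

    def test_heights_match_naive_reference(self):
        from .conftest import random_distance_matrix

        rng = np.random.default_rng(7)
        for _ in range(10):
            d = random_distance_matrix(rng, 6)
            dendro = ward_linkage(DistanceMatrix([f"f{i}" for i in range(6)], d))
            np.testing.assert_allclose(np.sort(dendro.heights), np.sort(naive_ward_heights(d)), atol=1e-9)

    def test_newick_export_contains_all_leaves(self):
        from .conftest import random_distance_matrix

        rng = np.random.default_rng(8)
        ids = [f"f{i}" for i in range(5)]
        nwk = ward_linkage(DistanceMatrix(ids, random_distance_matrix(rng, 5))).to_newick()
        assert all(i in nwk for i in ids)
        assert nwk.endswith(";")


def _block_distance(sizes, within, between, rng=None):
    n = sum(sizes)
    d = np.full((n, n), between, dtype=float)
    start = 0
    for s in sizes:
        d[start : start + s, start : start + s] = within
        start += s
    if rng is not None:  # jitter to break exact ties
        noise = rng.uniform(0, 0.01, size=(n, n))
        d += (noise + noise.T) / 2
    np.fill_diagonal(d, 0)
    return d


class TestDelineateGuilds:
    def test_two_perfect_blocks_yield_two_guilds(self):
        rng = np.random.default_rng(0)
        d = _block_distance([8, 8], 0.05, 1.9, rng)
        ids = [f"f{i}" for i in range(16)]
        dm = DistanceMatrix(ids, d)
        assignment = delineate_guilds(ward_linkage(dm), dm, seed=1)
        assert assignment.n_guilds == 2
        blocks = {frozenset(assignment.members(g)) for g in assignment.guild_ids}
        assert blocks == {frozenset(ids[:8]), frozenset(ids[8:])}

    def test_split_records_justify_boundaries(self):
        rng = np.random.default_rng(4)
        d = _block_distance([6, 6, 6], 0.05, 1.9, rng)
        ids = [f"f{i}" for i in range(18)]
        dm = DistanceMatrix(ids, d)
        assignment = delineate_guilds(ward_linkage(dm), dm, seed=2)
        accepted = [s for s in assignment.splits if s.split]
        assert all(s.p_value < assignment.alpha for s in accepted)
        assert assignment.n_guilds == len(accepted) + 1

    def test_guild_count_monotone_in_alpha(self):
        rng = np.random.default_rng(5)
        cfg = SimConfig(n_groups=2, mice_per_group=5, n_asvs=20, n_guilds=3, library_size_range=(2000, 3000), rng_seed=3)
        table, _ = simulate_community(cfg)
        rel = to_relative(table)
        subjects = [s.rsplit("_", 1)[0] for s in table.sample_ids]
        dist = coabundance_distance(rel, np.asarray(subjects))
        dendro = ward_linkage(dist)
        loose = delineate_guilds(dendro, dist, n_perm=999, alpha=0.05, seed=6)
        strict = delineate_guilds(dendro, dist, n_perm=999, alpha=0.001, seed=6)
        assert strict.n_guilds <= loose.n_guilds

    def test_deterministic_under_fixed_seed(self):
        rng = np.random.default_rng(6)
        d = _block_distance([5, 5, 5], 0.2, 1.5, rng)
        dm = DistanceMatrix([f"f{i}" for i in range(15)], d)
        dendro = ward_linkage(dm)
        a = delineate_guilds(dendro, dm, n_perm=999, seed=42)
        b = delineate_guilds(dendro, dm, n_perm=999, seed=42)
        assert a.guild_of == b.guild_of
        assert [s.p_value for s in a.splits] == [s.p_value for s in b.splits]

    def test_homogeneous_distances_yield_single_guild(self):
        """With all pairwise distances i.i.d. from one distribution, the
        recursion cannot certify any split at alpha = 0.001: at 12 items
        every clade's null is enumerated exactly and the smallest
        attainable p exceeds alpha, so one guild results every time."""
        from .conftest import random_distance_matrix

        for seed in range(100):
            rng = np.random.default_rng(seed)
            dm = DistanceMatrix([f"f{i}" for i in range(12)], random_distance_matrix(rng, 12, 0.9, 1.1))
            assignment = delineate_guilds(ward_linkage(dm), dm, n_perm=9999, alpha=0.001, seed=seed)
            if assignment.n_guilds != 1:
                pytest.fail(f"seed {seed}: {assignment.n_guilds} guilds from homogeneous distances")

    def test_small_clades_are_atomic(self):
        rng = np.random.default_rng(7)
        from .conftest import random_distance_matrix

        dm = DistanceMatrix(["a", "b"], random_distance_matrix(rng, 2))
        assignment = delineate_guilds(ward_linkage(dm), dm, seed=0)
        assert assignment.n_guilds == 1
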