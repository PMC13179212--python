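import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import to_tree
from scipy.spatial.distance import squareform

from reeffd import (
    bray_curtis,
    expand_traits,
    permanova,
    primary_split_depth,
    simprof,
    simprof_test,
    trait_frequency_profiles,
    ward_dendrogram,
)
from reeffd.distances import DistanceMatrix
from reeffd.fd_metrics import Community
from reeffd.trait_coding import TraitTable

from oracles import bray_curtis_brute, ward_heights_lw


def block_profiles(rng, n1=6, n2=6, k=10):
    """Two groups of rows using disjoint halves of the columns."""
    X = np.zeros((n1 + n2, k))
    X[:n1, : k // 2] = rng.uniform(1, 2, size=(n1, k // 2))
    X[n1:, k // 2 :] = rng.uniform(1, 2, size=(n2, k - k // 2))
    return pd.DataFrame(X, index=[float(i * 10) for i in range(n1 + n2)])


class TestTraitFrequencyProfiles:
    def test_single_species_one_hot(self, small_fixture):
        table, obs, _ = small_fixture
        bm = expand_traits(table)
        c = Community(site="A", depth_bin=0.0, abundances={"sp1": 2.0})
        prof = trait_frequency_profiles([c], bm)
        assert np.allclose(prof.iloc[0].to_numpy(), bm.data.loc["sp1"].to_numpy())

    def test_equal_abundance_split_category(self):
        table = TraitTable(
            schema={"t": ("a", "b")},
            assignments={
                "x": {"t": frozenset(["a"])},
                "y": {"t": frozenset(["b"])},
            },
        )
        bm = expand_traits(table)
        c = Community(site="A", depth_bin=0.0, abundances={"x": 3.0, "y": 3.0})
        prof = trait_frequency_profiles([c], bm)
        assert prof.iloc[0][("t", "a")] == pytest.approx(0.5)

    def test_full_schema_has_32_columns(self, small_survey):
        _, table, obs, _ = small_survey
        from reeffd import bin_depths

        bm = expand_traits(table)
        prof = trait_frequency_profiles(bin_depths(obs), bm)
        assert prof.shape[1] == 32

    def test_site_pooling_switch(self, small_survey):
        _, table, obs, _ = small_survey
        from reeffd import bin_depths

        bm = expand_traits(table)
        communities = bin_depths(obs)
        pooled = trait_frequency_profiles(communities, bm, pool_sites=True)
        by_site = trait_frequency_profiles(communities, bm, pool_sites=False)
        assert len(by_site) > len(pooled)


class TestBrayCurtis:
    def test_identical_rows_zero_disjoint_one(self):
        prof = pd.DataFrame([[1.0, 2.0, 0], [1.0, 2.0, 0], [0, 0, 5.0]])
        d = bray_curtis(prof)
        assert d.values[0, 1] == pytest.approx(0.0)
        assert d.values[0, 2] == pytest.approx(1.0)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(2)
        prof = pd.DataFrame(rng.uniform(0, 3, size=(5, 7)))
        d = bray_curtis(prof)
        for i in range(5):
            for j in range(5):
                assert d.values[i, j] == pytest.approx(
                    bray_curtis_brute(prof.iloc[i], prof.iloc[j]), abs=1e-12
                )

    def test_row_scaling_invariance(self):
        rng = np.random.default_rng(3)
        prof = pd.DataFrame(rng.uniform(0, 3, size=(4, 6)))
        d1 = bray_curtis(prof)
        d2 = bray_curtis(prof * 11.0)
        assert np.allclose(d1.values, d2.values)

    def test_all_zero_row_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            bray_curtis(pd.DataFrame([[0.0, 0.0], [1.0, 0.0]]))


class TestWard:
    def test_two_point_single_merge(self):
        d = DistanceMatrix(labels=["a", "b"], values=np.array([[0, 2.0], [2.0, 0]]))
        Z = ward_dendrogram(d)
        assert Z.shape == (1, 4)
        assert Z[0, 2] == pytest.approx(2.0)

    def test_heights_match_lance_williams_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            pts = rng.uniform(size=(7, 3))
            from scipy.spatial.distance import pdist

            v = squareform(pdist(pts, metric="cityblock"))
            d = DistanceMatrix(labels=[str(i) for i in range(7)], values=v)
            Z = ward_dendrogram(d)
            assert np.allclose(sorted(Z[:, 2]), sorted(ward_heights_lw(v)), atol=1e-10)

    def test_heights_non_decreasing(self):
        rng = np.random.default_rng(5)
        prof = pd.DataFrame(rng.uniform(0, 2, size=(10, 6)))
        Z = ward_dendrogram(bray_curtis(prof))
        assert (np.diff(Z[:, 2]) >= -1e-12).all()

    def test_separated_blocks_split_at_top(self):
        rng = np.random.default_rng(6)
        prof = block_profiles(rng)
        Z = ward_dendrogram(bray_curtis(prof))
        root = to_tree(Z)
        left = set(root.left.pre_order(lambda l: l.id))
        assert left in ({0, 1, 2, 3, 4, 5}, {6, 7, 8, 9, 10, 11})


class TestSimprof:
    def test_identical_rows_single_cluster_pi_zero(self):
        prof = pd.DataFrame(np.tile([1.0, 2.0, 3.0], (6, 1)),
                            index=[float(i) for i in range(6)])
        res = simprof(prof, alpha=0.05, n_expected=50, n_null=49, seed=0)
        assert len(res.clusters) == 1
        assert res.tests["pi"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_two_blocks_detected(self, seed):
        rng = np.random.default_rng(seed)
        prof = block_profiles(rng)
        res = simprof(prof, alpha=0.05, n_expected=200, n_null=199, seed=seed)
        root_split = [set(c) for c in res.clusters]
        # the two generated blocks must be separated (possibly further split)
        blocks = [set(prof.index[:6]), set(prof.index[6:])]
        for cluster in root_split:
            assert cluster <= blocks[0] or cluster <= blocks[1]
        assert len(res.clusters) >= 2

    def test_partition_invariant_to_row_order(self):
        rng = np.random.default_rng(7)
        prof = block_profiles(rng)
        res1 = simprof(prof, alpha=0.05, n_expected=100, n_null=99, seed=3)
        shuffled = prof.sample(frac=1.0, random_state=8)
        res2 = simprof(shuffled, alpha=0.05, n_expected=100, n_null=99, seed=3)
        part1 = {frozenset(c) for c in res1.clusters}
        part2 = {frozenset(c) for c in res2.clusters}
        assert part1 == part2

    def test_smaller_alpha_coarser_partition(self):
        rng = np.random.default_rng(9)
        base = block_profiles(rng, n1=5, n2=5)
        noise = rng.uniform(0, 0.4, size=base.shape)
        prof = base + noise
        k = {}
        for alpha in (0.5, 0.05, 1e-4):
            res = simprof(prof, alpha=alpha, n_expected=200, n_null=199, seed=1)
            k[alpha] = len(res.clusters)
        assert k[0.5] >= k[0.05] >= k[1e-4]

    def test_alpha_validation(self):
        prof = pd.DataFrame(np.eye(4))
        with pytest.raises(ValueError):
            simprof(prof, alpha=0.0)

    def test_primary_split_depth_on_blocks(self):
        rng = np.random.default_rng(10)
        prof = block_profiles(rng)  # break between bins 50 and 60
        res = simprof(prof, alpha=0.05, n_expected=100, n_null=99, seed=2)
        assert primary_split_depth(res) == pytest.approx(60.0)


class TestPermanova:
    def make_blocks(self, rng, shift=3.0):
        X = rng.normal(size=(16, 4))
        X[8:] += shift
        from scipy.spatial.distance import pdist

        v = squareform(pdist(X))
        d = DistanceMatrix(labels=[str(i) for i in range(16)], values=v)
        groups = ["a"] * 8 + ["b"] * 8
        return d, groups

    def test_clear_groups_significant(self):
        rng = np.random.default_rng(11)
        d, groups = self.make_blocks(rng)
        res = permanova(d, groups, n_perm=199, seed=0)
        assert res["p"] <= 0.01
        assert 0.0 <= res["R2"] <= 1.0

    def test_null_p_roughly_uniform(self):
        rng = np.random.default_rng(12)
        ps = []
        for _ in range(30):
            d, groups = self.make_blocks(rng, shift=0.0)
            ps.append(permanova(d, groups, n_perm=99, seed=1)["p"])
        assert 0.2 < np.mean(ps) < 0.8

    def test_agrees_with_skbio(self):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import permanova as sk_permanova

        rng = np.random.default_rng(13)
        d, groups = self.make_blocks(rng)
        mine = permanova(d, groups, n_perm=99, seed=0)
        ref = sk_permanova(skbio.DistanceMatrix(d.values, ids=d.labels),
                           grouping=groups, permutations=99)
        assert mine["F"] == pytest.approx(ref["test statistic"], rel=1e-10)

    def test_singleton_group_warns(self):
        rng = np.random.default_rng(14)
        d, groups = self.make_blocks(rng)
        groups = ["a"] + ["b"] * 15
        with pytest.warns(UserWarning, match="single member"):
            permanova(d, groups, n_perm=9, seed=0)
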