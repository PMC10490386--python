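import numpy as np
import pytest
from scipy.spatial.distance import squareform

from floregion import (
    DistanceMatrix,
    FloregionError,
    SiteAdjacency,
    assign_regions,
    ccc,
    cut_dendrogram,
    generate,
    gower_distance,
    harmonize,
    linkage,
    pairwise,
    select_k,
    select_method,
    silhouette,
)
from floregion.cluster import METHOD_ORDER, dendrogram_newick
from _oracles import upgma_by_hand


def _dm(vals, prefix="s"):
    n = vals.shape[0]
    return DistanceMatrix(tuple(f"{prefix}{i}" for i in range(n)), vals, "test")


@pytest.fixture
def three_site_dm():
    # d12=1, d13=4, d23=4
    return _dm(np.array([[0, 1, 4], [1, 0, 4], [4, 4, 0]], dtype=float))


class TestLinkage:
    def test_single_linkage_hand_merges(self, three_site_dm):
        res = linkage(three_site_dm, "single")
        np.testing.assert_allclose(np.sort(res.heights), [1.0, 4.0])

    def test_upgma_hand_merges(self, three_site_dm):
        res = linkage(three_site_dm, "UPGMA")
        np.testing.assert_allclose(np.sort(res.heights), [1.0, 4.0])  # (4+4)/2

    def test_all_equal_distances_merge_at_same_height(self):
        # holds for graph-based linkages and both Ward variants; centroid
        # methods genuinely shrink later merge heights below the common
        # distance (the Lance-Williams centroid update), as R hclust does too
        d = _dm(np.ones((5, 5)) - np.eye(5))
        for m in ("single", "complete", "UPGMA", "WPGMA"):
            res = linkage(d, m)
            np.testing.assert_allclose(res.heights, 1.0, atol=1e-12)
        for m in ("UPGMC", "WPGMC"):
            assert linkage(d, m).heights.max() <= 1.0 + 1e-12

    def test_matches_r_hclust_on_frozen_fixture(self):
        """Merge heights for all eight variants frozen from R 4.3.3:

            y <- c(...); d <- structure(y, Size=6L, class="dist")
            hclust(d, method=m)              # single..ward.D2
            sqrt(hclust(d^2, method=m)$height)  # centroid, median

        (R applies centroid/median to squared distances with squared
        heights; our UPGMC/WPGMC report heights on the distance scale.)
        """
        y = np.array([
            0.372, 0.8089, 0.3376, 0.5802, 0.9716, 1.0959, 0.374, 0.9038,
            1.1244, 0.9523, 0.3384, 0.5855, 0.6894, 0.9101, 0.6242,
        ])
        d = _dm(squareform(y))
        expected = {
            "single": [0.3376, 0.3384, 0.3720, 0.5802, 0.5855],
            "complete": [0.3376, 0.3384, 0.3740, 0.6242, 1.1244],
            "UPGMA": [0.3376, 0.3384, 0.3730, 0.60485, 0.8929555556],
            "WPGMA": [0.3376, 0.3384, 0.3730, 0.60485, 0.9557],
            "ward.D": [0.3376, 0.3384, 0.3848, 0.6936666667, 1.8016333333],
            "ward.D2": [0.3376, 0.3384, 0.3840773533, 0.6709091394, 1.4362369663],
            "UPGMC": [0.3326207450, 0.3376, 0.3384, 0.5810243584, 0.8292117991],
            "WPGMC": [0.3326207450, 0.3376, 0.3384, 0.5810243584, 0.8930495465],
        }
        for method, heights in expected.items():
            res = linkage(d, method)
            np.testing.assert_allclose(
                np.sort(res.heights), np.sort(heights), atol=1e-8, err_msg=method
            )

    def test_upgma_matches_naive_agglomeration(self):
        rng = np.random.default_rng(5)
        vals = squareform(rng.uniform(0.1, 1.0, size=45))
        d = _dm(vals)
        res = linkage(d, "UPGMA")
        heights, coph = upgma_by_hand(vals)
        np.testing.assert_allclose(np.sort(res.heights), np.sort(heights), rtol=1e-10)
        np.testing.assert_allclose(res.cophenetic.values, coph, rtol=1e-10)

    def test_unknown_method(self, three_site_dm):
        with pytest.raises(FloregionError, match="unknown linkage"):
            linkage(three_site_dm, "ward")

    def test_centroid_inversions_flagged_not_repaired(self):
        # classic inversion geometry: near-equilateral triangle
        pts = np.array([[0, 0], [1.0, 0], [0.5, 0.9]])
        from scipy.spatial.distance import pdist

        d = _dm(squareform(pdist(pts)))
        res = linkage(d, "UPGMC")
        assert res.has_inversions
        assert np.any(np.diff(res.heights) < 0)


class TestCophenetic:
    def test_read_off_three_site_merges(self, three_site_dm):
        res = linkage(three_site_dm, "single")
        np.testing.assert_allclose(
            np.sort(res.cophenetic.condensed()), [1.0, 4.0, 4.0]
        )

    def test_ultrametric_input_is_fixed_point_of_upgma(self, random_ultrametric):
        d = random_ultrametric(12, seed=3)
        res = linkage(d, "UPGMA")
        np.testing.assert_allclose(res.cophenetic.values, d.values, atol=1e-10)

    def test_cophenetic_is_ultrametric(self, random_ultrametric):
        rng = np.random.default_rng(0)
        d = _dm(squareform(rng.uniform(0.1, 1, size=45)))
        c = linkage(d, "UPGMA").cophenetic.values
        n = c.shape[0]
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert c[i, j] <= max(c[i, k], c[j, k]) + 1e-12


class TestFitScores:
    def test_identity_scores(self, three_site_dm):
        assert ccc(three_site_dm, three_site_dm) == pytest.approx(1.0)
        assert gower_distance(three_site_dm, three_site_dm) == 0.0

    def test_constant_shift(self):
        rng = np.random.default_rng(1)
        vals = squareform(rng.uniform(0.2, 1, size=10))
        d = _dm(vals)
        shifted = vals + 0.1
        np.fill_diagonal(shifted, 0.0)
        c = DistanceMatrix(d.site_ids, shifted, "shifted")
        assert ccc(d, c) == pytest.approx(1.0)
        assert gower_distance(d, c) == pytest.approx(0.01 * 10)

    def test_gd_nonnegative_for_all_methods(self, random_ultrametric):
        d = random_ultrametric(10, seed=5)
        for m in METHOD_ORDER:
            assert linkage(d, m).gd >= 0.0


class TestSelectMethod:
    def test_upgma_wins_on_its_own_fixed_point(self, random_ultrametric):
        d = random_ultrametric(15, seed=8)
        best, table, results = select_method(d)
        assert best == "UPGMA"
        assert results["UPGMA"].ccc == pytest.approx(1.0, abs=1e-10)
        assert results["UPGMA"].gd == pytest.approx(0.0, abs=1e-10)

    def test_table_schema(self, three_site_dm):
        _, table, _ = select_method(three_site_dm)
        assert list(table.columns) == ["CCC", "GD"]
        assert list(table.index) == list(METHOD_ORDER)

    def test_tie_broken_by_fixed_order(self):
        # all-equal distances: every method fits perfectly (CCC undefined,
        # GD = 0 for all) -> the fixed method order decides
        d = _dm(np.ones((4, 4)) - np.eye(4))
        best, table, results = select_method(d)
        assert best == METHOD_ORDER[0]
        assert all(np.isnan(results[m].ccc) for m in METHOD_ORDER)
        for m in ("single", "complete", "UPGMA", "WPGMA"):
            assert results[m].gd == pytest.approx(0.0)


class TestCutAndSilhouette:
    def test_cut_produces_exactly_k_nested_partitions(self, random_ultrametric):
        d = random_ultrametric(12, seed=2)
        res = linkage(d, "UPGMA")
        prev = None
        for k in range(2, 8):
            labels = cut_dendrogram(res, k)
            assert len(set(labels)) == k
            if prev is not None:
                # k-partition refines the (k-1)-partition
                for c in set(labels):
                    members = np.where(labels == c)[0]
                    assert len({prev[m] for m in members}) == 1
            prev = labels

    def test_two_separated_blocks_score_high(self):
        vals = np.full((8, 8), 1.0)
        vals[:4, :4] = 0.01
        vals[4:, 4:] = 0.01
        np.fill_diagonal(vals, 0.0)
        d = _dm(vals)
        widths, mean_s = silhouette(d, [0, 0, 0, 0, 1, 1, 1, 1])
        assert mean_s > 0.9

    def test_single_cluster_errors(self, three_site_dm):
        with pytest.raises(FloregionError):
            silhouette(three_site_dm, [0, 0, 0])

    def test_equidistant_site_scores_zero(self):
        vals = np.array(
            [
                [0.0, 0.2, 0.5, 0.5],
                [0.2, 0.0, 0.5, 0.5],
                [0.5, 0.5, 0.0, 0.2],
                [0.5, 0.5, 0.2, 0.0],
            ]
        )
        # site 0 at equal mean distance to own cluster {0,1} and cluster {2,3}
        vals[0, 1] = vals[1, 0] = 0.5
        d = _dm(vals)
        widths, _ = silhouette(d, [0, 0, 1, 1])
        assert widths[0] == pytest.approx(0.0)

    def test_singleton_cluster_scores_zero(self):
        rng = np.random.default_rng(2)
        vals = squareform(rng.uniform(0.1, 1, size=10))
        d = _dm(vals)
        widths, _ = silhouette(d, [0, 1, 1, 2, 2])
        assert widths[0] == 0.0

    def test_matches_sklearn_on_random_labels(self):
        from sklearn.metrics import silhouette_samples

        rng = np.random.default_rng(9)
        vals = squareform(rng.uniform(0.1, 1, size=66))
        d = _dm(vals)
        labels = rng.integers(0, 3, size=12)
        while len(set(labels.tolist())) < 3 or min(np.bincount(labels)) < 2:
            labels = rng.integers(0, 3, size=12)
        ours, _ = silhouette(d, labels)
        ref = silhouette_samples(vals, labels, metric="precomputed")
        np.testing.assert_allclose(ours, ref, atol=1e-12)


class TestSelectK:
    def test_recovers_two_blocks(self):
        vals = np.full((10, 10), 1.0)
        vals[:5, :5] = 0.05
        vals[5:, 5:] = 0.05
        np.fill_diagonal(vals, 0.0)
        d = _dm(vals + squareform(np.random.default_rng(0).uniform(0, 0.01, 45)))
        res = linkage(d, "UPGMA")
        k, curve = select_k(res, d)
        assert k == 2
        assert len(curve) == min(15, 10 - 1) - 2 + 1

    def test_recovers_planted_four_regions(self, strong_scenario):
        tree, mat, truth = generate(strong_scenario)
        tree, mat, _ = harmonize(tree, mat)
        d = pairwise(mat, "pbeta_sim", tree)
        res = linkage(d, "UPGMA")
        k, _ = select_k(res, d)
        assert k == 4

    def test_invalid_range(self, three_site_dm):
        res = linkage(three_site_dm, "UPGMA")
        with pytest.raises(FloregionError):
            select_k(res, three_site_dm, k_min=2, k_max=5)


class TestAssignRegions:
    def test_k2_realm_equals_region_partition(self, random_ultrametric):
        d = random_ultrametric(8, seed=1)
        res = linkage(d, "UPGMA")
        asg = assign_regions(res, d, 2)
        groups_r = {s: asg.regions[s] for s in asg.site_ids}
        groups_m = {s: asg.realms[s] for s in asg.site_ids}
        part = lambda g: {
            frozenset(s for s in g if g[s] == v) for v in set(g.values())
        }
        assert part(groups_r) == part(groups_m)

    def test_regions_nest_inside_realms(self, strong_scenario):
        tree, mat, truth = generate(strong_scenario)
        tree, mat, _ = harmonize(tree, mat)
        d = pairwise(mat, "pbeta_sim", tree)
        res = linkage(d, "UPGMA")
        asg = assign_regions(res, d, 4)
        for s in asg.site_ids:
            assert asg.realm_of_region[asg.regions[s]] == asg.realms[s]

    def test_noncontiguous_region_counted(self, random_ultrametric):
        d = random_ultrametric(6, seed=4)
        res = linkage(d, "UPGMA")
        asg0 = assign_regions(res, d, 2)
        # build an adjacency that splits one region into two islands
        regions = {}
        for s in asg0.site_ids:
            regions.setdefault(asg0.regions[s], []).append(s)
        big = max(regions.values(), key=len)
        pairs = []
        # chain everything except one site of the big region, left isolated
        chain = [s for s in asg0.site_ids if s != big[0]]
        pairs = [(chain[i], chain[i + 1]) for i in range(len(chain) - 1)]
        adj = SiteAdjacency.from_pairs(pairs, known_sites=asg0.site_ids)
        asg = assign_regions(res, d, 2, adjacency=adj)
        assert asg.criteria_report["n_noncontiguous_regions"] >= 1
        assert asg.criteria_report["monophyletic_regions"] is True

    def test_site_order_permutation_consistency(self, random_ultrametric):
        """Permuting site order permutes the assignment but not the partition."""
        d = random_ultrametric(10, seed=6)
        rng = np.random.default_rng(0)
        perm = rng.permutation(10)
        d2 = DistanceMatrix(
            tuple(d.site_ids[i] for i in perm),
            d.values[np.ix_(perm, perm)],
            d.metric,
        )
        a1 = assign_regions(linkage(d, "UPGMA"), d, 3)
        a2 = assign_regions(linkage(d2, "UPGMA"), d2, 3)
        part = lambda a: {
            frozenset(s for s in a.site_ids if a.regions[s] == v)
            for v in set(a.regions.values())
        }
        assert part(a1) == part(a2)


class TestDendrogramExport:
    def test_newick_round_trips_cophenetic_heights(self, random_ultrametric):
        from floregion import Phylogeny

        d = random_ultrametric(7, seed=9)
        res = linkage(d, "UPGMA")
        tree = Phylogeny.from_newick(dendrogram_newick(res))
        assert set(tree.tip_labels) == set(d.site_ids)
        # leaf depths equal half the root merge height? no: depths equal the
        # root height; pairwise path depth differences encode merge heights
        depths = tree.tip_depths()
        root_h = max(res.heights)
        for v in depths.values():
            assert v == pytest.approx(root_h, rel=1e-6)
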