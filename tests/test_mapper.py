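"""Mapper: filter geometry, cover, clustering, shape graph, ANOVA."""
import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from elanull.datatypes import MapperConfig
from elanull.errors import DegenerateStatisticError, ValidityError
from elanull.mapper import (condition_anova, geodesic_filter,
                            high_degree_proportion, overlapping_bins,
                            partial_cluster, run_mapper, shape_graph)
from elanull.simulate import simulate_switching, two_regime_model


class TestGeodesicFilter:
    def test_collinear_points_path_additivity(self):
        from elanull.mapper import _knn_geodesics
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [2.5, 0.0]])
        geo = _knn_geodesics(pts, k=1)
        assert geo[0, 2] == pytest.approx(geo[0, 1] + geo[1, 2])

    def test_exact_recovery_of_planar_configuration(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(30, 2))
        emb = geodesic_filter(pts, MapperConfig(k_neighbors=29))
        d_in = pdist(pts)
        d_out = pdist(emb)
        assert np.abs(d_in - d_out).max() < 1e-6

    def test_circle_preserves_cyclic_order(self):
        theta = np.linspace(0, 2 * np.pi, 100, endpoint=False)
        pts = np.column_stack([np.cos(theta), np.sin(theta)])
        emb = geodesic_filter(pts, MapperConfig(k_neighbors=3))
        angles = np.arctan2(emb[:, 1] - emb[:, 1].mean(),
                            emb[:, 0] - emb[:, 0].mean())
        order = np.argsort(angles)
        pos = np.empty(100, dtype=int)
        pos[order] = np.arange(100)
        steps = np.diff(pos[np.arange(100)]) % 100
        # consecutive circle points must be adjacent in angular order,
        # up to direction
        assert set(np.unique(steps)) <= {1, 99}

    def test_permutation_invariance_bit_exact(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(60, 3))
        perm = rng.permutation(60)
        emb = geodesic_filter(pts, MapperConfig(k_neighbors=5))
        emb_p = geodesic_filter(pts[perm], MapperConfig(k_neighbors=5))
        assert np.array_equal(emb[perm], emb_p)

    def test_disconnected_graph_is_bridged(self):
        pts = np.vstack([np.random.default_rng(2).normal(0, 0.1, (10, 2)),
                         np.random.default_rng(3).normal(50, 0.1, (10, 2))])
        emb = geodesic_filter(pts, MapperConfig(k_neighbors=3))
        assert np.all(np.isfinite(emb))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidityError):
            geodesic_filter(np.zeros((5, 2)), MapperConfig(k_neighbors=12))


class TestOverlappingBins:
    def test_zero_overlap_partition(self):
        emb = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0],
                        [0.5, 0.5]])
        cfg = MapperConfig(resolution=2, overlap_fraction=0.0)
        bins = overlapping_bins(emb, cfg)
        total = sum(len(v) for v in bins.values())
        assert total == 5          # each point in exactly one bin
        # centre point (0.5, 0.5) sits on the shared boundary -> lower bin
        assert 4 in bins[(0, 0)]

    def test_half_overlap_membership_counts(self):
        cfg = MapperConfig(resolution=4, overlap_fraction=0.5)
        grid = np.linspace(0.0, 1.0, 5)
        emb = np.array([[x, y] for x in grid for y in grid])
        bins = overlapping_bins(emb, cfg)
        counts = np.zeros(len(emb), dtype=int)
        for members in bins.values():
            counts[members] += 1
        # bin width 0.25, expansion 0.0625: a point at a bin centre
        # (e.g. 0.125, 0.125) lies in 1 bin; corner points in up to 4
        centre = 5 * 0 + 0  # (0, 0) is a corner of the bounding box
        assert counts.max() == 4
        assert counts[np.flatnonzero((emb[:, 0] == 0.0)
                                     & (emb[:, 1] == 0.0))[0]] == 1

    def test_total_membership_at_least_t(self):
        rng = np.random.default_rng(4)
        emb = rng.normal(size=(200, 2))
        for overlap in (0.0, 0.3, 0.6):
            cfg = MapperConfig(resolution=5, overlap_fraction=overlap)
            total = sum(len(v) for v in
                        overlapping_bins(emb, cfg).values())
            if overlap == 0.0:
                assert total == 200
            else:
                assert total >= 200


class TestPartialCluster:
    def test_singleton_bin_single_cluster(self):
        cfg = MapperConfig()
        nodes = partial_cluster({(0, 0): np.array([3])},
                                np.random.default_rng(5).normal(size=(5, 4)),
                                cfg)
        assert len(nodes) == 1 and nodes[0].members.tolist() == [3]

    def test_two_separated_pairs_split(self):
        data = np.array([[0.0, 0.0], [0.1, 0.0], [10.0, 0.0], [10.1, 0.0]])
        cfg = MapperConfig()
        nodes = partial_cluster({(0, 0): np.arange(4)}, data, cfg)
        member_sets = sorted(tuple(n.members) for n in nodes)
        assert member_sets == [(0, 1), (2, 3)]

    def test_agrees_with_exhaustive_single_linkage(self):
        from scipy.cluster.hierarchy import fcluster, linkage
        rng = np.random.default_rng(6)
        cfg = MapperConfig()
        for _ in range(20):
            data = rng.normal(size=(8, 3))
            nodes = partial_cluster({(0, 0): np.arange(8)}, data, cfg)
            # recompute the cut threshold from the histogram heuristic
            z = linkage(pdist(data), method="single")
            counts, edges = np.histogram(z[:, 2], bins=10)
            empty = np.flatnonzero(counts == 0)
            if empty.size:
                labels = fcluster(z, t=edges[empty[0]], criterion="distance")
            else:
                labels = np.ones(8, dtype=int)
            expected = sorted(tuple(np.flatnonzero(labels == lab))
                              for lab in np.unique(labels))
            got = sorted(tuple(n.members) for n in nodes)
            assert got == expected


class TestShapeGraph:
    def test_zero_overlap_graph_is_edgeless(self):
        rng = np.random.default_rng(7)
        emb = rng.normal(size=(100, 2))
        cfg = MapperConfig(resolution=4, overlap_fraction=0.0)
        bins = overlapping_bins(emb, cfg)
        g = shape_graph(partial_cluster(bins, emb, cfg))
        assert g.edges == []

    def test_one_shared_volume_one_edge(self):
        from elanull.datatypes import MapperNode
        nodes = [MapperNode(0, (0, 0), np.array([1, 2])),
                 MapperNode(1, (1, 0), np.array([2, 3]))]
        g = shape_graph(nodes)
        assert g.edges == [(0, 1)]

    def test_degrees_match_adjacency_recount(self):
        rng = np.random.default_rng(8)
        emb = rng.normal(size=(300, 2))
        cfg = MapperConfig(resolution=4, overlap_fraction=0.5)
        bins = overlapping_bins(emb, cfg)
        g = shape_graph(partial_cluster(bins, emb, cfg))
        nx_deg = dict(g.to_networkx().degree())
        for node, deg in zip(g.nodes, g.degrees):
            assert nx_deg[node.node_id] == deg


class TestDegreeStatistics:
    def test_trivial_proportions(self):
        from elanull.datatypes import MapperGraph, MapperNode
        nodes = [MapperNode(i, (i, 0), np.array([i])) for i in range(3)]
        g = MapperGraph(nodes=nodes, edges=[])
        assert high_degree_proportion(g, 20) == 0.0
        g2 = MapperGraph(nodes=nodes,
                         edges=[(0, 1), (0, 2)])
        assert high_degree_proportion(g2, 0) == 1.0
        assert high_degree_proportion(g2, 1) == pytest.approx(1 / 3)

    def test_empty_graph_rejected(self):
        from elanull.datatypes import MapperGraph
        with pytest.raises(ValidityError):
            high_degree_proportion(MapperGraph(), 20)


class TestConditionAnova:
    def test_identical_groups_f_zero(self):
        f, p = condition_anova({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        assert f == 0.0

    def test_matches_hand_computation(self):
        groups = {"a": [1.0, 2.0, 3.0], "b": [2.0, 3.0, 4.0],
                  "c": [5.0, 6.0, 7.0]}
        arrays = [np.array(v) for v in groups.values()]
        grand = np.concatenate(arrays).mean()
        ssb = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
        ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
        expected = (ssb / 2) / (ssw / 6)
        f, _ = condition_anova(groups)
        assert f == pytest.approx(expected)

    def test_degenerate_variance_raises(self):
        with pytest.raises(DegenerateStatisticError):
            condition_anova({"a": [1.0, 1.0], "b": [2.0, 2.0]})


class TestPipelineInvariance:
    def test_degree_multiset_invariant_under_row_permutation(self):
        model = two_regime_model(5, 4.0, 0.95, seed=9)
        series, _ = simulate_switching(model, 300, seed=10)
        cfg = MapperConfig()
        rng = np.random.default_rng(11)
        g_a = run_mapper(series.data, cfg)
        g_b = run_mapper(series.data[rng.permutation(300)], cfg)
        assert sorted(g_a.degrees.tolist()) == sorted(g_b.degrees.tolist())
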