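import math

import networkx as nx
import numpy as np
import pytest

from oracles import (
    enumerate_simple_paths,
    exhaustive_betweenness,
    random_weighted_graph,
    shortest_path_stats,
)
from psnflow.communication import (
    all_pairs_shortest_paths,
    betweenness,
    closeness,
    edge_weight,
    suboptimal_paths,
)


def _unit(graph):
    for u, v in graph.edges:
        graph[u][v]["weight"] = 1.0
    return graph


class TestEdgeWeight:
    def test_analytic_values(self):
        assert edge_weight(0.5) == pytest.approx(math.log(2), abs=1e-12)
        assert edge_weight(1.0) == 0.0
        assert edge_weight(-0.5) == pytest.approx(math.log(2), abs=1e-12)

    def test_floor_caps_uncorrelated_pairs(self):
        assert edge_weight(0.0, floor=1e-6) == pytest.approx(
            -math.log(1e-6), rel=1e-12
        )
        assert edge_weight(1e-9, floor=1e-6) == edge_weight(0.0, floor=1e-6)

    def test_out_of_range_correlation_rejected(self):
        with pytest.raises(ValueError):
            edge_weight(1.5)


class TestShortestPaths:
    def test_triangle_detour_beats_heavy_direct_edge(self):
        g = nx.Graph()
        g.add_edge("A", "B", weight=1.0)
        g.add_edge("B", "C", weight=1.0)
        g.add_edge("A", "C", weight=3.0)
        nodes, dist, counts = all_pairs_shortest_paths(g)
        i, j = nodes.index("A"), nodes.index("C")
        assert dist[i, j] == pytest.approx(2.0)
        assert counts[i, j] == 1

    def test_four_cycle_has_two_tied_paths(self):
        g = _unit(nx.cycle_graph(4))
        nodes, dist, counts = all_pairs_shortest_paths(g)
        assert dist[0, 2] == pytest.approx(2.0)
        assert counts[0, 2] == 2

    def test_negative_weight_rejected(self):
        g = nx.Graph()
        g.add_edge(0, 1, weight=-0.1)
        with pytest.raises(ValueError, match="negative"):
            all_pairs_shortest_paths(g)

    def test_matches_exhaustive_enumeration_on_random_graphs(self):
        for seed in range(40):
            g = random_weighted_graph(7, 0.45, seed)
            nodes, dist, counts = all_pairs_shortest_paths(g)
            ref_dist, ref_count = shortest_path_stats(g)
            for (u, v), d in ref_dist.items():
                i, j = nodes.index(u), nodes.index(v)
                if math.isinf(d):
                    assert math.isinf(dist[i, j]) and counts[i, j] == 0
                else:
                    assert dist[i, j] == pytest.approx(d, rel=1e-9)
                    assert counts[i, j] == ref_count[(u, v)], (seed, u, v)

    def test_distance_matrix_is_metric(self):
        g = random_weighted_graph(9, 0.5, 7, connected=True)
        _, dist, _ = all_pairs_shortest_paths(g)
        np.testing.assert_allclose(dist, dist.T, atol=1e-12)
        n = len(dist)
        for k in range(n):
            assert np.all(
                dist <= dist[:, k][:, None] + dist[k, :][None, :] + 1e-9
            )


class TestBetweenness:
    def test_path_graph_middle_node(self):
        btw = betweenness(_unit(nx.path_graph(3)))
        assert btw[1] == pytest.approx(1.0)
        assert btw[0] == btw[2] == 0.0

    def test_star_center_carries_all_paths(self):
        btw = betweenness(_unit(nx.star_graph(4)))
        assert btw[0] == pytest.approx(1.0)
        assert all(btw[leaf] == 0.0 for leaf in range(1, 5))

    def test_five_cycle_uniform_sixth(self):
        btw = betweenness(_unit(nx.cycle_graph(5)))
        for node in range(5):
            assert btw[node] == pytest.approx(1 / 6, abs=1e-12)

    def test_matches_exhaustive_enumeration_and_networkx(self):
        for seed in range(30):
            g = random_weighted_graph(7, 0.45, seed + 500)
            ours = betweenness(g)
            ref = exhaustive_betweenness(g)
            for node in g.nodes:
                assert ours[node] == pytest.approx(ref[node], abs=1e-9), seed
        # independent library cross-check at a larger size
        g = random_weighted_graph(12, 0.4, 42, connected=True)
        ours = betweenness(g)
        ref = nx.betweenness_centrality(g, weight="weight", normalized=True)
        for node in g.nodes:
            assert ours[node] == pytest.approx(ref[node], abs=1e-9)

    def test_removing_zero_betweenness_node_preserves_distances(self):
        g = random_weighted_graph(9, 0.5, 11, connected=True)
        btw = betweenness(g)
        zero_nodes = [
            node for node, b in btw.items()
            if b == 0.0 and g.degree[node] > 0
        ]
        if not zero_nodes:
            pytest.skip("no zero-betweenness node in this graph")
        victim = zero_nodes[0]
        nodes, dist, _ = all_pairs_shortest_paths(g)
        h = g.copy()
        h.remove_node(victim)
        nodes2, dist2, _ = all_pairs_shortest_paths(h)
        for u in nodes2:
            for v in nodes2:
                i1, j1 = nodes.index(u), nodes.index(v)
                i2, j2 = nodes2.index(u), nodes2.index(v)
                assert dist2[i2, j2] == pytest.approx(dist[i1, j1], rel=1e-9)

    def test_bridge_between_two_communities_dominates(self):
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
        g.add_node(10)
        g.add_edge(0, 10)
        g.add_edge(10, 5)
        btw = betweenness(_unit(g))
        assert btw[10] == max(btw.values())

    def test_tiny_graph_warns_and_returns_zero(self):
        g = _unit(nx.path_graph(2))
        with pytest.warns(UserWarning):
            btw = betweenness(g)
        assert set(btw.values()) == {0.0}


class TestCloseness:
    def test_inverse_mean_distance_on_path_graph(self):
        c = closeness(_unit(nx.path_graph(3)))
        assert c[1] == pytest.approx(1.0)       # distances 1, 1
        assert c[0] == pytest.approx(2 / 3)     # distances 1, 2


class TestSuboptimalPaths:
    def test_second_best_within_tolerance_is_returned(self):
        g = nx.Graph()
        g.add_edge("S", "A", weight=0.5)
        g.add_edge("A", "T", weight=0.5)
        g.add_edge("S", "B", weight=0.75)
        g.add_edge("B", "T", weight=0.75)
        pe = suboptimal_paths(g, "S", "T", tolerance=0.69)
        assert len(pe.paths) == 2
        assert pe.paths[0][0] == ["S", "A", "T"]
        assert pe.paths[1][1] == pytest.approx(1.5)

    def test_zero_tolerance_keeps_only_optima(self):
        g = _unit(nx.cycle_graph(4))
        pe = suboptimal_paths(g, 0, 2, tolerance=0.0)
        assert len(pe.paths) == 2
        assert all(length == pytest.approx(2.0) for _, length in pe.paths)

    def test_matches_brute_force_bounded_enumeration(self):
        for seed in range(30):
            g = random_weighted_graph(8, 0.4, seed + 900)
            nodes = list(g.nodes)
            src, dst = nodes[0], nodes[-1]
            pe = suboptimal_paths(g, src, dst, tolerance=0.69)
            everything = enumerate_simple_paths(g, src, dst)
            if not everything:
                assert pe.disconnected
                continue
            best = min(length for _, length in everything)
            want = sorted(
                [
                    (path, length) for path, length in everything
                    if length <= best + 0.69 + 1e-12
                ],
                key=lambda t: (t[1], t[0]),
            )
            assert [p for p, _ in pe.paths] == [p for p, _ in want], seed
            np.testing.assert_allclose(
                pe.lengths(), [length for _, length in want], rtol=1e-12
            )

    def test_disconnected_pair_is_flagged(self):
        g = nx.Graph()
        g.add_edge(0, 1, weight=1.0)
        g.add_node(2)
        pe = suboptimal_paths(g, 0, 2)
        assert pe.disconnected and pe.paths == []

    def test_path_cap_sets_truncation_flag(self):
        g = _unit(nx.complete_graph(7))
        pe = suboptimal_paths(g, 0, 6, tolerance=10.0, max_paths=5)
        assert pe.truncated
        assert len(pe.paths) == 5
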