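import itertools

import networkx as nx
import numpy as np
import pytest

from pcrnet.network import (
    SymptomNetwork,
    betweenness_weighted,
    build_mean_network,
    layout_fruchterman_reingold,
    permutation_null,
    threshold_network,
    weighted_degrees,
)
from conftest import build_record, random_digraph


def net_from_edges(edges, nodes=None):
    g = nx.DiGraph()
    if nodes:
        g.add_nodes_from(nodes)
    for u, v, w in edges:
        g.add_edge(u, v, weight=float(w))
    return SymptomNetwork(g)


class TestBuildMeanNetwork:
    def test_single_participant_single_edge(self, catalog):
        record = build_record("p1", {1: 1, 2: 1}, {(1, 2): 6}, catalog)
        net = build_mean_network([record], catalog=catalog)
        assert net.edge_weight(1, 2) == 6.0
        assert net.graph[1][2]["n"] == 1
        assert not net.graph.has_edge(2, 1)  # skipped question, no edge

    def test_mean_over_contributing_participants(self, catalog):
        r1 = build_record("p1", {1: 1, 2: 1}, {(1, 2): 4}, catalog)
        r2 = build_record("p2", {1: 1, 2: 1}, {(1, 2): 8}, catalog)
        net = build_mean_network([r1, r2], catalog=catalog)
        assert net.edge_weight(1, 2) == 6.0
        assert net.graph[1][2]["n"] == 2

    def test_available_case_means_with_design_gaps(self, catalog):
        # p2 never endorsed item 2, so only p1 and p3 contribute to (1, 2)
        r1 = build_record("p1", {1: 1, 2: 1}, {(1, 2): 3}, catalog)
        r2 = build_record("p2", {1: 1, 3: 1}, {(1, 3): 9}, catalog)
        r3 = build_record("p3", {1: 1, 2: 1}, {(1, 2): 8}, catalog)
        net = build_mean_network([r1, r2, r3], catalog=catalog)
        assert net.edge_weight(1, 2) == 5.5
        assert net.edge_weight(1, 3) == 9.0

    def test_min_n_filters_rare_edges(self, catalog):
        r1 = build_record("p1", {1: 1, 2: 1}, {(1, 2): 4}, catalog)
        r2 = build_record("p2", {1: 1, 2: 1}, {(1, 2): 8, (2, 1): 5}, catalog)
        net = build_mean_network([r1, r2], min_n=2, catalog=catalog)
        assert net.graph.has_edge(1, 2)
        assert not net.graph.has_edge(2, 1)

    def test_node_frequency_attribute(self, catalog):
        r1 = build_record("p1", {1: 4}, catalog=catalog)
        r2 = build_record("p2", {1: 2}, catalog=catalog)
        net = build_mean_network([r1, r2], catalog=catalog)
        assert net.graph.nodes[1]["mean_frequency"] == 3.0
        assert len(net.nodes) == 40  # every catalog item is a node


class TestThreshold:
    def test_zero_cutoff_nonstrict_is_identity(self):
        net = net_from_edges([(1, 2, 3.0), (2, 3, 0.5)])
        out = threshold_network(net, 0.0, strict=False)
        assert sorted(out.graph.edges) == sorted(net.graph.edges)

    def test_max_cutoff_strict_empties(self):
        net = net_from_edges([(1, 2, 10.0)])
        assert threshold_network(net, 10.0, strict=True).n_edges == 0

    def test_strict_vs_inclusive_at_boundary(self):
        net = net_from_edges([(1, 2, 4.5), (2, 3, 4.6), (3, 1, 2.0)])
        strict = threshold_network(net, 4.5, strict=True)
        loose = threshold_network(net, 4.5, strict=False)
        assert sorted(strict.graph.edges) == [(2, 3)]
        assert sorted(loose.graph.edges) == [(1, 2), (2, 3)]

    def test_monotone_shrinkage(self, rng):
        g = random_digraph(rng, 8, 0.4, weighted=True)
        net = SymptomNetwork(g)
        previous = None
        for cutoff in (0, 2, 4, 6, 8, 10):
            edges = set(threshold_network(net, cutoff).graph.edges)
            if previous is not None:
                assert edges <= previous
            previous = edges


class TestWeightedDegrees:
    def test_single_edge(self):
        net = net_from_edges([(1, 2, 6.0)], nodes=[1, 2, 3])
        deg = weighted_degrees(net)
        assert deg.loc[1, "outdegree"] == 6.0
        assert deg.loc[2, "indegree"] == 6.0
        assert deg.loc[3].sum() == 0.0

    def test_uniform_complete_digraph(self):
        n, w = 5, 2.5
        edges = [(u, v, w) for u in range(n) for v in range(n) if u != v]
        deg = weighted_degrees(net_from_edges(edges))
        assert (deg["outdegree"] == (n - 1) * w).all()
        assert (deg["indegree"] == (n - 1) * w).all()

    def test_degree_sums_balance(self, rng):
        g = random_digraph(rng, 10, 0.3, weighted=True)
        deg = weighted_degrees(SymptomNetwork(g))
        total_weight = sum(d["weight"] for _, _, d in g.edges(data=True))
        assert deg["outdegree"].sum() == pytest.approx(total_weight)
        assert deg["indegree"].sum() == pytest.approx(total_weight)


def brute_force_betweenness(g, alpha=1.0):
    """Exhaustive minimal-cost path enumeration over all simple paths."""
    nodes = list(g.nodes)
    scores = {v: 0.0 for v in nodes}
    for s, t in itertools.permutations(nodes, 2):
        best, paths = None, []
        for path in nx.all_simple_paths(g, s, t):
            cost = sum(
                g[u][v]["weight"] ** (-alpha) for u, v in zip(path, path[1:])
            )
            if best is None or cost < best - 1e-12:
                best, paths = cost, [path]
            elif abs(cost - best) <= 1e-12:
                paths.append(path)
        for path in paths:
            for v in path[1:-1]:
                scores[v] += 1.0 / len(paths)
    return scores


class TestBetweenness:
    def test_chain_center_scores_one(self):
        net = net_from_edges([(1, 2, 3.0), (2, 3, 7.0)])
        btw = betweenness_weighted(net)
        assert btw[2] == 1.0
        assert btw[1] == btw[3] == 0.0

    def test_uniform_complete_digraph_is_zero(self):
        edges = [(u, v, 4.0) for u in range(5) for v in range(5) if u != v]
        btw = betweenness_weighted(net_from_edges(edges))
        assert (btw == 0).all()

    def test_strong_relay_beats_direct_weak_edge(self):
        # cost 1/w: 1 -> 2 -> 3 costs 1/9 + 1/9 < 1/1 direct
        net = net_from_edges([(1, 3, 1.0), (1, 2, 9.0), (2, 3, 9.0)])
        btw = betweenness_weighted(net)
        assert btw[2] == 1.0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        g = random_digraph(rng, 6, 0.45, weighted=True)
        net = SymptomNetwork(g)
        expected = brute_force_betweenness(g)
        got = betweenness_weighted(net)
        for v in g.nodes:
            assert got[v] == pytest.approx(expected[v]), f"node {v}"

    @pytest.mark.parametrize("seed", range(4))
    def test_unit_weights_equal_unweighted_betweenness(self, seed):
        rng = np.random.default_rng(100 + seed)
        g = random_digraph(rng, 8, 0.3, weighted=False)
        got = betweenness_weighted(SymptomNetwork(g))
        unweighted = nx.betweenness_centrality(g, normalized=False)
        for v in g.nodes:
            assert got[v] == pytest.approx(unweighted[v])

    def test_zero_weight_edges_uncrossable(self):
        net = net_from_edges([(1, 2, 0.0), (2, 3, 5.0)])
        btw = betweenness_weighted(net)
        assert (btw == 0).all()


class TestPermutationNull:
    def test_equal_weights_give_zero_width_and_no_flags(self):
        edges = [(1, 2, 5.0), (2, 3, 5.0), (3, 1, 5.0), (1, 3, 5.0)]
        report = permutation_null(net_from_edges(edges), n_perm=200, seed=0)
        for measure in ("outdegree", "indegree", "betweenness"):
            width = (
                report.table[f"{measure}_p97.5"] - report.table[f"{measure}_p2.5"]
            )
            assert (width == 0).all()
            assert not report.table[f"{measure}_extreme"].any()

    def test_same_seed_reproduces_report(self, rng):
        g = random_digraph(rng, 8, 0.4, weighted=True)
        net = SymptomNetwork(g)
        a = permutation_null(net, n_perm=150, seed=9)
        b = permutation_null(net, n_perm=150, seed=9)
        assert a.table.equals(b.table)

    def test_dominant_hub_flagged_for_outdegree(self):
        # node 1 holds five weight-9 edges; thirty weight-1 edges elsewhere.
        # Any permutation scatters the 9s, so the hub's outdegree collapses.
        edges = [(1, v, 9.0) for v in range(2, 7)]
        others = [(u, v) for u in range(2, 12) for v in range(2, 12) if u != v]
        edges += [(u, v, 1.0) for u, v in others[:30]]
        net = net_from_edges(edges)
        report = permutation_null(net, n_perm=1000, seed=1)
        assert 1 in report.flagged("outdegree")

    def test_percentiles_monotone(self, rng):
        g = random_digraph(rng, 8, 0.5, weighted=True)
        report = permutation_null(SymptomNetwork(g), n_perm=150, seed=2)
        for measure in ("outdegree", "indegree", "betweenness"):
            t = report.table
            assert (t[f"{measure}_p2.5"] <= t[f"{measure}_p50"]).all()
            assert (t[f"{measure}_p50"] <= t[f"{measure}_p97.5"]).all()

    def test_rewire_mode_runs_and_differs(self, rng):
        g = random_digraph(rng, 8, 0.5, weighted=True)
        net = SymptomNetwork(g)
        shuffle = permutation_null(net, n_perm=150, seed=3, mode="shuffle_weights")
        rewire = permutation_null(net, n_perm=150, seed=3, mode="rewire_pairs")
        assert not shuffle.table.equals(rewire.table)

    def test_too_few_permutations_rejected(self):
        with pytest.raises(ValueError):
            permutation_null(net_from_edges([(1, 2, 5.0)]), n_perm=10, seed=0)


class TestLayout:
    def test_single_node_at_origin(self):
        net = net_from_edges([], nodes=[7])
        assert layout_fruchterman_reingold(net) == {7: (0.0, 0.0)}

    def test_deterministic_per_seed(self, rng):
        g = random_digraph(rng, 10, 0.3, weighted=True)
        net = SymptomNetwork(g)
        assert layout_fruchterman_reingold(net, seed=4) == layout_fruchterman_reingold(net, seed=4)

    def test_connected_triad_clusters_tighter_than_isolate(self):
        edges = [(1, 2, 9.0), (2, 3, 9.0), (3, 1, 9.0)]
        net = net_from_edges(edges, nodes=[1, 2, 3, 4])
        closer = 0
        for seed in range(5):
            pos = layout_fruchterman_reingold(net, seed=seed)
            triad = [np.array(pos[v]) for v in (1, 2, 3)]
            centroid = np.mean(triad, axis=0)
            triad_spread = np.mean([np.linalg.norm(p - centroid) for p in triad])
            isolate_dist = np.linalg.norm(np.array(pos[4]) - centroid)
            closer += triad_spread < isolate_dist
        assert closer >= 4


def test_edgelist_and_graphml_round_trip(tmp_path, rng):
    g = random_digraph(rng, 6, 0.5, weighted=True)
    net = SymptomNetwork(g)
    net.to_edgelist_csv(tmp_path / "edges.csv")
    net.to_graphml(tmp_path / "net.graphml")
    back = nx.read_graphml(tmp_path / "net.graphml")
    assert back.number_of_edges() == net.n_edges
    import pandas as pd

    df = pd.read_csv(tmp_path / "edges.csv")
    assert list(df.columns) == ["source", "target", "weight", "n"]
    assert len(df) == net.n_edges
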