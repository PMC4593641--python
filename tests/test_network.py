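"""Edge filtering, Dijkstra subnetworks, sink bookkeeping, restart walk."""

import numpy as np
import pytest

from _oracles import floyd_warshall, restart_walk_solve
from cnvprior.network import (
    SINK,
    WeightedGeneNetwork,
    build_subnetwork,
    edge_distance,
    filter_top_edges,
    neighbor_weight,
    random_walk_ranks,
    read_edge_list,
)


def _random_net(rng, n_nodes, n_edges):
    net = WeightedGeneNetwork()
    nodes = [f"g{i}" for i in range(n_nodes)]
    for n in nodes:
        net.add_node(n)
    added = 0
    while added < n_edges:
        i, j = rng.choice(n_nodes, 2, replace=False)
        a, b = nodes[int(i)], nodes[int(j)]
        if not net.graph().has_edge(a, b):
            net.add_edge(a, b, float(rng.uniform(0.1, 5.0)))
            added += 1
    return net, nodes


class TestNetworkContainer:
    def test_rejects_self_loop_and_nonpositive_weight(self):
        net = WeightedGeneNetwork()
        with pytest.raises(ValueError, match="self-loop"):
            net.add_edge("a", "a", 1.0)
        with pytest.raises(ValueError, match="positive"):
            net.add_edge("a", "b", 0.0)

    def test_duplicate_pairs_summed(self, tmp_path):
        path = tmp_path / "edges.tsv"
        path.write_text("a\tb\t1.5\nb\ta\t2.5\nb\tc\t1.0\n")
        net = read_edge_list(str(path))
        assert net.weight("a", "b") == pytest.approx(4.0)
        assert net.max_weight == pytest.approx(4.0)


class TestFilterTopEdges:
    def test_keeps_five_largest_of_hundred(self):
        rng = np.random.default_rng(0)
        net, _ = _random_net(rng, 30, 100)
        kept = filter_top_edges(net, 0.05)
        assert kept.n_edges() == 5
        top5 = sorted((w for _, _, w in net.edges()), reverse=True)[:5]
        assert sorted((w for _, _, w in kept.edges()), reverse=True) == pytest.approx(top5)
        assert kept.nodes == net.nodes  # isolates retained

    def test_fraction_one_is_identity(self):
        rng = np.random.default_rng(1)
        net, _ = _random_net(rng, 10, 20)
        kept = filter_top_edges(net, 1.0)
        canon = lambda es: {(frozenset((a, b)), round(w, 12)) for a, b, w in es}
        assert canon(kept.edges()) == canon(net.edges())

    def test_ties_at_cutoff_all_kept(self):
        net = WeightedGeneNetwork()
        for i, w in enumerate([5.0, 3.0, 3.0, 3.0, 1.0]):
            net.add_edge(f"a{i}", f"b{i}", w)
        kept = filter_top_edges(net, 0.4)  # nominal 2 edges, cutoff weight 3.0
        weights = sorted(w for _, _, w in kept.edges())
        assert weights == [3.0, 3.0, 3.0, 5.0]

    def test_nested_as_fraction_decreases(self):
        rng = np.random.default_rng(2)
        net, _ = _random_net(rng, 20, 60)
        prev = None
        for frac in (1.0, 0.5, 0.2, 0.05):
            kept = {(a, b) for a, b, _ in filter_top_edges(net, frac).edges()}
            if prev is not None:
                assert kept <= prev
            prev = kept


class TestEdgeDistance:
    def test_max_weight_edge_has_distance_one(self):
        assert edge_distance(4.0, 4.0) == pytest.approx(1.0)

    def test_inverse_proportionality(self):
        assert edge_distance(2.0, 4.0) == pytest.approx(2.0)

    def test_monotone_decreasing_in_weight(self):
        rng = np.random.default_rng(3)
        ws = np.sort(rng.uniform(0.1, 4.0, size=20))
        ds = [edge_distance(float(w), 4.0) for w in ws]
        assert all(d1 >= d2 for d1, d2 in zip(ds, ds[1:]))

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            edge_distance(0.0, 4.0)


class TestBuildSubnetwork:
    def test_path_graph_smaller_than_k(self):
        net = WeightedGeneNetwork(
            [(f"n{i}", f"n{i+1}", 1.0) for i in range(4)]
        )
        sub = build_subnetwork(net, "n0", k_sub=30)
        assert set(sub.members) == {f"n{i}" for i in range(5)}
        assert not sub.has_sink

    def test_sink_weight_is_sum_of_removed_edges(self):
        # star around q; cut keeps 2 nearest, boundary gene loses 2 edges
        net = WeightedGeneNetwork([
            ("q", "a", 4.0), ("q", "b", 3.0), ("q", "c", 1.0),
            ("b", "x", 1.5), ("b", "y", 2.5),
            ("x", "y", 0.1),
        ])
        sub = build_subnetwork(net, "q", k_sub=2)
        assert set(sub.members) == {"q", "a", "b"}
        assert sub.has_sink
        assert sub.graph["b"][SINK]["weight"] == pytest.approx(1.5 + 2.5)

    def test_isolated_query_is_singleton(self):
        net = WeightedGeneNetwork([("a", "b", 1.0)])
        net.add_node("lone")
        sub = build_subnetwork(net, "lone")
        assert sub.members == ["lone"]
        assert not sub.has_sink

    def test_unknown_query_rejected(self):
        with pytest.raises(KeyError):
            build_subnetwork(WeightedGeneNetwork([("a", "b", 1.0)]), "zzz")

    @pytest.mark.parametrize("seed", range(15))
    def test_members_match_floyd_warshall_oracle(self, seed):
        rng = np.random.default_rng(seed)
        net, nodes = _random_net(rng, 12, 25)
        max_w = net.max_weight
        dist_edges = {(a, b): max_w / w for a, b, w in net.edges()}
        D = floyd_warshall(nodes, dist_edges)
        query = nodes[int(rng.integers(len(nodes)))]
        qi = nodes.index(query)
        k = 5
        sub = build_subnetwork(net, query, k_sub=k)
        reachable = sorted(
            (D[qi, i], n) for i, n in enumerate(nodes)
            if n != query and np.isfinite(D[qi, i])
        )
        expected = {n for _, n in reachable[:k]}
        # distance ties at the boundary may swap equally-near genes
        cut = reachable[k - 1][0] if len(reachable) >= k else np.inf
        chosen = set(sub.neighbors)
        assert {n for d, n in reachable[:k] if d < cut - 1e-12} <= chosen
        assert all(
            d <= cut + 1e-12
            for d, n in ((sub.distances[m], m) for m in sub.neighbors)
        )
        assert len(chosen) == min(k, len(reachable))
        for m in sub.neighbors:  # distances agree with the oracle
            assert sub.distances[m] == pytest.approx(D[qi, nodes.index(m)])
            assert sub.distances[m] >= 1.0 - 1e-12


class TestRandomWalk:
    def test_single_neighbor_rank_one(self):
        net = WeightedGeneNetwork([("q", "a", 2.0)])
        sub = build_subnetwork(net, "q")
        ranks = random_walk_ranks(sub)
        assert ranks == {"a": 1}

    def test_symmetric_neighbors_equal_probability(self):
        net = WeightedGeneNetwork([("q", "a", 2.0), ("q", "b", 2.0)])
        sub = build_subnetwork(net, "q")
        random_walk_ranks(sub)
        pa = sub.walk_probabilities["a"]
        pb = sub.walk_probabilities["b"]
        assert pa == pytest.approx(pb, abs=1e-9)
        assert sub.ranks["a"] == 1 and sub.ranks["b"] == 2  # deterministic tie

    def test_probabilities_are_distribution_and_match_dense_oracle(self):
        rng = np.random.default_rng(7)
        net, nodes = _random_net(rng, 8, 14)
        query = nodes[0]
        sub = build_subnetwork(net, query, k_sub=5)
        random_walk_ranks(sub, alpha=0.5)
        probs = sub.walk_probabilities
        assert sum(probs.values()) == pytest.approx(1.0, abs=1e-9)
        assert all(p >= 0 for p in probs.values())
        weight_edges = {
            (a, b): d["weight"] for a, b, d in sub.graph.edges(data=True)
        }
        oracle = restart_walk_solve(list(sub.graph.nodes), weight_edges, query, 0.5)
        for n, p in probs.items():
            assert p == pytest.approx(oracle[n], abs=1e-8)

    def test_ranks_are_permutation_and_query_unranked(self):
        rng = np.random.default_rng(8)
        net, nodes = _random_net(rng, 10, 20)
        sub = build_subnetwork(net, nodes[0], k_sub=6)
        ranks = random_walk_ranks(sub)
        assert sorted(ranks.values()) == list(range(1, len(sub.neighbors) + 1))
        assert nodes[0] not in ranks
        assert SINK not in ranks


class TestNeighborWeight:
    def test_direct_max_weight_edge(self):
        net = WeightedGeneNetwork([("q", "a", 4.0), ("a", "b", 2.0)])
        sub = build_subnetwork(net, "q")
        assert neighbor_weight(sub, "a") == pytest.approx(4.0)
        assert neighbor_weight(sub, "b") == pytest.approx(4.0 / (1.0 + 2.0))

    def test_rejects_non_member(self):
        net = WeightedGeneNetwork([("q", "a", 1.0)])
        sub = build_subnetwork(net, "q")
        with pytest.raises(KeyError):
            neighbor_weight(sub, "zzz")

    def test_non_increasing_in_distance(self):
        rng = np.random.default_rng(9)
        net, nodes = _random_net(rng, 12, 24)
        sub = build_subnetwork(net, nodes[0], k_sub=8)
        ordered = sorted(sub.neighbors, key=sub.distances.__getitem__)
        ws = [neighbor_weight(sub, m) for m in ordered]
        assert all(w1 >= w2 - 1e-12 for w1, w2 in zip(ws, ws[1:]))
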