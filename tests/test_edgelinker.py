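"""Core algorithm: super-node wiring, Dijkstra halves, per-edge paths, ranking."""

import io
import math

import networkx as nx
import pytest

from toxsignet.edgelinker import (
    SUPER_SOURCE,
    SUPER_TARGET,
    BonusConfig,
    DisconnectedError,
    apply_responsive_bonus,
    augment_with_super_nodes,
    per_edge_best_paths,
    rank_and_truncate,
    run_edgelinker,
    shortest_distances_from_source,
    shortest_distances_to_target,
    write_ranked_edges,
    write_ranked_paths,
)
from toxsignet.toxcast import ToxicantProfile

from conftest import (
    algorithm_per_edge_costs,
    assert_costs_equal,
    brute_force_per_edge_costs,
    make_interactome,
    random_interactome,
)


class TestAugmentation:
    def test_super_edge_count(self):
        g = make_interactome(
            [("A", "B", 0.5), ("B", "C", 0.5), ("C", "D", 0.5), ("D", "E", 0.5)]
        )
        aug = augment_with_super_nodes(g, {"A", "B"}, {"C", "D", "E"})
        assert aug.number_of_edges() == g.n_edges() + 5

    def test_super_edges_cost_zero(self):
        g = make_interactome([("A", "B", 0.5)])
        aug = augment_with_super_nodes(g, {"A"}, {"B"})
        assert aug.edges[SUPER_SOURCE, "A"]["cost"] == 0.0
        assert aug.edges["B", SUPER_TARGET]["cost"] == 0.0

    def test_node_in_both_roles_gets_both_edges(self):
        g = make_interactome([("A", "B", 0.5)])
        aug = augment_with_super_nodes(g, {"A"}, {"A", "B"})
        assert aug.has_edge(SUPER_SOURCE, "A") and aug.has_edge("A", SUPER_TARGET)

    def test_empty_sets_rejected(self):
        g = make_interactome([("A", "B", 0.5)])
        with pytest.raises(ValueError):
            augment_with_super_nodes(g, set(), {"B"})
        with pytest.raises(ValueError):
            augment_with_super_nodes(g, {"A"}, set())

    def test_unknown_nodes_rejected(self):
        g = make_interactome([("A", "B", 0.5)])
        with pytest.raises(ValueError, match="not in graph"):
            augment_with_super_nodes(g, {"Z"}, {"B"})


class TestDijkstraHalves:
    def test_sources_at_distance_zero(self, chain_graph):
        aug = augment_with_super_nodes(chain_graph, {"A"}, {"C"})
        d_s, _ = shortest_distances_from_source(aug)
        assert d_s["A"] == 0.0

    def test_targets_at_distance_zero(self, chain_graph):
        aug = augment_with_super_nodes(chain_graph, {"A"}, {"C"})
        d_t, _ = shortest_distances_to_target(aug)
        assert d_t["C"] == 0.0

    def test_hand_computed_chain(self):
        # s -> A (w=1 super), A -> B (w=0.5), B -> t: d_s(B) = -log 0.5 = log 2
        g = make_interactome([("A", "B", 0.5)])
        aug = augment_with_super_nodes(g, {"A"}, {"B"})
        d_s, pred = shortest_distances_from_source(aug)
        assert d_s["B"] == pytest.approx(math.log(2))
        assert pred["B"] == "A" and pred["A"] == SUPER_SOURCE

    def test_unreachable_nodes_absent(self):
        g = make_interactome([("A", "B", 0.5), ("C", "D", 0.5)])
        aug = augment_with_super_nodes(g, {"A"}, {"B"})
        d_s, _ = shortest_distances_from_source(aug)
        assert "C" not in d_s and "D" not in d_s

    def test_matches_networkx_distances(self, rng):
        for _ in range(10):
            g = random_interactome(rng, 8, 14, 0)
            nodes = sorted(g.nodes)
            s, t = {nodes[0]}, {nodes[-1]}
            aug = augment_with_super_nodes(g, s, t)
            d_s, _ = shortest_distances_from_source(aug)
            ref = nx.single_source_dijkstra_path_length(aug, SUPER_SOURCE, weight="cost")
            assert set(d_s) == set(ref)
            for n in ref:
                assert d_s[n] == pytest.approx(ref[n], abs=1e-12)


class TestPerEdgePaths:
    def test_shared_best_path_deduplicated(self):
        g = make_interactome([("A", "B", 0.5), ("B", "C", 0.5)])
        net = run_edgelinker(g, {"A"}, {"C"}, k=10)
        # both edges' best path is A-B-C: a single candidate
        assert len(net.all_paths) == 1
        assert net.all_paths[0].nodes == ("A", "B", "C")

    def test_dead_end_edge_yields_nothing(self):
        g = make_interactome([("A", "B", 0.5), ("B", "C", 0.5), ("B", "X", 0.5)])
        net = run_edgelinker(g, {"A"}, {"C"}, k=10)
        assert all("X" not in p.nodes for p in net.all_paths)

    def test_path_endpoints_are_sources_and_targets(self, rng):
        for _ in range(10):
            g = random_interactome(rng, 10, 25, 0)
            nodes = sorted(g.nodes)
            s, t = set(nodes[:2]), set(nodes[-2:])
            net = run_edgelinker(g, s, t, k=1000, require_candidates=False)
            for p in net.all_paths:
                assert p.nodes[0] in s and p.nodes[-1] in t
                for u, v in p.edges:
                    assert g.graph.has_edge(u, v)
                assert p.score == pytest.approx(
                    math.prod(g.weight(u, v) for u, v in p.edges), rel=1e-9
                )

    def test_candidate_count_bounded_by_edges(self, rng):
        for _ in range(10):
            g = random_interactome(rng, 8, 16, 4)
            nodes = sorted(g.nodes)
            net = run_edgelinker(g, {nodes[0]}, {nodes[-1]}, k=10_000,
                                 require_candidates=False)
            assert len(net.all_paths) <= g.n_edges()

    def test_oracle_equivalence_small_graphs(self, rng):
        checked = 0
        for _ in range(25):
            g = random_interactome(rng, rng.integers(4, 9), rng.integers(5, 14),
                                   rng.integers(0, 3))
            nodes = sorted(g.nodes)
            s = set(rng.choice(nodes, size=2, replace=False))
            t_pool = [n for n in nodes if n not in s]
            t = set(rng.choice(t_pool, size=2, replace=False))
            oracle = brute_force_per_edge_costs(g, s, t)
            algo = algorithm_per_edge_costs(g, s, t)
            assert_costs_equal(algo, oracle)
            checked += len(oracle)
        assert checked > 0

    def test_single_node_path_excluded_by_default(self):
        g = make_interactome([("A", "B", 0.5)])
        net = run_edgelinker(g, {"A"}, {"A", "B"}, k=10)
        assert all(len(p.nodes) > 1 for p in net.all_paths)
        net2 = run_edgelinker(g, {"A"}, {"A", "B"}, k=10, include_single_node=True)
        assert ("A",) in {p.nodes for p in net2.all_paths}


class TestRanking:
    def test_k_larger_than_candidates_is_noop(self, rng):
        g = random_interactome(rng, 8, 16, 0)
        nodes = sorted(g.nodes)
        net = run_edgelinker(g, {nodes[0]}, {nodes[-1]}, k=10_000,
                             require_candidates=False)
        assert net.paths == net.all_paths

    def test_k1_is_global_shortest_path(self, rng):
        for _ in range(10):
            g = random_interactome(rng, 9, 20, 0)
            nodes = sorted(g.nodes)
            s, t = {nodes[0], nodes[1]}, {nodes[-1]}
            aug = augment_with_super_nodes(g, s, t)
            try:
                ref_cost = nx.dijkstra_path_length(aug, SUPER_SOURCE, SUPER_TARGET,
                                                   weight="cost")
            except nx.NetworkXNoPath:
                continue
            net = run_edgelinker(g, s, t, k=1)
            assert net.paths[0].cost == pytest.approx(ref_cost, abs=1e-12)

    def test_ranks_increase_with_cost(self, rng):
        g = random_interactome(rng, 10, 30, 0)
        nodes = sorted(g.nodes)
        net = run_edgelinker(g, {nodes[0]}, {nodes[-1]}, k=5, require_candidates=False)
        costs = [p.cost for p in net.all_paths]
        assert costs == sorted(costs)
        assert [p.rank for p in net.paths] == list(range(1, len(net.paths) + 1))

    def test_disconnected_is_explicit(self):
        g = make_interactome([("A", "B", 0.5), ("C", "D", 0.5)])
        with pytest.raises(DisconnectedError):
            run_edgelinker(g, {"A"}, {"C"}, k=5)
        net = run_edgelinker(g, {"A"}, {"C"}, k=5, require_candidates=False)
        assert net.disconnected and not net.paths

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            rank_and_truncate([], k=0)

    def test_network_union_matches_paths(self, rng):
        g = random_interactome(rng, 12, 40, 0)
        nodes = sorted(g.nodes)
        net = run_edgelinker(g, set(nodes[:2]), set(nodes[-2:]), k=8,
                             require_candidates=False)
        union_edges = {e for p in net.paths for e in p.edges}
        union_nodes = {n for p in net.paths for n in p.nodes}
        assert net.edge_set == union_edges
        assert net.node_set == union_nodes
        for (u, v), r in net.edge_first_rank.items():
            assert r <= net.k
            assert (u, v) in net.paths[r - 1].edges

    def test_deterministic_output_bytes(self, rng):
        g = random_interactome(rng, 10, 30, 5)
        nodes = sorted(g.nodes)
        outputs = []
        for _ in range(2):
            net = run_edgelinker(g, {nodes[0]}, {nodes[-1]}, k=10,
                                 require_candidates=False)
            p, e = io.StringIO(), io.StringIO()
            write_ranked_paths(net, p)
            write_ranked_edges(net, e)
            outputs.append((p.getvalue(), e.getvalue()))
        assert outputs[0] == outputs[1]


class TestResponsiveBonus:
    def two_route_graph(self):
        # two equal-cost routes A->M1->B and A->M2->B
        return make_interactome(
            [("A", "M1", 0.5), ("M1", "B", 0.5), ("A", "M2", 0.5), ("M2", "B", 0.5)]
        )

    def profile(self, z):
        return ToxicantProfile(
            chemical="c", sources=frozenset({"A"}), targets=frozenset({"B"}),
            responsive_intermediates=frozenset({"M2"}), zscores=z,
        )

    def test_zero_strength_is_identity(self):
        g = self.two_route_graph()
        out = apply_responsive_bonus(g, self.profile({"M2": 3.0}), BonusConfig(strength=0))
        assert out is g

    def test_bonus_routes_through_perturbed_protein(self):
        g = self.two_route_graph()
        boosted = apply_responsive_bonus(
            g, self.profile({"M2": 5.0}), BonusConfig(strength=0.5)
        )
        net = run_edgelinker(boosted, {"A"}, {"B"}, k=1)
        assert "M2" in net.paths[0].nodes

    def test_higher_z_never_raises_cost(self):
        g = self.two_route_graph()
        cfg = BonusConfig(strength=0.3)
        lo = apply_responsive_bonus(g, self.profile({"M2": 0.5}), cfg)
        hi = apply_responsive_bonus(g, self.profile({"M2": 4.0}), cfg)
        for u, v in g.graph.edges:
            assert hi.graph.edges[u, v]["cost"] <= lo.graph.edges[u, v]["cost"] + 1e-12

    def test_missing_zscores_no_bonus(self):
        g = self.two_route_graph()
        out = apply_responsive_bonus(g, self.profile({}), BonusConfig(strength=0.5))
        assert out is g

    def test_weights_stay_capped(self):
        g = make_interactome([("A", "M", 0.98), ("M", "B", 0.98)])
        prof = ToxicantProfile(
            chemical="c", sources=frozenset({"A"}), targets=frozenset({"B"}),
            responsive_intermediates=frozenset({"M"}), zscores={"M": 50.0},
        )
        out = apply_responsive_bonus(g, prof, BonusConfig(strength=1.0))
        for _, _, d in out.graph.edges(data=True):
            assert 0 < d["weight"] <= 0.99
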