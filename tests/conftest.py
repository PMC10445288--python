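"""Shared fixtures: small graphs and an exhaustive path-cost oracle."""

from __future__ import annotations

import math

import networkx as nx
import numpy as np
import pytest

from toxsignet.edgelinker import (
    SUPER_SOURCE,
    SUPER_TARGET,
    augment_with_super_nodes,
)
from toxsignet.interactome import DIRECTED, UNDIRECTED, Interactome


def make_interactome(edges, orientation=DIRECTED) -> Interactome:
    """Interactome from (tail, head, weight) triples, all one orientation."""
    g = Interactome()
    for u, v, w in edges:
        g.add_edge(u, v, w, orientation)
    return g


def random_interactome(
    rng: np.random.Generator,
    n_nodes: int,
    n_directed: int,
    n_undirected: int = 0,
) -> Interactome:
    """Random mixed graph with continuous weights; no duplicates/self-loops."""
    nodes = [f"N{i}" for i in range(n_nodes)]
    g = Interactome()
    g.graph.add_nodes_from(nodes)
    made = 0
    attempts = 0
    while made < n_directed and attempts < 50 * n_directed:
        attempts += 1
        i, j = rng.integers(0, n_nodes, size=2)
        if i == j or g.graph.has_edge(nodes[i], nodes[j]):
            continue
        g.add_edge(nodes[i], nodes[j], float(rng.uniform(0.1, 0.95)), DIRECTED)
        made += 1
    made = 0
    attempts = 0
    while made < n_undirected and attempts < 50 * max(n_undirected, 1):
        attempts += 1
        i, j = rng.integers(0, n_nodes, size=2)
        if i == j or g.graph.has_edge(nodes[i], nodes[j]) or g.graph.has_edge(nodes[j], nodes[i]):
            continue
        g.add_edge(nodes[i], nodes[j], float(rng.uniform(0.1, 0.95)), UNDIRECTED)
        made += 1
    return g


def brute_force_per_edge_costs(
    g: Interactome, sources, targets
) -> dict[tuple[str, str], float]:
    """Exhaustive oracle for the best source-to-target cost through each edge.

    Enumerates every simple path from the super source to each edge tail and
    from each edge head to the super target, and minimizes the sum — the
    quantity the per-edge concatenation defines.  Feasible only on tiny
    graphs.
    """
    aug = augment_with_super_nodes(g, sources, targets)

    def path_cost(p):
        return sum(aug.edges[a, b]["cost"] for a, b in zip(p, p[1:]))

    best_from: dict[str, float] = {}
    best_to: dict[str, float] = {}
    for u in aug.nodes:
        if u in (SUPER_SOURCE, SUPER_TARGET):
            continue
        from_costs = [path_cost(p) for p in nx.all_simple_paths(aug, SUPER_SOURCE, u)]
        to_costs = [path_cost(p) for p in nx.all_simple_paths(aug, u, SUPER_TARGET)]
        if from_costs:
            best_from[u] = min(from_costs)
        if to_costs:
            best_to[u] = min(to_costs)

    out: dict[tuple[str, str], float] = {}
    for u, v, d in g.graph.edges(data=True):
        if u in best_from and v in best_to:
            out[(u, v)] = best_from[u] + d["cost"] + best_to[v]
    return out


def algorithm_per_edge_costs(g: Interactome, sources, targets):
    """Per-edge best-path costs as EdgeLinker computes them."""
    from toxsignet.edgelinker import (
        per_edge_best_paths,
        shortest_distances_from_source,
        shortest_distances_to_target,
    )

    aug = augment_with_super_nodes(g, sources, targets)
    d_s, pred = shortest_distances_from_source(aug)
    d_t, succ = shortest_distances_to_target(aug)
    candidates, witnesses = per_edge_best_paths(aug, d_s, pred, d_t, succ)
    cost_by_nodes = {p.nodes: p.cost for p in candidates}
    return {
        e: cost_by_nodes[nodes]
        for nodes, edges in witnesses.items()
        for e in edges
    }


@pytest.fixture
def rng():
    return np.random.default_rng(20230720)


@pytest.fixture
def chain_graph():
    """A -> B -> C with weights 0.5 each."""
    return make_interactome([("A", "B", 0.5), ("B", "C", 0.5)])


def assert_costs_equal(a: dict, b: dict, tol: float = 1e-9):
    assert set(a) == set(b)
    for k in a:
        assert math.isclose(a[k], b[k], rel_tol=tol, abs_tol=tol), (k, a[k], b[k])
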