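"""EdgeLinker: per-edge best receptor-to-TF paths through the interactome.

For every edge (u, v) of the weighted interactome, EdgeLinker finds the
lowest-cost path from any source (responsive receptor) to any target
(responsive TF) that uses that edge, where the cost of a path is the sum of
the -log weights of its edges — equivalently the highest-scoring path, with
score the product of the edge weights.  The construction:

1. add a super source s with zero-cost edges to every source, and a super
   target t with zero-cost edges from every target;
2. one Dijkstra run from s gives d_s(u), the best cost reaching u through
   some source; one Dijkstra run from t on the reversed graph gives d_t(v),
   the best cost from v to some target;
3. the best path through (u, v) is the s->u path, the edge, and the v->t
   path, with cost d_s(u) + cost(u, v) + d_t(v);
4. distinct edges may share a best path; paths are deduplicated, ranked by
   increasing cost, and the union of the top k forms the signaling network.

Because every retained path is the optimum for at least one edge, growing k
always adds at least one new edge to the network (barring exact cost ties),
unlike top-k path enumeration where a new path may reuse only known edges.

Note the source-side and target-side half-paths are each simple (shortest
paths under nonnegative costs) but their concatenation may revisit a node;
such paths are kept — the per-edge optimum is defined by the concatenation.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, TextIO

import networkx as nx

from .interactome import Interactome
from .toxcast import ToxicantProfile

SUPER_SOURCE = "__source__"
SUPER_TARGET = "__target__"

DEFAULT_K = 150

#: relative tolerance for comparing path costs / scores
COST_RTOL = 1e-9


class DisconnectedError(RuntimeError):
    """No source can reach any target in the interactome."""


@dataclass(frozen=True)
class RankedPath:
    """A source-to-target node sequence with its cost, score and rank."""

    nodes: tuple[str, ...]
    cost: float
    rank: int = 0

    @property
    def score(self) -> float:
        return math.exp(-self.cost)

    @property
    def edges(self) -> tuple[tuple[str, str], ...]:
        return tuple(zip(self.nodes[:-1], self.nodes[1:]))

    def __len__(self) -> int:
        return len(self.nodes)


@dataclass
class SignalingNetwork:
    """The union of the top-k ranked paths for one chemical.

    ``paths`` holds the retained (top-k) paths in rank order; ``all_paths``
    every deduplicated candidate, so any smaller or larger cutoff can be
    re-applied without recomputation.  ``edge_first_rank`` maps each network
    edge to the rank of the first path that contains it.  ``disconnected``
    marks the explicit no-candidates outcome (sources cannot reach targets).
    """

    chemical: str
    k: int
    paths: list[RankedPath] = field(default_factory=list)
    all_paths: list[RankedPath] = field(default_factory=list)
    edge_first_rank: dict[tuple[str, str], int] = field(default_factory=dict)
    disconnected: bool = False

    @property
    def node_set(self) -> set[str]:
        return {n for p in self.paths for n in p.nodes}

    @property
    def edge_set(self) -> set[tuple[str, str]]:
        return set(self.edge_first_rank)

    def score_at_rank(self, k: int) -> float:
        """s_k: the score of the k-th ranked candidate path (clamped to the
        last candidate when fewer than k exist)."""
        if not self.all_paths:
            raise DisconnectedError(f"{self.chemical}: no candidate paths")
        return self.all_paths[min(k, len(self.all_paths)) - 1].score

    def count_at_least(self, score: float) -> int:
        """Number of candidate paths with score >= ``score`` (up to tolerance)."""
        return count_paths_at_least(self.all_paths, score)


def count_paths_at_least(paths: Sequence[RankedPath], score: float) -> int:
    cutoff = score * (1.0 - COST_RTOL)
    return sum(1 for p in paths if p.score >= cutoff)


def augment_with_super_nodes(
    g: Interactome, sources: Iterable[str], targets: Iterable[str]
) -> nx.DiGraph:
    """Copy the graph and wire super source/target with weight-1 (cost-0) edges."""
    sources, targets = set(sources), set(targets)
    if not sources or not targets:
        raise ValueError("sources and targets must be nonempty")
    nodes = set(g.graph.nodes)
    if not sources <= nodes or not targets <= nodes:
        missing = (sources | targets) - nodes
        raise ValueError(f"sources/targets not in graph: {sorted(missing)}")
    if SUPER_SOURCE in nodes or SUPER_TARGET in nodes:
        raise ValueError("graph already contains a super node identifier")
    aug = g.graph.copy()
    for u in sources:
        aug.add_edge(SUPER_SOURCE, u, weight=1.0, cost=0.0, orientation="super")
    for v in targets:
        aug.add_edge(v, SUPER_TARGET, weight=1.0, cost=0.0, orientation="super")
    return aug


def _dijkstra(graph: nx.DiGraph, root: str, reverse: bool = False):
    """Single-source Dijkstra with a deterministic predecessor tree.

    Among predecessors achieving the optimal distance, the smallest node ID
    that settles before the node wins; the predecessor tree is acyclic even
    in zero-cost components.  With ``reverse`` the graph is traversed against
    edge direction (distances *to* ``root``), and the returned map holds
    successors instead of predecessors.
    """
    succ = graph.pred if reverse else graph.succ
    dist: dict[str, float] = {root: 0.0}
    pred: dict[str, str | None] = {root: None}
    settled: set[str] = set()
    heap: list[tuple[float, str]] = [(0.0, root)]
    while heap:
        d, u = heapq.heappop(heap)
        if u in settled:
            continue
        settled.add(u)
        for v, data in succ[u].items():
            cost = data["cost"]
            if cost < 0:
                raise ValueError(f"negative edge cost on ({u}, {v})")
            nd = d + cost
            if v not in dist or nd < dist[v]:
                dist[v] = nd
                pred[v] = u
                heapq.heappush(heap, (nd, v))
            elif v not in settled and nd == dist[v] and u < pred[v]:
                pred[v] = u  # equal-cost tie: smallest settled predecessor ID
    return dist, pred


def shortest_distances_from_source(aug: nx.DiGraph):
    """d_s(v) and a predecessor map for best paths from the super source."""
    return _dijkstra(aug, SUPER_SOURCE)


def shortest_distances_to_target(aug: nx.DiGraph):
    """d_t(v) and a successor map for best paths to the super target.

    Computed by running Dijkstra from the super target with every edge
    reversed, then reading the tree in the original orientation.
    """
    return _dijkstra(aug, SUPER_TARGET, reverse=True)


def _walk(tree: Mapping[str, str | None], node: str) -> list[str]:
    out = [node]
    while tree[node] is not None:
        node = tree[node]
        out.append(node)
    return out


def per_edge_best_paths(
    aug: nx.DiGraph,
    d_s: Mapping[str, float],
    pred: Mapping[str, str | None],
    d_t: Mapping[str, float],
    succ: Mapping[str, str | None],
    include_single_node: bool = False,
) -> tuple[list[RankedPath], dict[tuple[str, ...], list[tuple[str, str]]]]:
    """Best source-to-target path through every reachable edge.

    Returns the deduplicated candidate paths (super nodes stripped, unranked)
    and, for the edge-growth guarantee, the map from each path's node tuple
    to the edges for which that path is the optimum.  Edges whose tail cannot
    be reached from a source or whose head cannot reach a target yield no
    candidate.  Degenerate single-node paths (a protein that is both source
    and target) are excluded unless ``include_single_node``.
    """
    best: dict[tuple[str, ...], float] = {}
    witnesses: dict[tuple[str, ...], list[tuple[str, str]]] = {}
    for u, v, data in aug.edges(data=True):
        if SUPER_SOURCE in (u, v) or SUPER_TARGET in (u, v):
            continue
        if u not in d_s or v not in d_t:
            continue
        cost = d_s[u] + data["cost"] + d_t[v]
        left = _walk(pred, u)[::-1]   # s .. u
        right = _walk(succ, v)        # v .. t
        nodes = tuple(left[1:] + right[:-1])  # strip super nodes
        best[nodes] = cost
        witnesses.setdefault(nodes, []).append((u, v))
    if include_single_node:
        # a node in both S and T forms the zero-edge path s->u->t
        for u in aug.succ[SUPER_SOURCE]:
            if aug.has_edge(u, SUPER_TARGET):
                nodes = (u,)
                best[nodes] = d_s[u] + d_t[u]
                witnesses.setdefault(nodes, [])
    paths = [RankedPath(nodes=n, cost=c) for n, c in best.items()]
    return paths, witnesses


def rank_and_truncate(
    candidates: Sequence[RankedPath],
    k: int,
    chemical: str = "",
    require_candidates: bool = True,
) -> SignalingNetwork:
    """Rank candidates by increasing cost and keep the union of the top k.

    Ties in cost are broken lexicographically on the node sequence so runs
    are reproducible.  With no candidates at all, the result is flagged
    ``disconnected`` (or raises :class:`DisconnectedError` when
    ``require_candidates``).
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if not candidates:
        if require_candidates:
            raise DisconnectedError(
                f"{chemical or 'network'}: sources cannot reach targets"
            )
        return SignalingNetwork(chemical=chemical, k=k, disconnected=True)
    ordered = sorted(candidates, key=lambda p: (p.cost, p.nodes))
    ranked = [RankedPath(nodes=p.nodes, cost=p.cost, rank=i)
              for i, p in enumerate(ordered, start=1)]
    top = ranked[:k]
    first_rank: dict[tuple[str, str], int] = {}
    for p in top:
        for e in p.edges:
            first_rank.setdefault(e, p.rank)
    return SignalingNetwork(
        chemical=chemical,
        k=k,
        paths=top,
        all_paths=ranked,
        edge_first_rank=first_rank,
    )


def run_edgelinker(
    g: Interactome,
    profile_or_sources: ToxicantProfile | Iterable[str],
    targets: Iterable[str] | None = None,
    k: int = DEFAULT_K,
    include_single_node: bool = False,
    require_candidates: bool = True,
) -> SignalingNetwork:
    """Build the signaling network for one chemical.

    Accepts either a :class:`ToxicantProfile` (its sources/targets are first
    restricted to graph nodes) or explicit source and target collections.
    """
    if isinstance(profile_or_sources, ToxicantProfile):
        profile = profile_or_sources.restricted_to(g.graph.nodes)
        sources, targets = profile.sources, profile.targets
        chemical = profile.chemical
    else:
        sources = set(profile_or_sources) & set(g.graph.nodes)
        targets = set(targets or ()) & set(g.graph.nodes)
        chemical = ""
    aug = augment_with_super_nodes(g, sources, targets)
    d_s, pred = shortest_distances_from_source(aug)
    d_t, succ = shortest_distances_to_target(aug)
    candidates, _ = per_edge_best_paths(
        aug, d_s, pred, d_t, succ, include_single_node=include_single_node
    )
    return rank_and_truncate(candidates, k, chemical, require_candidates)


@dataclass(frozen=True)
class BonusConfig:
    """How strongly severity z-scores pull paths toward responsive proteins.

    The weight of every edge incident to a responsive protein with a z-score
    is multiplied by ``1 + strength * (1 - exp(-max(z, 0) / scale))`` — a
    factor that rises monotonically from 1 toward ``1 + strength`` — then
    re-capped at ``cap`` (never below the original weight).  ``strength`` 0
    disables the bonus.
    """

    strength: float = 0.0
    scale: float = 1.0
    cap: float = 0.99


def apply_responsive_bonus(
    g: Interactome, profile: ToxicantProfile, config: BonusConfig = BonusConfig()
) -> Interactome:
    """Up-weight edges touching strongly perturbed responsive proteins.

    Only edge weights change (ranking effect); topology is untouched.
    Proteins without z-scores get no bonus.
    """
    from .interactome import edge_cost

    if config.strength == 0.0 or not profile.zscores:
        return g
    eligible = profile.sources | profile.targets | profile.responsive_intermediates
    factor: dict[str, float] = {}
    for p in eligible:
        z = profile.zscores.get(p)
        if z is not None:
            factor[p] = 1.0 + config.strength * (1.0 - math.exp(-max(z, 0.0) / config.scale))
    out = g.copy()
    for u, v, d in out.graph.edges(data=True):
        f = max(factor.get(u, 1.0), factor.get(v, 1.0))
        if f > 1.0:
            d["weight"] = max(d["weight"], min(d["weight"] * f, config.cap))
            d["cost"] = edge_cost(d["weight"])
    return out


def write_ranked_paths(net: SignalingNetwork, handle: TextIO | str,
                       all_candidates: bool = True) -> None:
    """Ranked-paths TSV: ``rank score cost node1|node2|...``.

    By default every candidate path is written (not just the top k) so any
    cutoff can be re-applied later.
    """
    close = False
    if isinstance(handle, str):
        handle = open(handle, "w")
        close = True
    try:
        handle.write("rank\tscore\tcost\tpath\n")
        for p in net.all_paths if all_candidates else net.paths:
            handle.write(f"{p.rank}\t{p.score:.10g}\t{p.cost:.10g}\t{'|'.join(p.nodes)}\n")
    finally:
        if close:
            handle.close()


def write_ranked_edges(net: SignalingNetwork, handle: TextIO | str) -> None:
    """Ranked-edges TSV: ``tail head first_path_rank`` (edges of the top-k union)."""
    close = False
    if isinstance(handle, str):
        handle = open(handle, "w")
        close = True
    try:
        handle.write("tail\thead\tfirst_path_rank\n")
        for (u, v), r in sorted(net.edge_first_rank.items(), key=lambda kv: (kv[1], kv[0])):
            handle.write(f"{u}\t{v}\t{r}\n")
    finally:
        if close:
            handle.close()
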