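"""Weighted protein interactome: loading, evidence combination, edge costs.

The interactome is a mixed directed/undirected protein interaction network
G = (V, E, w).  Directed edges are regulatory/signaling interactions (or
physical interactions with a predicted orientation); undirected edges are
physical interactions of unknown direction.  Each edge carries a confidence
weight w in (0, 1] derived from the evidence supporting it: the larger the
weight, the more evidence for the interaction.

For path finding every undirected record (u, v) is converted to the two
directed edges u->v and v->u with equal weight, and the cost of a directed
edge is -log(w), so the lowest-cost path is also the highest-scoring path
(score = product of weights).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, TextIO

import networkx as nx

logger = logging.getLogger(__name__)

DIRECTED = "directed"
UNDIRECTED = "undirected"

#: confidence assumed for an evidence source absent from the confidence map
DEFAULT_SOURCE_CONFIDENCE = 0.6
#: weights never reach 1 exactly so every real edge keeps a positive cost
DEFAULT_WEIGHT_CAP = 0.99
DEFAULT_UNDIRECTED_PENALTY = 0.75


@dataclass(frozen=True)
class EvidenceRecord:
    """One piece of support for an interaction (a database or experiment type)."""

    tail: str
    head: str
    source: str


@dataclass
class Interactome:
    """A directed graph of proteins with confidence-weighted edges.

    Edges live in a :class:`networkx.DiGraph`; each carries ``weight`` in
    (0, 1], ``cost`` = -log(weight), ``orientation`` (``directed`` for native
    directed interactions, ``undirected`` for the two directed edges derived
    from an undirected record) and an ``evidence`` tuple of source names.
    """

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)
    penalty_applied: bool = False

    # -- construction -----------------------------------------------------

    def add_edge(
        self,
        tail: str,
        head: str,
        weight: float,
        orientation: str = DIRECTED,
        evidence: Iterable[str] = (),
    ) -> None:
        if tail == head:
            raise ValueError(f"self-loop {tail!r} not allowed")
        if not 0.0 < weight <= 1.0:
            raise ValueError(f"weight {weight} outside (0, 1] for edge {tail}->{head}")
        self.graph.add_edge(
            tail,
            head,
            weight=float(weight),
            cost=edge_cost(weight),
            orientation=orientation,
            evidence=tuple(evidence),
        )
        if orientation == UNDIRECTED:
            self.graph.add_edge(
                head,
                tail,
                weight=float(weight),
                cost=edge_cost(weight),
                orientation=UNDIRECTED,
                evidence=tuple(evidence),
            )

    # -- views ------------------------------------------------------------

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def directed_edges(self) -> list[tuple[str, str]]:
        return [
            (u, v)
            for u, v, o in self.graph.edges(data="orientation")
            if o == DIRECTED
        ]

    def undirected_pairs(self) -> list[tuple[str, str]]:
        """Unordered endpoint pairs of undirected-derived edges (u < v)."""
        return sorted(
            {
                (min(u, v), max(u, v))
                for u, v, o in self.graph.edges(data="orientation")
                if o == UNDIRECTED
            }
        )

    def weight(self, u: str, v: str) -> float:
        return self.graph.edges[u, v]["weight"]

    def copy(self) -> "Interactome":
        return Interactome(graph=self.graph.copy(), penalty_applied=self.penalty_applied)

    def validate(self) -> None:
        """Check structural invariants; raise ``ValueError`` on violation."""
        for u, v, d in self.graph.edges(data=True):
            if u == v:
                raise ValueError(f"self-loop at {u}")
            if not 0.0 < d["weight"] <= 1.0:
                raise ValueError(f"weight out of range on {u}->{v}")
            if d["orientation"] == UNDIRECTED and not self.graph.has_edge(v, u):
                raise ValueError(f"undirected edge {u}--{v} missing its mirror")


def edge_cost(weight: float) -> float:
    """Cost of an edge of the given weight: -ln(w); 0 for weight 1.

    Raises ``ValueError`` outside (0, 1].  Natural log; any base gives the
    same path ranking.
    """
    if not 0.0 < weight <= 1.0:
        raise ValueError(f"weight must be in (0, 1], got {weight}")
    return -math.log(weight)


def combine_evidence_weights(
    sources: Iterable[str],
    source_confidences: Mapping[str, float] | None = None,
    cap: float = DEFAULT_WEIGHT_CAP,
) -> float:
    """Combine per-source confidences into one edge weight (noisy-OR).

    weight = 1 - prod_s (1 - c_s) over the *distinct* supporting sources,
    capped at ``cap`` so the cost -log(w) stays strictly positive.  Monotone
    nondecreasing in the number of sources and invariant to their order.

    Parameters
    ----------
    sources
        Evidence source names supporting the edge (duplicates collapsed).
    source_confidences
        Map source name -> confidence in (0, 1).  When ``None``, every source
        gets :data:`DEFAULT_SOURCE_CONFIDENCE`.  With an explicit map, an
        unknown source raises ``KeyError`` listing the known names.
    """
    distinct = sorted(set(sources))
    if not distinct:
        raise ValueError("at least one evidence source is required")
    miss = 1.0
    for s in distinct:
        if source_confidences is None:
            c = DEFAULT_SOURCE_CONFIDENCE
        elif s in source_confidences:
            c = source_confidences[s]
        else:
            raise KeyError(
                f"unknown evidence source {s!r}; known sources: "
                f"{sorted(source_confidences)}"
            )
        if not 0.0 < c < 1.0:
            raise ValueError(f"confidence for {s!r} must be in (0, 1), got {c}")
        miss *= 1.0 - c
    return min(1.0 - miss, cap)


def load_interactome(
    handle: TextIO | str,
    source_confidences: Mapping[str, float] | None = None,
    cap: float = DEFAULT_WEIGHT_CAP,
) -> Interactome:
    """Parse an evidence edge table into a weighted :class:`Interactome`.

    Expected TSV columns (header required):
    ``tail<TAB>head<TAB>directed(0/1)<TAB>evidence_sources`` where the last
    column is a comma-separated list of evidence source names.

    Duplicate records for the same (orientation-aware) edge are merged with
    the union of their evidence.  A directed record and an undirected record
    on the same endpoint pair: the directed record wins and the undirected
    record contributes only evidence (the undirected edge is considered
    replaced by its predicted direction).  Self-loops are dropped with a
    warning.  Malformed rows raise ``ValueError`` naming the line number.
    """
    close = False
    if isinstance(handle, str):
        handle = open(handle)
        close = True
    try:
        directed: dict[tuple[str, str], set[str]] = {}
        undirected: dict[frozenset, set[str]] = {}
        header = handle.readline()
        if not header:
            raise ValueError("empty interactome file")
        n_rows = 0
        for lineno, line in enumerate(handle, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 4 or not all(parts[:4]):
                raise ValueError(f"line {lineno}: expected 4 tab-separated fields")
            tail, head, flag, ev = parts[0], parts[1], parts[2], parts[3]
            if flag not in ("0", "1"):
                raise ValueError(f"line {lineno}: directed flag must be 0 or 1, got {flag!r}")
            if tail == head:
                logger.warning("line %d: dropping self-loop on %s", lineno, tail)
                continue
            sources = {s.strip() for s in ev.split(",") if s.strip()}
            if not sources:
                raise ValueError(f"line {lineno}: no evidence sources")
            n_rows += 1
            if flag == "1":
                directed.setdefault((tail, head), set()).update(sources)
            else:
                undirected.setdefault(frozenset((tail, head)), set()).update(sources)
        if n_rows == 0:
            raise ValueError("interactome file contains no edge records")
    finally:
        if close:
            handle.close()

    # directed wins over undirected on the same pair; the undirected record
    # is absorbed as extra evidence for the directed edge(s)
    for pair in list(undirected):
        u, v = tuple(sorted(pair))
        hits = [k for k in ((u, v), (v, u)) if k in directed]
        if hits:
            ev = undirected.pop(pair)
            for k in hits:
                directed[k].update(ev)

    g = Interactome()
    for (u, v), ev in sorted(directed.items()):
        g.add_edge(u, v, combine_evidence_weights(ev, source_confidences, cap),
                   DIRECTED, sorted(ev))
    for pair, ev in sorted(undirected.items(), key=lambda kv: tuple(sorted(kv[0]))):
        u, v = tuple(sorted(pair))
        g.add_edge(u, v, combine_evidence_weights(ev, source_confidences, cap),
                   UNDIRECTED, sorted(ev))
    g.validate()
    return g


def load_weighted_interactome(handle: TextIO | str) -> Interactome:
    """Read a pre-weighted edge list: ``tail head weight cost orientation`` TSV.

    This is the format :func:`write_weighted_interactome` produces and the
    format the ``edgelinker run`` command consumes.  The mirror of an
    undirected edge may appear explicitly or be implied; both forms load to
    the same graph.
    """
    close = False
    if isinstance(handle, str):
        handle = open(handle)
        close = True
    try:
        g = Interactome()
        header = handle.readline()
        if not header:
            raise ValueError("empty interactome file")
        for lineno, line in enumerate(handle, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise ValueError(f"line {lineno}: expected 5 tab-separated fields")
            tail, head, w, _cost, orient = parts[0], parts[1], float(parts[2]), parts[3], parts[4]
            if orient not in (DIRECTED, UNDIRECTED):
                raise ValueError(f"line {lineno}: bad orientation {orient!r}")
            if orient == UNDIRECTED and g.graph.has_edge(tail, head):
                continue  # mirror already added
            g.add_edge(tail, head, w, orient)
        g.validate()
        return g
    finally:
        if close:
            handle.close()


def write_weighted_interactome(g: Interactome, handle: TextIO | str) -> None:
    """Write ``tail head weight cost orientation`` TSV (both mirror edges)."""
    close = False
    if isinstance(handle, str):
        handle = open(handle, "w")
        close = True
    try:
        handle.write("tail\thead\tweight\tcost\torientation\n")
        for u, v, d in sorted(g.graph.edges(data=True)):
            handle.write(
                f"{u}\t{v}\t{d['weight']:.10g}\t{d['cost']:.10g}\t{d['orientation']}\n"
            )
    finally:
        if close:
            handle.close()


def apply_undirected_penalty(
    g: Interactome, penalty: float = DEFAULT_UNDIRECTED_PENALTY
) -> Interactome:
    """Down-weight undirected-derived edges by a multiplicative penalty.

    Directed (oriented) interactions are better supported as signaling links,
    so paths are steered toward them by multiplying every undirected-derived
    edge weight by ``penalty`` in (0, 1).  Returns a new interactome; a guard
    flag prevents accidental double application.
    """
    if not 0.0 < penalty < 1.0:
        raise ValueError(f"penalty must be in (0, 1), got {penalty}")
    if g.penalty_applied:
        raise ValueError("undirected penalty already applied to this interactome")
    out = g.copy()
    for u, v, d in out.graph.edges(data=True):
        if d["orientation"] == UNDIRECTED:
            d["weight"] *= penalty
            d["cost"] = edge_cost(d["weight"])
    out.penalty_applied = True
    return out
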