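"""Synthetic fixtures with the statistical structure the pipeline assumes.

Generates, at arbitrary (small) scale and fully seeded:

* mixed directed/undirected weighted interactomes with planted high-weight
  receptor-to-TF paths whose per-edge weights strictly exceed every
  background edge weight, so the planted paths rank first and recovery is
  checkable against ground truth;
* screening hit/z-score matrices plus assay annotations that round-trip
  through the hit-matrix parser to requested source/target sets, including
  the deliberate edge cases (up/down assay pairs, -1/NA cells, non-NVS
  receptor assays, nuclear-receptor family rows);
* toy chemical-gene interaction tables with "(de)phosphorylation"
  interaction strings for the evaluation module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .interactome import DIRECTED, UNDIRECTED, Interactome
from .toxcast import AssayAnnotation, ToxicantProfile

#: background edge weights: 0.05 + 0.5 * Beta(2, 2), i.e. in (0.05, 0.55)
BACKGROUND_WEIGHT_LOW = 0.05
BACKGROUND_WEIGHT_SPAN = 0.5
#: planted edge weights: uniform in [0.93, 0.99]
PLANTED_WEIGHT_RANGE = (0.93, 0.99)
#: max planted path length keeping the planted score above any single
#: background edge weight (0.93**5 = 0.696 > 0.55)
MAX_PLANTED_LENGTH = 5


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic study.

    ``planted_path_lengths`` gives the edge count of each planted
    source-to-target path (each <= 5 so the whole path outscores any single
    background edge).  ``seed`` is mandatory: the generator is fully
    deterministic given the spec.
    """

    n_nodes: int = 60
    n_directed: int = 180
    n_undirected: int = 60
    planted_path_lengths: tuple[int, ...] = (3, 4)
    weight_beta: tuple[float, float] = (2.0, 2.0)
    n_chemicals: int = 4
    n_filler_assays: int = 20
    seed: int = 0

    def validate(self) -> None:
        for length in self.planted_path_lengths:
            if not 1 <= length <= MAX_PLANTED_LENGTH:
                raise ValueError(
                    f"planted path length {length} outside [1, {MAX_PLANTED_LENGTH}]"
                )
        need = sum(l + 1 for l in self.planted_path_lengths)
        if need > self.n_nodes:
            raise ValueError(
                f"{self.n_nodes} nodes cannot host node-disjoint planted paths "
                f"needing {need} nodes"
            )
        if self.n_nodes < 3:
            raise ValueError("need at least 3 nodes")


def _node_names(n: int) -> list[str]:
    return [f"P{i:04d}" for i in range(n)]


def generate_interactome(
    spec: SyntheticSpec, rng: np.random.Generator | None = None
) -> tuple[Interactome, list[tuple[str, ...]]]:
    """Random weighted graph with planted high-weight paths.

    Returns the interactome and the planted paths (node tuples).  Planted
    paths are node-disjoint from each other; background edges never
    duplicate a planted edge and their weights (max 0.55) are strictly below
    every planted edge weight (min 0.93), so each planted path is the
    top-ranked path between its own endpoints.
    """
    spec.validate()
    rng = rng or np.random.default_rng(spec.seed)
    nodes = _node_names(spec.n_nodes)
    g = Interactome()
    g.graph.add_nodes_from(nodes)

    # plant node-disjoint paths on a random node permutation
    perm = [nodes[i] for i in rng.permutation(spec.n_nodes)]
    planted: list[tuple[str, ...]] = []
    pos = 0
    lo, hi = PLANTED_WEIGHT_RANGE
    for length in spec.planted_path_lengths:
        path = tuple(perm[pos: pos + length + 1])
        pos += length + 1
        for u, v in zip(path[:-1], path[1:]):
            g.add_edge(u, v, float(rng.uniform(lo, hi)), DIRECTED, ("planted",))
        planted.append(path)

    a, b = spec.weight_beta

    def background_weight() -> float:
        return float(BACKGROUND_WEIGHT_LOW + BACKGROUND_WEIGHT_SPAN * rng.beta(a, b))

    def free_pair(symmetric: bool) -> tuple[str, str]:
        while True:
            i, j = rng.integers(0, spec.n_nodes, size=2)
            if i == j:
                continue
            u, v = nodes[i], nodes[j]
            if g.graph.has_edge(u, v) or (symmetric and g.graph.has_edge(v, u)):
                continue
            return u, v

    for _ in range(spec.n_directed):
        u, v = free_pair(symmetric=False)
        g.add_edge(u, v, background_weight(), DIRECTED, ("synthetic",))
    for _ in range(spec.n_undirected):
        u, v = free_pair(symmetric=True)
        g.add_edge(u, v, background_weight(), UNDIRECTED, ("synthetic",))
    g.validate()
    return g, planted


@dataclass(frozen=True)
class ProfileRequest:
    """Requested ground-truth protein sets for one synthetic chemical."""

    chemical: str
    sources: tuple[str, ...]
    targets: tuple[str, ...]
    responsive_intermediates: tuple[str, ...] = ()
    nonresponsive: tuple[str, ...] = ()


def generate_hit_matrix(
    requests: Sequence[ProfileRequest],
    rng: np.random.Generator,
    n_filler_assays: int = 20,
    include_edge_cases: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame, list[AssayAnnotation]]:
    """Hit matrix, z-score matrix and annotations realizing requested profiles.

    Each requested source gets an NVS receptor assay, each target a TF assay,
    intermediates enzyme assays; hit values are set so the hit-matrix parser
    recovers exactly the requested sets for every chemical.  With
    ``include_edge_cases`` the tables additionally contain an up/down assay
    pair, an undetermined (-1/NA only) protein, a responsive non-NVS receptor
    and a responsive nuclear-receptor-family protein — none of which may
    enter any S_x/T_x.  Filler assays (unmapped proteins, random 0/1 values)
    pad the tested-assay count.
    """
    chemicals = [r.chemical for r in requests]
    annotations: list[AssayAnnotation] = []
    columns: dict[str, dict[str, float]] = {}

    def add_assay(assay_id: str, protein: str | None, type_sub: str, family: str,
                  vendor: str, values: Mapping[str, float]) -> None:
        annotations.append(AssayAnnotation(assay_id, protein, type_sub, family, vendor))
        columns[assay_id] = dict(values)

    def hit_values(responsive_for: set[str], nonresp_for: set[str]) -> dict[str, float]:
        return {
            c: 1.0 if c in responsive_for else (0.0 if c in nonresp_for else np.nan)
            for c in chemicals
        }

    all_sources = {p for r in requests for p in r.sources}
    all_targets = {p for r in requests for p in r.targets}
    all_inter = {p for r in requests for p in r.responsive_intermediates}
    all_nonresp = {p for r in requests for p in r.nonresponsive}

    by_protein_resp: dict[str, set[str]] = {}
    by_protein_nonresp: dict[str, set[str]] = {}
    for r in requests:
        for p in r.sources + r.targets + r.responsive_intermediates:
            by_protein_resp.setdefault(p, set()).add(r.chemical)
        for p in r.nonresponsive:
            by_protein_nonresp.setdefault(p, set()).add(r.chemical)

    for p in sorted(all_sources):
        add_assay(f"NVS_rcpt_{p}", p, "receptor", "gpcr", "NVS",
                  hit_values(by_protein_resp[p], by_protein_nonresp.get(p, set())))
    for p in sorted(all_targets):
        add_assay(f"ATG_tf_{p}", p, "transcription factor", "dna binding", "ATG",
                  hit_values(by_protein_resp[p], by_protein_nonresp.get(p, set())))
    for p in sorted(all_inter - all_sources - all_targets):
        add_assay(f"TOX_enz_{p}", p, "enzyme", "kinase", "TOX",
                  hit_values(by_protein_resp[p], by_protein_nonresp.get(p, set())))
    for p in sorted(all_nonresp - all_sources - all_targets - all_inter):
        add_assay(f"TOX_enz_{p}", p, "enzyme", "kinase", "TOX",
                  hit_values(set(), by_protein_nonresp[p]))

    if include_edge_cases:
        everywhere = set(chemicals)
        # up/down pair, responsive via the "either member hits" rule
        add_assay("ATG_pair_XUPDN_up", "X_UPDN", "enzyme", "kinase", "ATG",
                  hit_values(everywhere, set()))
        add_assay("ATG_pair_XUPDN_dn", "X_UPDN", "enzyme", "kinase", "ATG",
                  hit_values(set(), everywhere))
        # undetermined protein: -1 and NA only
        add_assay("TOX_und_XUND", "X_UND", "enzyme", "kinase", "TOX",
                  {c: (-1.0 if i % 2 == 0 else np.nan) for i, c in enumerate(chemicals)})
        # responsive receptor from the wrong vendor: must not reach S_x
        add_assay("ATG_rcpt_XNONNVS", "X_NONNVS", "receptor", "gpcr", "ATG",
                  hit_values(everywhere, set()))
        # responsive nuclear-receptor family protein: excluded from S_x and T_x
        add_assay("NVS_nr_XNR", "X_NR", "receptor", "nuclear receptor", "NVS",
                  hit_values(everywhere, set()))

    for i in range(n_filler_assays):
        vals = {c: float(rng.integers(0, 2)) for c in chemicals}
        add_assay(f"FILL_{i:03d}", None, "background measurement", "na", "FILL", vals)

    hits = pd.DataFrame(columns, index=pd.Index(chemicals, name="chemical"))
    zvals = np.abs(rng.normal(2.0, 1.0, size=hits.shape)) + 0.5
    z = pd.DataFrame(
        np.where(hits.to_numpy() == 1.0, zvals, np.nan),
        index=hits.index,
        columns=hits.columns,
    )
    return hits, z, annotations


def generate_ctd_table(
    gene_sets: Mapping[str, Sequence[str]],
    rng: np.random.Generator,
    n_decoys: int = 3,
) -> pd.DataFrame:
    """Toy chemical-gene table in CTD layout.

    Each listed gene gets a human row whose interaction text mentions
    phosphorylation or dephosphorylation; decoy rows (non-phospho
    interactions and non-human organisms) must be filtered out by the parser.
    """
    rows = []
    verbs = (
        "increased phosphorylation of {g} protein",
        "decreased phosphorylation of {g} protein",
        "results in increased dephosphorylation of {g}",
    )
    for chem, genes in sorted(gene_sets.items()):
        for g in genes:
            rows.append(
                {
                    "ChemicalName": chem,
                    "GeneSymbol": g,
                    "Organism": "Homo sapiens",
                    "Interaction": verbs[rng.integers(0, len(verbs))].format(g=g),
                    "InteractionActions": "increases^phosphorylation",
                }
            )
        for i in range(n_decoys):
            rows.append(
                {
                    "ChemicalName": chem,
                    "GeneSymbol": f"DECOY{i}",
                    "Organism": "Homo sapiens" if i % 2 else "Mus musculus",
                    "Interaction": "increased expression of DECOY mRNA"
                    if i % 2
                    else f"increased phosphorylation of DECOY{i} protein",
                    "InteractionActions": "increases^expression",
                }
            )
    return pd.DataFrame(rows)


@dataclass
class SyntheticStudy:
    """A full generated study: graph, ground truth and screening tables."""

    spec: SyntheticSpec
    interactome: Interactome
    planted_paths: list[tuple[str, ...]]
    profiles: dict[str, ToxicantProfile]
    hits: pd.DataFrame
    zscores: pd.DataFrame
    annotations: list[AssayAnnotation] = field(default_factory=list)
    ctd: pd.DataFrame = field(default_factory=pd.DataFrame)


def generate_study(spec: SyntheticSpec) -> SyntheticStudy:
    """End-to-end synthetic study keyed to one seed.

    Chemicals cycle over the planted paths: chemical i uses planted path
    (i mod #paths)'s endpoints as its source/target pair, plus a couple of
    random responsive intermediates and nonresponsive proteins drawn from
    the rest of the graph.  The CTD table lists each chemical's planted-path
    genes (gene symbol == protein ID) so evaluation overlap is nontrivial.
    """
    from .toxcast import build_profile

    rng = np.random.default_rng(spec.seed)
    g, planted = generate_interactome(spec, rng)
    nodes = sorted(g.nodes)
    planted_nodes = {n for p in planted for n in p}

    requests = []
    for i in range(spec.n_chemicals):
        path = planted[i % len(planted)]
        others = [n for n in nodes if n not in planted_nodes]
        picked = rng.choice(others, size=min(4, len(others)), replace=False)
        requests.append(
            ProfileRequest(
                chemical=f"chem{i:02d}",
                sources=(path[0],),
                targets=(path[-1],),
                responsive_intermediates=tuple(sorted(picked[:2])),
                nonresponsive=tuple(sorted(picked[2:])),
            )
        )
    hits, z, annotations = generate_hit_matrix(
        requests, rng, n_filler_assays=spec.n_filler_assays
    )
    profiles = {
        r.chemical: build_profile(hits, annotations, r.chemical, zmatrix=z)
        for r in requests
    }
    ctd = generate_ctd_table(
        {r.chemical: list(planted[i % len(planted)]) for i, r in enumerate(requests)},
        rng,
    )
    return SyntheticStudy(
        spec=spec,
        interactome=g,
        planted_paths=planted,
        profiles=profiles,
        hits=hits,
        zscores=z,
        annotations=annotations,
        ctd=ctd,
    )
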