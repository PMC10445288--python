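"""Evaluation of signaling networks: phospho-interaction overlap and summaries.

Curated chemical-gene interaction tables (CTD-style) record, among other
effects, which proteins are (de)phosphorylated upon exposure to a chemical.
Since phosphorylation is the primary mechanism of cellular signaling, these
records serve as a proxy gold standard: a reconstructed network is supported
when its proteins overlap the chemical's phospho-interaction genes more than
expected by chance (upper-tail hypergeometric test).
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping, TextIO

import numpy as np
import pandas as pd
from scipy import stats

from .edgelinker import SignalingNetwork
from .interactome import DIRECTED, Interactome
from .toxcast import ToxicantProfile

logger = logging.getLogger(__name__)

CTD_REQUIRED_COLUMNS = ["ChemicalName", "GeneSymbol", "Organism", "Interaction"]
HUMAN_ORGANISMS = {"homo sapiens", "human"}
PHOSPHO_PATTERN = "phosphorylation"  # matches de-phosphorylation too


def parse_ctd(table: pd.DataFrame | TextIO | str) -> dict[str, set[str]]:
    """Per-chemical gene sets with (de)phosphorylation interactions.

    Keeps rows whose organism is human and whose interaction text contains
    "phosphorylation" (case-insensitive substring, which also captures
    "dephosphorylation").  Raises ``ValueError`` naming any missing column.
    """
    df = table if isinstance(table, pd.DataFrame) else pd.read_csv(table, sep="\t", dtype=str)
    missing = [c for c in CTD_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"CTD table missing columns: {missing}")
    human = df["Organism"].str.strip().str.lower().isin(HUMAN_ORGANISMS)
    phospho = df["Interaction"].str.lower().str.contains(PHOSPHO_PATTERN, na=False)
    kept = df[human & phospho]
    out: dict[str, set[str]] = {}
    for chem, genes in kept.groupby("ChemicalName")["GeneSymbol"]:
        out[chem] = {g for g in genes if isinstance(g, str) and g.strip()}
    return out


def overlap_test(
    network_genes: Iterable[str],
    ctd_genes: Iterable[str],
    universe: int,
) -> tuple[int, float]:
    """Hypergeometric enrichment of a network's genes in a chemical's CTD set.

    Draws |network| genes from a universe containing |ctd| successes; the
    p-value is the upper-tail probability of at least the observed overlap.
    """
    network_genes, ctd_genes = set(network_genes), set(ctd_genes)
    if universe < len(network_genes) or universe < len(ctd_genes):
        raise ValueError(
            f"universe ({universe}) smaller than a gene set "
            f"({len(network_genes)} network / {len(ctd_genes)} CTD)"
        )
    if universe < len(network_genes | ctd_genes):
        raise ValueError("universe smaller than the union of the two sets")
    overlap = len(network_genes & ctd_genes)
    p = float(stats.hypergeom.sf(overlap - 1, universe, len(ctd_genes), len(network_genes)))
    return overlap, min(p, 1.0)


def load_gene_mapping(handle: TextIO | str) -> dict[str, str]:
    """Two-column protein-to-gene TSV (header ``protein<TAB>gene``)."""
    df = pd.read_csv(handle, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("mapping table needs two columns: protein, gene")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def map_proteins_to_genes(
    proteins: Iterable[str], mapping: Mapping[str, str] | None
) -> set[str]:
    """Apply a protein-to-gene mapping; unmapped proteins dropped with a log."""
    proteins = set(proteins)
    if mapping is None:
        return proteins
    mapped = {mapping[p] for p in proteins if p in mapping}
    n_lost = sum(1 for p in proteins if p not in mapping)
    if n_lost:
        logger.info("dropped %d proteins without a gene mapping", n_lost)
    return mapped


def network_summary(
    net: SignalingNetwork,
    profile: ToxicantProfile | None = None,
    interactome: Interactome | None = None,
) -> dict[str, float]:
    """Size and recall statistics for one signaling network.

    Returns node/edge counts, the fraction of directed (regulatory) edges
    (when the interactome is given), the average path length (mean number of
    edges over the retained paths) and — with a profile — the fraction of
    responsive and nonresponsive intermediate proteins (screened proteins
    other than the input sources/targets) recalled in the network.  Recall
    fractions with an empty denominator are NaN.
    """
    nodes = net.node_set
    edges = net.edge_set
    summary: dict[str, float] = {
        "n_nodes": len(nodes),
        "n_edges": len(edges),
        "n_paths": len(net.paths),
        "avg_path_length": (
            float(np.mean([len(p.nodes) - 1 for p in net.paths])) if net.paths else math.nan
        ),
    }
    if interactome is not None and edges:
        n_dir = sum(
            1 for (u, v) in edges
            if interactome.graph.edges[u, v]["orientation"] == DIRECTED
        )
        summary["directed_edge_fraction"] = n_dir / len(edges)
    if profile is not None:
        inputs = profile.sources | profile.targets
        resp = profile.responsive_intermediates - inputs
        nonresp = profile.nonresponsive - inputs
        summary["responsive_recall"] = (
            len(resp & nodes) / len(resp) if resp else math.nan
        )
        summary["nonresponsive_recall"] = (
            len(nonresp & nodes) / len(nonresp) if nonresp else math.nan
        )
    return summary


def evaluate_networks(
    networks: Mapping[str, SignalingNetwork],
    ctd: Mapping[str, set[str]],
    universe: int,
    mapping: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-chemical CTD overlap table with BH q-values over tested chemicals.

    Chemicals absent from the CTD table are skipped.  Columns: chemical,
    n_nodes, n_edges, ctd_size, ctd_overlap, ctd_p, ctd_q.
    """
    from .nullmodel import bh_qvalues

    rows = []
    for chem, net in sorted(networks.items()):
        if chem not in ctd:
            continue
        genes = map_proteins_to_genes(net.node_set, mapping)
        overlap, p = overlap_test(genes, ctd[chem], universe)
        rows.append(
            {
                "chemical": chem,
                "n_nodes": len(net.node_set),
                "n_edges": len(net.edge_set),
                "ctd_size": len(ctd[chem]),
                "ctd_overlap": overlap,
                "ctd_p": p,
            }
        )
    df = pd.DataFrame(rows)
    if not df.empty:
        df["ctd_q"] = bh_qvalues(df["ctd_p"].to_numpy())
    return df
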