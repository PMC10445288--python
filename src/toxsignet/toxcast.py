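"""High-throughput screening (hit-matrix) parsing and responsiveness calls.

A screening release reports, for every chemical x assay pair, one of four
values: 1 (hit: AC50 <= 50 uM), 0 (nonhit), -1 (activity could not be
determined), NA (not tested).  Assays map to proteins through an annotation
table; a protein is *responsive* to a chemical when all of its successfully
tested assays are hits, where an up/down assay pair counts as one logical
assay that is a hit if either member is.

Responsive receptors (from cell-free receptor-binding assays, vendor NVS)
become a chemical's path sources S_x and responsive transcription factors
its targets T_x, excluding the nuclear-receptor family whose members act as
TFs themselves rather than upstream signal receivers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence, TextIO

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RESPONSIVE = "responsive"
NONRESPONSIVE = "nonresponsive"
UNDETERMINED = "undetermined"

RECEPTOR_TYPE = "receptor"
TF_TYPE = "transcription factor"
NUCLEAR_RECEPTOR_FAMILY = "nuclear receptor"
RECEPTOR_VENDOR = "NVS"

#: assay-ID suffixes marking the two members of an up/down pair
UPDOWN_SUFFIXES = ("_up", "_dn")

LEGAL_HIT_VALUES = {1.0, 0.0, -1.0}


@dataclass(frozen=True)
class AssayAnnotation:
    """Annotation row for one assay: protein mapping and classification tags."""

    assay_id: str
    protein_id: str | None
    target_type_sub: str = ""
    target_family: str = ""
    vendor: str = ""

    @property
    def is_receptor_assay(self) -> bool:
        return (
            self.protein_id is not None
            and self.target_type_sub.strip().lower() == RECEPTOR_TYPE
            and self.target_family.strip().lower() != NUCLEAR_RECEPTOR_FAMILY
            and self.vendor.strip().upper() == RECEPTOR_VENDOR
        )

    @property
    def is_tf_assay(self) -> bool:
        return (
            self.protein_id is not None
            and self.target_type_sub.strip().lower() == TF_TYPE
            and self.target_family.strip().lower() != NUCLEAR_RECEPTOR_FAMILY
        )


@dataclass
class ToxicantProfile:
    """One chemical's responsive protein sets and severity scores.

    ``sources`` (S_x) and ``targets`` (T_x) are disjoint; intermediates are
    responsive proteins that are neither, and ``nonresponsive`` holds tested
    proteins that failed the all-hits rule.  ``zscores`` carries the
    per-protein severity (max z over the protein's assays) where available.
    """

    chemical: str
    sources: frozenset[str]
    targets: frozenset[str]
    responsive_intermediates: frozenset[str] = frozenset()
    nonresponsive: frozenset[str] = frozenset()
    zscores: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sources & self.targets:
            raise ValueError(
                f"{self.chemical}: sources and targets overlap: "
                f"{sorted(self.sources & self.targets)}"
            )

    def restricted_to(self, nodes: Iterable[str]) -> "ToxicantProfile":
        """Profile with all protein sets intersected with ``nodes``."""
        keep = set(nodes)
        return ToxicantProfile(
            chemical=self.chemical,
            sources=self.sources & keep,
            targets=self.targets & keep,
            responsive_intermediates=self.responsive_intermediates & keep,
            nonresponsive=self.nonresponsive & keep,
            zscores={p: z for p, z in self.zscores.items() if p in keep},
        )


def load_hit_matrix(handle: TextIO | str) -> pd.DataFrame:
    """Read a chemicals-by-assays CSV hit matrix, validating the value set.

    Cells must be 1, 0, -1 or empty (NA).  Returned as a float DataFrame with
    NaN for NA.
    """
    df = pd.read_csv(handle, index_col=0)
    values = set(df.stack(future_stack=True).dropna().unique())
    bad = values - LEGAL_HIT_VALUES
    if bad:
        raise ValueError(f"illegal hit-matrix values: {sorted(bad)}")
    return df.astype(float)


def load_assay_annotations(handle: TextIO | str) -> list[AssayAnnotation]:
    """Read the assay annotation TSV.

    Columns: assay_id, protein_id (may be empty), target_type_sub,
    target_family, vendor.
    """
    df = pd.read_csv(handle, sep="\t", dtype=str).fillna("")
    required = ["assay_id", "protein_id", "target_type_sub", "target_family", "vendor"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"annotation table missing columns: {missing}")
    return [
        AssayAnnotation(
            assay_id=r.assay_id,
            protein_id=r.protein_id or None,
            target_type_sub=r.target_type_sub,
            target_family=r.target_family,
            vendor=r.vendor,
        )
        for r in df.itertuples()
    ]


def _updown_stem(assay_id: str) -> str | None:
    for suf in UPDOWN_SUFFIXES:
        if assay_id.endswith(suf):
            return assay_id[: -len(suf)]
    return None


def _logical_assay_values(
    assay_ids: Sequence[str], row: Mapping[str, float]
) -> list[float]:
    """Collapse up/down pairs and return one value per logical assay.

    A pair is a hit (1) if either member is 1; a nonhit (0) if neither is a
    hit but at least one was successfully tested; untested (NaN) otherwise.
    Values -1 and NA both count as not successfully tested.
    """
    groups: dict[str, list[str]] = {}
    for a in sorted(assay_ids):
        stem = _updown_stem(a)
        groups.setdefault(stem if stem is not None else a, []).append(a)
    out = []
    for _, members in sorted(groups.items()):
        vals = [row.get(a, np.nan) for a in members]
        tested = [v for v in vals if v in (0.0, 1.0)]
        if not tested:
            out.append(np.nan)
        elif any(v == 1.0 for v in tested):
            out.append(1.0)
        else:
            out.append(0.0)
    return out


def call_responsive(
    hits: pd.DataFrame,
    annotations: Sequence[AssayAnnotation],
    chemical: str,
) -> dict[str, Literal["responsive", "nonresponsive", "undetermined"]]:
    """Classify every annotated protein for one chemical.

    responsive: every successfully tested logical assay of the protein is a
    hit (and at least one was tested); nonresponsive: tested but not all
    hits; undetermined: no assay of the protein was successfully tested.

    Raises ``KeyError`` if the chemical is absent from the matrix.
    """
    if chemical not in hits.index:
        raise KeyError(f"chemical {chemical!r} not in hit matrix")
    row = hits.loc[chemical].to_dict()
    by_protein: dict[str, list[str]] = {}
    for ann in annotations:
        if ann.protein_id is not None and ann.assay_id in hits.columns:
            by_protein.setdefault(ann.protein_id, []).append(ann.assay_id)
    calls: dict[str, str] = {}
    for protein, assay_ids in by_protein.items():
        logical = _logical_assay_values(assay_ids, row)
        tested = [v for v in logical if not np.isnan(v)]
        if not tested:
            calls[protein] = UNDETERMINED
        elif all(v == 1.0 for v in tested):
            calls[protein] = RESPONSIVE
        else:
            calls[protein] = NONRESPONSIVE
    return calls


def classify_sources_targets(
    annotations: Sequence[AssayAnnotation],
    responsive: Iterable[str],
    conflict: Literal["exclude", "source", "target"] = "exclude",
) -> tuple[frozenset[str], frozenset[str]]:
    """Split responsive proteins into sources S_x (receptors) and targets T_x (TFs).

    A protein is receptor-classified when it has at least one NVS-vendor
    receptor assay outside the nuclear-receptor family; TF-classified when it
    has at least one TF assay outside that family.  A protein classified as
    both follows the ``conflict`` policy (default: excluded from both sets,
    logged), keeping S_x and T_x disjoint.
    """
    responsive = set(responsive)
    receptor_proteins = {a.protein_id for a in annotations if a.is_receptor_assay}
    tf_proteins = {a.protein_id for a in annotations if a.is_tf_assay}
    s = responsive & receptor_proteins
    t = responsive & tf_proteins
    both = s & t
    if both:
        logger.info("proteins classified both receptor and TF: %s (policy=%s)",
                    sorted(both), conflict)
        if conflict == "exclude":
            s -= both
            t -= both
        elif conflict == "source":
            t -= both
        else:
            s -= both
    return frozenset(s), frozenset(t)


def select_chemicals(
    hits: pd.DataFrame,
    annotations: Sequence[AssayAnnotation],
    min_tested: int = 500,
) -> list[str]:
    """Chemicals usable for network construction.

    Keeps chemicals successfully tested (value 0 or 1) in at least
    ``min_tested`` assays and having at least one responsive receptor and one
    responsive TF after classification.
    """
    tested_counts = hits.isin([0.0, 1.0]).sum(axis=1)
    out = []
    for chemical in hits.index:
        if tested_counts[chemical] < min_tested:
            continue
        calls = call_responsive(hits, annotations, chemical)
        resp = {p for p, c in calls.items() if c == RESPONSIVE}
        s, t = classify_sources_targets(annotations, resp)
        if s and t:
            out.append(chemical)
    return out


def aggregate_zscore(
    zmatrix: pd.DataFrame,
    annotations: Sequence[AssayAnnotation],
    chemical: str,
) -> dict[str, float]:
    """Per-protein severity: the maximum z-score over the protein's assays.

    Proteins with no recorded z-score for this chemical are omitted.
    """
    if chemical not in zmatrix.index:
        raise KeyError(f"chemical {chemical!r} not in z-score matrix")
    row = zmatrix.loc[chemical]
    by_protein: dict[str, list[float]] = {}
    for ann in annotations:
        if ann.protein_id is None or ann.assay_id not in zmatrix.columns:
            continue
        z = row[ann.assay_id]
        if not pd.isna(z):
            by_protein.setdefault(ann.protein_id, []).append(float(z))
    return {p: max(zs) for p, zs in by_protein.items()}


def build_profile(
    hits: pd.DataFrame,
    annotations: Sequence[AssayAnnotation],
    chemical: str,
    zmatrix: pd.DataFrame | None = None,
    conflict: Literal["exclude", "source", "target"] = "exclude",
) -> ToxicantProfile:
    """Assemble a :class:`ToxicantProfile` for one chemical."""
    calls = call_responsive(hits, annotations, chemical)
    resp = {p for p, c in calls.items() if c == RESPONSIVE}
    nonresp = {p for p, c in calls.items() if c == NONRESPONSIVE}
    s, t = classify_sources_targets(annotations, resp, conflict=conflict)
    z = aggregate_zscore(zmatrix, annotations, chemical) if zmatrix is not None else {}
    return ToxicantProfile(
        chemical=chemical,
        sources=s,
        targets=t,
        responsive_intermediates=frozenset(resp - s - t),
        nonresponsive=frozenset(nonresp),
        zscores=z,
    )


def write_profile(profile: ToxicantProfile, handle: TextIO | str) -> None:
    """Write a per-chemical TSV: protein, role, zscore."""
    close = False
    if isinstance(handle, str):
        handle = open(handle, "w")
        close = True
    try:
        handle.write("protein\trole\tzscore\n")
        roles = [
            ("source", sorted(profile.sources)),
            ("target", sorted(profile.targets)),
            ("intermediate", sorted(profile.responsive_intermediates)),
            ("nonresponsive", sorted(profile.nonresponsive)),
        ]
        for role, proteins in roles:
            for p in proteins:
                z = profile.zscores.get(p)
                handle.write(f"{p}\t{role}\t{'' if z is None else f'{z:.6g}'}\n")
    finally:
        if close:
            handle.close()


def read_profile(handle: TextIO | str, chemical: str = "") -> ToxicantProfile:
    """Read a per-chemical TSV written by :func:`write_profile`."""
    df = pd.read_csv(handle, sep="\t", dtype={"protein": str, "role": str})
    by_role: dict[str, set[str]] = {}
    z: dict[str, float] = {}
    for r in df.itertuples():
        by_role.setdefault(r.role, set()).add(r.protein)
        if not pd.isna(r.zscore):
            z[r.protein] = float(r.zscore)
    return ToxicantProfile(
        chemical=chemical,
        sources=frozenset(by_role.get("source", ())),
        targets=frozenset(by_role.get("target", ())),
        responsive_intermediates=frozenset(by_role.get("intermediate", ())),
        nonresponsive=frozenset(by_role.get("nonresponsive", ())),
        zscores=z,
    )
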