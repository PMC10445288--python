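"""Significance of signaling networks against a degree-preserving null.

The null hypothesis: the number of high-scoring receptor-to-TF paths depends
only on the degree of each protein in the interactome, not on who actually
interacts with whom.  To test it, the interactome is randomized by repeated
double edge swaps — edges (a, b) and (c, d) are replaced by (a, d) and
(c, b), rejecting self-loops and duplicates — which preserves every node's
in-/out-degree while shuffling partners.  Directed edges and undirected
(bidirected) records are swapped in separate pools so the mix of edge kinds
matches the original network.

For each chemical, EdgeLinker is rerun on N randomized interactomes with the
same sources and targets; the test statistic is the number of candidate
paths scoring at least s_k, the score of the k-th ranked path in the
original network.  A pseudocount gives the permutation p-value a floor of
1/N.  P-values below that resolution are refined by fitting a generalized
Pareto distribution (GPD) to the tail of the null counts (maximum
likelihood on the ~250 most extreme values, shrinking by 10 while an
Anderson-Darling-type bootstrap goodness-of-fit test rejects).  Finally a
Benjamini-Hochberg correction yields q-values across chemicals.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .edgelinker import (
    SignalingNetwork,
    count_paths_at_least,
    run_edgelinker,
)
from .interactome import DIRECTED, UNDIRECTED, Interactome

logger = logging.getLogger(__name__)

DEFAULT_N_RANDOM = 10_000
DEFAULT_N_EXCEED = 250
DEFAULT_EXCEED_STEP = 10
DEFAULT_GOF_ALPHA = 0.05
DEFAULT_GOF_BOOT = 200
#: accepted swaps per pool, as a multiple of pool size
DEFAULT_SWAP_FACTOR = 10


@dataclass
class NullEnsembleResult:
    """Null-count summary for one chemical's network."""

    chemical: str
    s_k: float
    c0: int
    counts: np.ndarray  # Y_n for each randomized interactome

    @property
    def n_random(self) -> int:
        return len(self.counts)


@dataclass
class SignificanceResult:
    """Permutation, GPD-refined and BH-corrected significance.

    ``gpd_shape`` uses scipy's ``genpareto`` convention (Hosking xi; the
    negated shape of some extreme-value texts); ``gpd_scale`` is the scale
    parameter a.  ``n_exceed`` is 0 when the GPD refinement was not applied
    and ``p_gpd`` equals ``p_perm``.
    """

    p_perm: float
    p_gpd: float
    n_exceed: int = 0
    gpd_scale: float = float("nan")
    gpd_shape: float = float("nan")
    q: float = float("nan")


# ---------------------------------------------------------------------------
# degree-preserving randomization


def _swap_pool(
    edges: list[tuple[str, str, dict]],
    occupied: set[tuple[str, str]],
    symmetric: bool,
    n_swaps: int,
    rng: np.random.Generator,
    max_attempt_factor: int = 100,
) -> None:
    """Double-edge-swap a pool in place.

    ``edges`` holds (tail, head, attrs); attrs travel with the tail's
    outgoing slot, so (a,b)+(c,d) -> (a,d) with (a,b)'s attrs and (c,b) with
    (c,d)'s.  ``occupied`` is the set of ordered pairs taken by *any* edge of
    the graph (both directions for undirected records) and is kept current.
    ``symmetric`` marks the undirected pool, whose pairs occupy both
    orientations.
    """
    m = len(edges)
    if m < 2 or n_swaps == 0:
        return

    def pairs_of(u: str, v: str) -> tuple[tuple[str, str], ...]:
        return ((u, v), (v, u)) if symmetric else ((u, v),)

    accepted = 0
    attempts = 0
    max_attempts = max_attempt_factor * n_swaps
    buf = np.empty(0, dtype=np.int64)
    pos = 0
    while accepted < n_swaps and attempts < max_attempts:
        attempts += 1
        if pos >= len(buf):
            buf = rng.integers(0, m, size=4096)
            pos = 0
        i, j = buf[pos], buf[pos + 1]
        pos += 2
        if i == j:
            continue
        a, b, ab = edges[i]
        c, d, cd = edges[j]
        if a == d or c == b:
            continue  # would create a self-loop
        new1, new2 = (a, d), (c, b)
        if new1 == new2:
            continue
        removed = pairs_of(a, b) + pairs_of(c, d)
        new_pairs = pairs_of(*new1) + pairs_of(*new2)
        if any(p in occupied and p not in removed for p in new_pairs):
            continue  # would duplicate an existing edge
        occupied.difference_update(removed)
        occupied.update(new_pairs)
        edges[i] = (a, d, ab)
        edges[j] = (c, b, cd)
        accepted += 1
    if accepted < n_swaps:
        logger.warning(
            "swap pool mixed only %d/%d accepted swaps (pool size %d)",
            accepted, n_swaps, m,
        )


def swap_randomize(
    g: Interactome,
    seed: int | np.random.Generator,
    n_swaps: int | None = None,
) -> Interactome:
    """Degree-preserving randomization of an interactome.

    Directed edges and undirected records are swapped in separate pools with
    no self-loops and no duplicate edges allowed (checked against the whole
    graph, so a new undirected pair never collides with a directed edge).
    Every node keeps its in-/out-degree in the directed pool and its degree
    in the undirected pool; the multiset of edge weights per pool is
    preserved (weights travel with the tail's outgoing slot).  ``n_swaps``
    is the number of *accepted* swaps per pool (default 10x pool size);
    pools with fewer than two edges are left unchanged with a warning.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_swaps is not None and n_swaps < 0:
        raise ValueError("n_swaps must be >= 0")

    directed = [
        (u, v, dict(d))
        for u, v, d in sorted(g.graph.edges(data=True))
        if d["orientation"] == DIRECTED
    ]
    und_pairs = g.undirected_pairs()
    undirected = [(u, v, dict(g.graph.edges[u, v])) for u, v in und_pairs]

    occupied: set[tuple[str, str]] = set()
    for u, v, _ in directed:
        occupied.add((u, v))
    for u, v, _ in undirected:
        occupied.add((u, v))
        occupied.add((v, u))

    for pool, symmetric in ((directed, False), (undirected, True)):
        target = n_swaps if n_swaps is not None else DEFAULT_SWAP_FACTOR * len(pool)
        if len(pool) < 2:
            if pool and target:
                logger.warning("pool too small to swap (%d edges); left unchanged", len(pool))
            continue
        _swap_pool(pool, occupied, symmetric, target, rng)

    out = Interactome()
    out.graph.add_nodes_from(g.graph.nodes)  # keep isolated nodes
    for u, v, d in directed:
        out.add_edge(u, v, d["weight"], DIRECTED, d.get("evidence", ()))
    for u, v, d in undirected:
        out.add_edge(u, v, d["weight"], UNDIRECTED, d.get("evidence", ()))
    out.penalty_applied = g.penalty_applied
    return out


# ---------------------------------------------------------------------------
# permutation p-values


def null_path_counts(
    g: Interactome,
    sources: Iterable[str],
    targets: Iterable[str],
    s_k: float,
    n_random: int,
    seed: int,
    n_swaps: int | None = None,
    top_k_only: int | None = None,
) -> np.ndarray:
    """Y_n: candidate paths scoring >= s_k in each of ``n_random`` randomized
    interactomes, run with the same sources and targets.

    Counted over the full candidate list by default (``top_k_only`` restricts
    each null network to its k best paths first).  A disconnected randomized
    network contributes 0.
    """
    sources, targets = set(sources), set(targets)
    child_seeds = np.random.SeedSequence(seed).spawn(n_random)
    counts = np.zeros(n_random, dtype=int)
    for n, ss in enumerate(child_seeds):
        rand = swap_randomize(g, np.random.default_rng(ss), n_swaps=n_swaps)
        net = run_edgelinker(rand, sources, targets, k=max(top_k_only or 1, 1),
                             require_candidates=False)
        paths = net.all_paths if top_k_only is None else net.paths
        counts[n] = count_paths_at_least(paths, s_k)
    return counts


def permutation_pvalue(c0: int, counts: Sequence[int] | np.ndarray) -> float:
    """Pseudocounted permutation p-value: (1 + #{Y_n >= c0}) / N, capped at 1.

    The pseudocount stands in for the identity permutation (some random
    network is the original), putting the floor at exactly 1/N.
    """
    counts = np.asarray(counts)
    n = len(counts)
    if n < 1:
        raise ValueError("need at least one null count")
    return min((1 + int(np.sum(counts >= c0))) / n, 1.0)


# ---------------------------------------------------------------------------
# GPD tail refinement


def _ad_statistic(z: np.ndarray, shape: float, scale: float) -> float:
    """Anderson-Darling statistic of exceedances against a fitted GPD."""
    u = stats.genpareto.cdf(np.sort(z), shape, loc=0.0, scale=scale)
    u = np.clip(u, 1e-12, 1 - 1e-12)
    n = len(u)
    i = np.arange(1, n + 1)
    return -n - np.mean((2 * i - 1) * (np.log(u) + np.log1p(-u[::-1])))


def _fit_gpd(z: np.ndarray) -> tuple[float, float]:
    """MLE fit of a zero-location GPD; returns (shape, scale)."""
    shape, _, scale = stats.genpareto.fit(z, floc=0.0)
    return float(shape), float(scale)


def _gof_pvalue(
    z: np.ndarray, shape: float, scale: float, n_boot: int, rng: np.random.Generator
) -> float:
    """Parametric-bootstrap p-value for the AD goodness-of-fit statistic."""
    obs = _ad_statistic(z, shape, scale)
    exceed = 0
    for _ in range(n_boot):
        sim = stats.genpareto.rvs(shape, loc=0.0, scale=scale, size=len(z),
                                  random_state=rng)
        try:
            c_s, a_s = _fit_gpd(sim)
        except Exception:  # pragma: no cover - rare optimizer failure
            exceed += 1
            continue
        if _ad_statistic(sim, c_s, a_s) >= obs:
            exceed += 1
    return (1 + exceed) / (n_boot + 1)


def gpd_refined_pvalue(
    counts: Sequence[int] | np.ndarray,
    c0: int,
    n_exceed_start: int = DEFAULT_N_EXCEED,
    step: int = DEFAULT_EXCEED_STEP,
    gof_alpha: float = DEFAULT_GOF_ALPHA,
    gof_boot: int = DEFAULT_GOF_BOOT,
    seed: int = 0,
) -> SignificanceResult:
    """Refine a permutation p-value below the 1/N resolution with a GPD tail fit.

    The exceedances of the null counts above a threshold between the
    ``n_exceed``-th and (``n_exceed``+1)-th largest values are fitted by
    maximum likelihood; if the bootstrap Anderson-Darling test rejects at
    ``gof_alpha``, ``n_exceed`` shrinks by ``step`` and the fit is retried.
    On success the refined p-value is (n_exceed / N) * (1 - F_GPD(c0 - t)).

    The refinement only applies when c0 lies beyond the tail threshold;
    otherwise (or when no fit ever passes, or the tail is degenerate) the
    plain permutation p-value is returned with ``n_exceed`` 0.
    """
    counts = np.asarray(counts, dtype=float)
    n = len(counts)
    p_perm = permutation_pvalue(c0, counts)
    fallback = SignificanceResult(p_perm=p_perm, p_gpd=p_perm)
    if n <= n_exceed_start:
        raise ValueError(
            f"need more than {n_exceed_start} null counts, got {n}"
        )
    ys = np.sort(counts)
    rng = np.random.default_rng(seed)
    n_exc = n_exceed_start
    while n_exc >= step:
        tail = ys[n - n_exc:]
        below = ys[n - n_exc - 1]
        if tail[-1] == below:
            return fallback  # degenerate: whole tail tied with the bulk
        t = 0.5 * (below + tail[0])
        if c0 <= t:
            return fallback  # c0 not in the extreme tail; refinement n/a
        z = tail - t
        if z[0] <= 0 or np.all(z == z[0]):
            n_exc -= step
            continue
        try:
            shape, scale = _fit_gpd(z)
        except Exception:  # pragma: no cover - optimizer failure
            n_exc -= step
            continue
        if _gof_pvalue(z, shape, scale, gof_boot, rng) > gof_alpha:
            tail_prob = stats.genpareto.sf(c0 - t, shape, loc=0.0, scale=scale)
            p = (n_exc / n) * float(tail_prob)
            p = min(max(p, 5e-324), 1.0)  # keep strictly positive
            return SignificanceResult(
                p_perm=p_perm, p_gpd=p, n_exceed=n_exc,
                gpd_scale=scale, gpd_shape=shape,
            )
        n_exc -= step
    logger.warning("GPD goodness-of-fit never passed; using permutation p-value")
    return fallback


def bh_qvalues(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (order-preserving, q >= p)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# per-chemical driver


def network_significance(
    g: Interactome,
    network: SignalingNetwork,
    sources: Iterable[str],
    targets: Iterable[str],
    n_random: int,
    seed: int,
    k: int | None = None,
    n_swaps: int | None = None,
    refine: bool = True,
    gof_boot: int = DEFAULT_GOF_BOOT,
) -> tuple[NullEnsembleResult, SignificanceResult]:
    """Null ensemble and significance for one chemical's network."""
    k = k if k is not None else network.k
    s_k = network.score_at_rank(k)
    c0 = network.count_at_least(s_k)
    counts = null_path_counts(g, sources, targets, s_k, n_random, seed, n_swaps=n_swaps)
    ens = NullEnsembleResult(chemical=network.chemical, s_k=s_k, c0=c0, counts=counts)
    if refine and n_random > DEFAULT_N_EXCEED:
        sig = gpd_refined_pvalue(counts, c0, gof_boot=gof_boot, seed=seed)
    else:
        p = permutation_pvalue(c0, counts)
        sig = SignificanceResult(p_perm=p, p_gpd=p)
    return ens, sig
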