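# Methods

This note documents the models and procedures `toxsignet` implements, the
defaults and why, the numerical choices, what the synthetic generator does
and does not emulate, and the known limitations.

## Interactome model

The interactome is a directed graph of proteins. Two kinds of records enter
it: natively directed (regulatory/signaling, or physical interactions with a
predicted orientation) and undirected physical interactions. Each undirected
record (u, v) is converted into the two directed edges u→v and v→u with
equal weight, so one shortest-path machinery serves both kinds. Self-loops
are dropped at load time; duplicate records for the same oriented edge merge
with the union of their evidence. When a directed record and an undirected
record cover the same endpoint pair, the directed record wins and the
undirected one contributes only evidence — the undirected edge is treated as
replaced by its predicted direction, so no mirror edge is created.

**Evidence weighting.** Each edge's weight in (0, 1] aggregates per-source
confidences c_s ∈ (0, 1) by a noisy-OR: w = 1 − Π_s (1 − c_s) over distinct
supporting sources. This is monotone — more independent evidence never
lowers confidence — and order-invariant. The weight is capped (default
0.99) so the cost −log w of every real edge stays strictly positive and
longer paths are never free. Sources without a supplied confidence map all
default to 0.6, a deliberately uninformative middle value; with an explicit
map, unknown source names are an error. The aggregation rule is a package
design choice: any calibrated per-source confidence table can be plugged in.

**Undirected penalty.** Undirected-derived edges are down-weighted by a
multiplicative penalty (default 0.75, configurable) to steer paths toward
oriented interactions, which are better evidence of signal flow. The
penalty is applied once; a guard flag makes double application an error
rather than a silent compounding.

**Costs.** cost(u→v) = −ln w(u→v). The natural log is stated explicitly so
costs are reproducible; any base gives the same ranking, since path score
Π w = exp(−Σ cost) is a strictly decreasing transform of path cost.

## Hit-matrix semantics

Each chemical × assay cell holds 1 (hit), 0 (nonhit), −1 (activity not
determinable) or NA (not tested). A protein with several assays is called
**responsive** to a chemical when *all of its successfully tested assays*
(values 0/1) are hits, after collapsing each up/down assay pair (IDs sharing
a stem with `_up`/`_dn` suffixes, configurable) into one logical assay that
is a hit if either member is — either direction of perturbation indicates
the protein responded. −1 and NA are ignored in this rule: treating them as
blocking would make any partially tested protein nonresponsive and leave the
undetermined category unreachable. A protein with no successfully tested
assay is **undetermined**; tested but not all hits is **nonresponsive**.

Chemicals are retained when successfully tested (0 or 1) in at least 500
assays (−1/NA do not count as tested) and when they have at least one
responsive receptor and one responsive TF. Receptor classification requires
an NVS-vendor assay (cell-free, direct receptor–chemical binding) outside
the nuclear-receptor family; TF classification requires a TF assay outside
that family (nuclear receptors act as TFs upon ligand binding, so they are
ambiguous endpoints and are excluded from both roles). A protein classified
as both receptor and TF is excluded from both sets by default (logged;
policy configurable) so S_x ∩ T_x = ∅. Per-protein severity is the maximum
z-score over the protein's assays.

## EdgeLinker

For every edge (u, v), the best S_x→T_x path through it is
d_s(u) + cost(u, v) + d_t(v): two Dijkstra passes (from a super source s
wired to all of S_x, and from a super target t over the reversed graph)
cover all |E| edges in O(|E| log |V|). Candidate paths are deduplicated
(several edges can share one best path), ranked by increasing cost with
ties broken lexicographically on the node sequence, and the union of the
top k forms the network. Default k = 150; all candidates are always written
ranked, so any other cutoff can be applied without recomputation.

Numerical and degenerate-input choices:

* **Predecessor determinism.** A hand-written Dijkstra assigns predecessors
  on strict improvement; among equal-cost predecessors that settled before a
  node, the smallest node ID wins. This keeps the predecessor tree acyclic
  even across zero-cost edges (the super edges) and makes every
  reconstructed path, and hence every output file, byte-reproducible.
* **Half-path overlap.** The s→u and v→t halves are each simple, but their
  concatenation may revisit a node; such paths are kept, because the
  per-edge optimum is defined by the concatenation. In practice overlap is
  rare and harmless for the edge-union network.
* **Degenerate single-node paths.** A protein in both S_x and T_x would
  yield a zero-edge "path"; these are excluded by default
  (`include_single_node` re-enables them).
* **Disconnection.** If no source reaches any target, the result is an
  explicit disconnected outcome (exception, or a flagged empty network),
  never a silently empty file.
* **Edge growth.** Each retained path is the optimum for at least one edge,
  so with continuous (tie-free) weights the edge set grows strictly with k
  as long as new candidates exist. Exact cost ties could in principle
  produce a rank whose edges are all already covered; with evidence-derived
  continuous weights this has probability zero, and the property is
  asserted over randomized synthetic graphs in the test suite.
* **Severity prioritization.** An optional hook multiplies the weights of
  edges incident to responsive proteins by
  1 + strength·(1 − exp(−max(z, 0)/scale)), re-capped below 1 and never
  below the original weight — a bounded, monotone-in-z bonus that biases
  path choice toward strongly perturbed proteins without changing topology.
  Default strength 0 (off); the functional form is a documented stand-in
  for any monotone severity-to-weight transformation.

## Significance against a degree-preserving null

Randomized interactomes are produced by double edge swaps: edges (a, b) and
(c, d) become (a, d) and (c, b), rejecting self-loops and any duplicate of
an existing edge (checked against the whole graph, so an undirected pair
never collides with a directed edge). Directed edges and undirected records
are swapped in separate pools, preserving in-/out-degrees and undirected
degrees respectively, as well as each pool's weight multiset — weights
travel with the tail's outgoing slot; any consistent carriage convention
preserves the multiset. Default mixing: 10× pool size *accepted* swaps per
pool (the sampling goal is approximate uniformity over the degree-preserving
ensemble; mixing count is configurable). Pools with fewer than two edges
are left unchanged with a warning.

The test statistic is Y_n, the number of candidate paths in randomized
network n scoring at least s_k (the k-th ranked score in the original
network, compared with a 10⁻⁹ relative tolerance so ties at s_k count).
Counting paths at s_k rather than comparing the k-th score directly is
robust to the large tie groups integer-like score distributions produce.
Y is counted over the full candidate list by default (a flag restricts each
null network to its top k). With c₀ the original count at s_k,

P_perm = (1 + Σ I(Y_n ≥ c₀)) / N, capped at 1 — the pseudocount represents
the identity permutation, putting the floor at exactly 1/N.

**GPD refinement.** P-values below the 1/N resolution are refined by
fitting a generalized Pareto distribution to the exceedances of Y above a
threshold placed midway between the 250th and 251st largest values
(maximum likelihood, location fixed at 0; scipy's shape convention).
Goodness of fit is an Anderson–Darling statistic with a parametric
bootstrap (default 200 replicates, α = 0.05); on rejection the exceedance
count shrinks by 10 and the fit is retried. The refined value is
(n_exceed/N)·(1 − F_GPD(c₀ − t)), floored at the smallest positive float.
The refinement only applies when c₀ lies beyond the threshold; otherwise,
or when the tail is degenerate (heavily tied integer counts are common at
small N) or no fit ever passes, the permutation p-value is returned
unchanged — a deliberate, visible fallback (`n_exceed = 0`). Finally,
Benjamini–Hochberg q-values are computed across chemicals (statsmodels).

A calibration property holds by construction: when the "observed" network is
itself drawn from the swap ensemble, I(Y_n ≥ c₀) = I(s_k(G_n) ≥ s_k(G_obs))
(both sides say network n's k-th best score reaches the observed threshold),
so P_perm is the rank-based permutation p-value of a continuous statistic
and is uniform on {1/N, …, 1} up to score ties. The test suite checks this
at N = 200 nulls × 50 source/target sets.

## Evaluation

Chemical–gene interaction tables are filtered to human rows whose
interaction text contains "phosphorylation" (case-insensitive substring,
which also captures "dephosphorylation"), grouped by chemical. Network
proteins are mapped to gene symbols through a supplied two-column table
(unmapped proteins dropped with a logged count) and compared with the
chemical's phospho gene set by an upper-tail hypergeometric test; the
universe defaults to the interactome node count and is configurable, since
the appropriate background depends on how the gene sets were ascertained.
Network summaries report node/edge counts, the directed-edge fraction, the
mean number of edges per retained path, and the fraction of responsive and
nonresponsive screened proteins (excluding the input receptors/TFs)
recalled in the network; empty denominators yield NaN, not 0.

## Synthetic data generator

The generator emulates the *structure* the pipeline consumes, at small
scale: a mixed directed/undirected graph with Beta(2, 2) background weights
scaled to (0.05, 0.55); node-disjoint planted source→target paths of length
≤ 5 with edge weights in [0.93, 0.99]; hit/z-score matrices and assay
annotations that parse back to requested source/target sets and include the
deliberate edge cases (up/down pairs, −1/NA-only proteins, non-NVS
receptors, nuclear-receptor family rows); and a toy chemical–gene table
with phospho and decoy rows. The weight separation guarantees each planted
path outscores any single background edge (0.93⁵ ≈ 0.70 > 0.55), so top-1
recovery of planted paths is a sharp correctness check, and planted
endpoints give strongly significant networks under the swap null.

What it does **not** emulate: the scale-free degree structure and size of a
real interactome (tests use tens of nodes, not ~16,000), dose–response
curve fitting upstream of the hit matrix, correlated assay noise, and
imperfect protein-to-gene mappings. Passing tests therefore demonstrate
algorithmic correctness and statistical calibration, not biological
recovery performance on real screening data.

## Problem sizes in the test suite

Tests run the machinery at reduced scale, chosen as the smallest sizes at
which each property is sharply testable: oracle equivalence on graphs of
≤ 8 nodes (exhaustive path enumeration); null calibration at N = 200
randomizations × 50 source/target sets on a 40-node graph with k = 10; GPD
tail accuracy with 10⁵ exponential null draws per replicate, checked at the
10⁻⁴ tail — with 250 exceedances the fit then extrapolates from the
~2.5×10⁻³ quantile, a span over which the maximum-likelihood tail estimate
is accurate to well within a factor of 2; extrapolating the same fit from
an N = 10⁴ ensemble down to 10⁻⁴ spans two further decades and the shape
parameter's sampling error alone makes factor-2 accuracy unreliable. The
acceptance script uses N = 300 randomizations per chemical and 6 chemicals.

## Known limitations

* The evidence weighting is a generic noisy-OR, not a calibrated Bayesian
  integration over experiment types; confidences are user-supplied.
* The severity bonus's functional form is a stand-in; only monotonicity and
  boundedness are guaranteed.
* GPD refinement needs > 250 informative (not heavily tied) null counts;
  at small N it almost always falls back to the permutation p-value.
* Swap mixing (10× pool size) approximates, not guarantees, uniform
  sampling of the degree-preserving ensemble.
* No ID mapping, no external database fetching, no GO enrichment: inputs
  arrive pre-resolved in the documented text formats.
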