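# Methods

## Interolog transfer with a homology-range score

The core model predicts protein–protein interactions (PPIs) in a target
species from two reference interactomes.  An interaction (p, q) in a
reference species is transferred to a target pair (x, y) whenever x is
homologous to p and y to q.  Homology evidence is a BLAST E-value,
interpreted as a degree of similarity and mapped to a score
s ∈ [0, 1] over a homology range [h_l, h_u]:

* E ≥ h_u → s = 0 (too weak to transfer);
* E ≤ h_l → s = 1 (effectively certain);
* otherwise s = (log₁₀ h_u − log₁₀ E) / (log₁₀ h_u − log₁₀ h_l).

Interpolating **linearly in log₁₀(E)** is a design choice: E-values span
hundreds of orders of magnitude, and equal ratios of E-values should
move the score equally.  Two further rules: a reference protein with
exactly one target homolog scores 1 whenever its E-value is at most
`single_homolog_evalue` (default 1e−5) — uniqueness itself is treated as
strong evidence, and this override is applied before the range mapping;
and E = 0 (BLAST underflow) is the strongest possible hit.

Each supporting reference edge contributes a per-support score combining
its two endpoint scores (default: the mean — symmetric in the
endpoints); an edge supported several times (several reference edges, or
both species) takes the maximum across supports (best evidence wins).
Both rules are configurable (`support_rule` ∈ {mean, min, max},
`edge_rule` ∈ {max, mean}) because no canonical combination exists;
changing them changes scores but never the edge set.  Pairs collapsing
onto one target protein (x = y) are dropped; the output is a simple
undirected graph with full provenance per edge.

## Parameter fitting

The bounds are fitted by grid search: h_u ∈ {1e−20, 1e−40, …, 1e−160}
and, for each h_u = 10⁻ᵘ, h_l ∈ {10⁻⁽ᵘ⁺⁴⁰⁾, …, 1e−200} in steps of 20
decades — 36 pairs in total.  Each predicted network is scored by
coverage of a small curated gold network (protein coverage = gold
proteins present; interaction coverage = gold pairs present as *direct*
edges; a gold pair connected only via an intermediate node counts as
missed).  Selection maximises (interactions covered, proteins covered)
lexicographically; ties break towards the widest log-range (best
discrimination between E-values) and then the largest h_u (least
strictness).  ROC-style evaluation is deliberately out of scope: absence
of an interaction in sparse interactome data is not evidence of absence,
so false-positive counts are not meaningful.

## Network assembly

Yeast-two-hybrid (Y2H) prey tables are merged as bait–prey edges.
Experimental edges carry the clone count as categorical evidence
strength, not a [0, 1] score — the two evidence types are not
commensurable.  An edge found both ways keeps its prediction score and
gains the `y2h` evidence tag.  Topological validation runs on the
prediction-only subnetwork: Y2H edges all touch one bait, and that star
would distort every feature being tested.

## Topological validation

Five features are computed: diameter (longest shortest path; on a
disconnected graph, the largest component's — the permissive convention
of common graph toolkits), global transitivity c = 3n/t (n triangles, t
connected triples; undefined without triples), modularity
Q = Σᵢ (e_ii − aᵢ²) of the partition found by random-walk (walktrap)
community detection with step length 4 (a common default) cut at maximum
modularity, node degrees, and unnormalised betweenness (equal-length
shortest paths split fractionally).  `compute_modularity` is an
independent implementation rather than a call into the community-detection
library, so partitions can be verified against exhaustive enumeration.

Two null ensembles of (by default) 1000 graphs each:

* **set 1** — degree-preserving randomisation: 10·|E| accepted
  double-edge swaps per sample, rejecting self-loops and multi-edges.
  The swap count is a numerical choice (enough to decorrelate an edge
  list of this size); graphs with no legal swap (e.g. a star) are
  returned as copies with a warning, making them honest fixed points.
* **set 2** — uniform simple graphs with identical |V| and |E|.

Tests per feature: the diameter is discrete, so its p-value is the
relative frequency of the observed value among the set-1 diameters (the
upper-tail frequency is reported alongside, since "frequency of the
observed value" and "tail probability" are both defensible readings of
an empirical p for a discrete statistic).  Modularity and transitivity
are tested against set 1 through a Shapiro–Wilk normality gate (α =
0.05) followed by a one-sided p from a normal fitted to the random mean
and SD, taken in the direction of the observed deviation (an observation
at the mean gives p = 0.5); a failed gate flags the p-value rather than
suppressing it.  Degree and betweenness distributions are compared with
the pooled per-node values of all set-2 graphs by a two-sample
Kolmogorov–Smirnov test — pooling is a design choice; the alternative
(per-graph tests, then combination) answers a different question.

Hub ranking sums the degree rank and betweenness rank (descending,
competition/"min" ranking for ties) into a total rank, ascending.  The
degree-distribution shape is summarised by a least-squares line on
log₁₀(count_k) vs log₁₀(k) over observed degrees ≥ 1; a power-law
("scale-free") distribution appears as a straight line with negative
slope, and a regular graph is degenerate for this fit.

## Expression analysis

The expression matrix holds strictly positive abundances over ordered
age points (default: ordinal indices 1…7; a calendar-day vector can be
supplied).  Co-expression is Pearson correlation at |r| ≥ 0.9 (positive
and opposite directions handled separately).  Genes with constant
profiles have undefined correlation and are excluded from pair universes
(and logged).  Enrichment of co-expression within a pathway set uses a
2×2 table over *all unordered pairs of usable genes* — {pair within
pathway} × {co-expressed} — with a one-sided Fisher's exact test and the
hypergeometric expectation for the pathway∩co-expressed cell.  No
multiple-testing correction is applied across pairs: the test is one
global table, not per-pair inference.

Per-gene age trends report the Pearson correlation with the age vector,
the last/first abundance ratio, and a trend class.  "Continuously
up-regulated" is operationalised by a configurable stand-in classifier:
up ⇔ age-correlation ≥ 0.7 **and** every consecutive step of the
3-point moving-average profile is non-decreasing (symmetric for down).
The thresholds are defaults, not fitted; externally derived up/down gene
lists can be passed to the enrichment test directly, bypassing the
classifier.  Up-regulation enrichment crosses {gene in network} ×
{classified up} over all profiles, again with a one-sided Fisher test;
a matrix with zero up-calls yields a flagged degenerate result with
p = 1.

## What the synthetic data emulates — and what it does not

The generator reproduces the *conditions* of the emulated study, not its
data: 259/108 reference proteins (all autophagy-tagged by default) with
487/313 typed interactions (type proportions 61/27/2/2/1 for
physical/direct/association/colocalization/covalent, normalised),
homology tables with 60 planted conserved interologs whose E-values are
log-uniform in [1e−180, 1e−30], a 15-protein/12-interaction gold network
carved from the planted truth, a Y2H table of 62 retained clones over 21
preys plus 6 discarded rows, and 10,059 expression profiles over 7 age
points with 418 increasing and 1202 decreasing planted trends (the
~3:1 down:up imbalance) plus co-expression clusters of sizes 12/8/5
sharing a non-linear template each.

Decoy homology hits (30% of the table by default) are drawn log-uniform
in (2e−5, 1e−4]: past the ingest cutoff (1e−4) but above every grid h_u
and above the single-homolog override, so they can never produce an
edge.  Planted conserved edges are sampled as *connected* subgraphs of
each reference interactome (breadth-first edge growth), so a connected
gold network exists; the two species' ortholog maps are disjoint, so
both-species edge evidence is exercised by hand-built fixtures rather
than by the generator.  The planted truth is the *induced* set — every
reference edge whose endpoints both received orthologs — which makes
perfect recovery a sharp contract (recall = precision = 1).

Deliberately not emulated: BLAST alignment mechanics (E-values are
sampled, not computed), degree heterogeneity of real interactomes
(uniform simple graphs by default; a preferential-attachment option
exists for scale-free tests), clone-level Y2H screening noise beyond the
clone-count column, and microarray normalisation artefacts.  Passing
tests therefore demonstrate correctness of the computations and
recoverability of planted structure under controlled noise — not that
real interactomes or transcriptomes satisfy the model's assumptions.

Trend templates are linear in the age index before noise (the simplest
shape that is continuously monotone); noise is multiplicative
log-normal (σ = `noise_sd`, default 0.2), which keeps abundances
positive and leaves noise-free correlations exactly ±1.  All generators
are driven by per-component substreams of a single seed;
identical configuration and seed reproduce identical outputs
byte-for-byte through the writers.

## Problem sizes and calibration checks

The default test suite runs at a scaled-down configuration (≈50-protein
references, 24 planted interologs, 400 genes) chosen so the full suite
completes in seconds while every contract stays non-trivial.
`scripts/acceptance.py` runs the full default conditions with both null
ensembles at n = 1000.

The Fisher-test calibration checks use their own conditions, fixed in
advance from a power calculation: trend rates 12%/36% (the 3:1 ratio
kept) and noise σ = 0.05, because at the default 4.2% up-rate a 2×
enrichment inside a ~90-gene network corresponds to an expected count of
only ~3.7 and is undetectable at α = 0.01 regardless of implementation.
Type-I control draws the network genes independently of the trends
(4000 genes, 500-gene network, 200 seeds; the one-sided p must be
(super)uniform); power plants an exact 2× up-rate in a 90-gene network
within 10,000 profiles (50 seeds, rejection required in ≥ 80% at
α = 0.01).

## Known limitations

* Walktrap maximises modularity greedily along its dendrogram; it is not
  guaranteed to reach the global maximum-modularity partition (the
  oracle tests assert ≤, plus equality on the worked micro-examples).
* The degree-preserving swap chain is run for a fixed number of accepted
  swaps, not to a proven mixing time.
* The trend classifier's strict smoothed-monotonicity is conservative at
  higher noise levels; recovery of planted trends degrades gracefully
  (fully recovered at σ = 0, ≈56% of up-trends at σ = 0.2) and the
  enrichment tests remain valid because the same classifier is applied
  inside and outside the network set.
* Accession namespaces are opaque strings; species identity lives only
  in taxon ids.
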