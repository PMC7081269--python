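# Methods

This note describes the models and procedures mlwalk implements, the
parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic benchmarks do and do not show.

## Multilayer network model

A network is an ordered collection of *layers* over a shared gene universe.
Node identity is the gene symbol string: the same symbol in two layers denotes
the same gene, so inter-layer coupling is implicit (node-coupled multiplex) and
no inter-layer edge lists are materialized.  Layers may be directed (the
regulatory layer) or undirected (co-expression, physical binding) and weighted
(co-expression correlations in (0, 1]) or unweighted.  Canonicalization rules:
self-loops are dropped with a warning, undirected edges are stored once in
lexicographically sorted orientation, duplicate edges collapse with the last
weight winning.  Isolated nodes are retained — they matter for the
presence/counterpart bookkeeping even with no edges.

Genes whose average expression is zero (or that are absent from the expression
matrix altogether) are removed from the regulatory and physical layers before
analysis: a gene that is never expressed is never translated, so it can carry
no regulatory or binding interaction.

## Expression preprocessing and the co-expression layer

Gene filtering removes genes failing any of four conjunctive rules: (1) any
missing value; (2) zero expression in strictly more than 80% of samples;
(3) zero standard deviation; (4) mean CPM strictly below 1, where the CPM of
sample *s* is `value * 1e6 / colsum(s)`.  The CPM rule needs a counts-scale
matrix and is skipped with a warning when the matrix is flagged as already
normalized (FPKM-like).  The rules commute, so filtering is idempotent.

The co-expression adjacency is *unsigned*: entry (i, j) is |PCC(i, j)| over a
caller-chosen sample subset — in the pipeline, the tumor samples only.  Using
the absolute value keeps strong negative correlations (regulators and their
targets) as edges.  An optional log2(x+1) transform before correlating is
provided and is the pipeline default for FPKM-like values; correlations of
heavy-tailed raw intensities are systematically attenuated relative to the
log scale, which matters next to a hard cutoff.  The layer keeps edges with
adjacency strictly above `tau` (default 0.75) and carries the correlation as
edge weight.  `tau` is a plain parameter; a log-log degree-distribution R²
diagnostic (`scale_free_fit_r2`) is provided for reporting, but no automatic
scale-freeness fit is performed.

## Heterogeneous random walker

States are (gene, layer) pairs.  Each move, with probability `beta` (default
0.2) the walker jumps to a gene drawn from the personalization distribution

    pr(i) = exp(x_i) / sum_k exp(x_k)

where `x_i` is gene *i*'s mean expression over the tumor samples, evaluated
with max-subtraction (mathematically identical, overflow-safe).  The landing
layer is chosen uniformly among layers containing the gene (an open choice;
any fixed rule mixes to the same per-gene aggregate for the graphs we study).
With probability `1 - beta` the walker moves.  Two layer-switch semantics are
implemented:

* **flattened** (default): intra-layer neighbors (weight 1 on unweighted
  layers, the correlation on the co-expression layer) and counterparts
  (weight 1 each) are pooled and normalized jointly.  On unweighted layers
  this makes one neighbor move and one counterpart move exactly equiprobable,
  which is the only quantitative statement available about the intended
  switch behaviour.
* **two_stage**: choose uniformly among {each counterpart, "intra-layer
  step"}, then distribute the intra-layer step by edge weight.  Kept
  selectable because the two readings cannot be distinguished from the
  published description.

Dangling states (no neighbors, no counterparts) force a jump; with `beta = 0`
a dangling state would stall the walk, which is detected up front and
reported.  The initial state is drawn from the jump distribution
(asymptotically irrelevant, logged for reproducibility); no burn-in is
discarded by default since the default 3×10⁶ moves dominate mixing at the
graph sizes involved (burn-in is a config option).  Visit counts are
accumulated per gene (summed over layers) and **max-normalized** so the top
gene scores exactly 1.0 — consistent with reported score summaries whose
maximum is 1.0 and whose quantiles sit far below the mean.  Genes scoring
strictly above 0.5 become seeds.

`stationary_oracle` materializes the full state-level transition matrix
implied by the same step distribution, jump rule and `beta`, power-iterates to
an L1 tolerance of 1e-12 (iteration-capped with an explicit error for
non-converging chains), and aggregates identically.  Walker/oracle agreement
is measured as the L1 distance between the two *sum-normalized* visit
distributions; on max-normalized scores the distance would grow with gene
count.

On the pipeline's FPKM-like scale the softmax input is log1p-transformed by
default (`jump_transform: log1p`): the softmax of raw means in the tens is
winner-take-all, whereas the log scale yields a graded bias toward highly
expressed genes.  `jump_distribution` itself defaults to the identity
transform, which is appropriate for inputs already on a bounded scale.

## Local community detection (ML-LCD)

Communities are grown greedily around a seed to maximize

    LC(C) = LC_int(C) / LC_ext(C)

with `LC_int = (1/|C|) Σ_{v∈C} Σ_i ω_i |E_i^C(v)|` (per-member, layer-weighted
internal degree) and `LC_ext = (1/|B|) Σ_{v∈B} Σ_i ω_i |E_i^B(v)|` over the
boundary members B (members adjacent to shell nodes).  Inside this module all
layers are treated as undirected and unweighted and the layer weights ω_i are
equal (1/3 for three layers) by default.

Numerical/degenerate choices:

* **Empty boundary**: LC is undefined when the community has no outgoing edge;
  it is treated as +∞ — a fully detached community is maximally isolated and
  terminal.  A finite-LC community can still absorb the last node of its
  component (∞ > anything finite), but an ∞-LC state accepts no further move.
* **Greedy policy**: add-only best-improvement; at each round every shell gene
  is scored and the best strictly improving one is added (ties: higher
  LC_int, then lexicographically smallest gene).  Plateau moves (equal LC) are
  not taken.  There is no removal step.
* **max_size** defaults to 300, comfortably above the 63–250 module sizes
  observed in real use, guarding against pathological growth on dense graphs.

The test-suite's exhaustive oracle maximizes LC over connected seed-containing
subsets *with nonempty boundary*; without that restriction any whole connected
component would trivially "win" with the ∞ sentinel.

## Module validation

*Involvement* is |members ∩ disease set| / |members|, passing at ≥ 0.25
(inclusive — "at least 25%").  The overlap p-value is the hypergeometric upper
tail P(X ≥ k) with Benjamini–Hochberg adjustment across modules; this is the
package's own choice of test for an otherwise unnamed column and is labelled
as such.  The one-sample proportions test uses the continuity-corrected
chi-square statistic `(max(|x − n·p0| − 0.5, 0))² / (n·p0·(1−p0))` with 1 df —
the correction is clamped so it never over-corrects past zero, matching
R's `prop.test`.  DEG-homogeneity criteria per module: |mean log2FC|, sample
sd of log2FC, and a two-sided one-sample t-test of the module's log2FCs
against 0 (p set to 1 or 0 when the sd degenerates to zero).

## Differential expression

The DE stage is a deliberately simple, fully characterized substitute for
moderated count-model statistics, which the framework does not need: it
consumes only (log2fc, adj_p, is_deg).  Per gene, the per-pair difference
`d_j = log2(tumor_j + 1) − log2(normal_j + 1)` (pseudocount configurable)
gives `log2fc = mean(d)`, a two-sided paired t-test p (constant d: p = 1 if
the constant is 0, else 0), BH adjustment across genes, and the strict gates
|log2FC| > 1 and adjusted p < 0.01.  Under the global null the combination of
both gates keeps the DEG rate far below the nominal 1% (≤ 2% is asserted; in
practice it is ~0 because a fold-change above 1 almost never co-occurs with a
tiny p at realistic noise levels).

## Survival screening

Kaplan–Meier estimation and the two-group log-rank test (chi-square reference,
1 df) are delegated to lifelines.  The screen dichotomizes subjects at each
gene's median tumor expression, ties to "low" — a deterministic,
assumption-free split chosen over cohort-optimized risk grouping, which is not
reproducible — and retains genes with log-rank p strictly below 0.05.  Genes
whose split leaves one group empty (constant expression) cannot be screened
and are not retained.

## Pipeline

Stage order: filter → co-expression layer (tumor samples, log2 scale) →
restriction of curated layers to expressed genes → assembly → jump
distribution → walker → seeds → one local community per seed → validation →
DE → survival screen of each *passing* module's DEGs that are **not** in the
disease gene set (the "not previously reported" filter, implemented as a set
difference against the same disease set used for involvement) → biomarker
union.  Reports are JSON with sorted keys and no timestamps, so identical
config + seed gives a byte-identical report.  Walker scores are cached under
the output directory keyed by a content hash of the network and walker
parameters; the other stages are cheap at every supported scale, so only the
walker is cached.

## Synthetic data: what it emulates, and what it does not

`generate_expression` uses a block-factor model on the log2 scale: gene *g*
in block *b* has `z_gs = μ_g + σ(√ρ f_bs + √(1−ρ) ε_gs)` with μ_g ~ N(5, 1)
(FPKM-like tens after exponentiation), σ = 1 and ρ = 0.8 — the target
within-block pairwise correlation, which puts block pairs above the 0.75 edge
threshold with margin *on the log scale* (the factor-model route was chosen
over explicit covariance matrices for scalability and direct control of ρ).
Planted DEGs get a +2 log2 shift on tumor columns.  `generate_multilayer`
builds the co-expression layer with the package's own correlation/threshold
operations (so planted correlation becomes planted edges), and plants the
same blocks in a directed regulatory and an undirected physical
planted-partition graph (intra 0.6 / inter 0.05; orientation uniform at
random — the community module symmetrizes anyway).  One hub per block gets 10
extra random edges per layer.  `generate_clinical` draws exponential event
times with hazard `0.1 × 3^{[above-median biomarker expression]}` and an
independent exponential censoring clock at rate 0.01.

Study conditions are the generator defaults: 3 blocks of 15 genes, 49 subject
pairs (a realistic paired-cohort size for this design), and the parameters
above.  At those conditions the median-split log-rank screen has ~0.93 power
for the planted biomarker, which sets the end-to-end recovery rate (~9/10
replicates); community recovery and walker accuracy are essentially
deterministic successes.

The disease gene set used in end-to-end tests is the biomarker's planted
block *minus the biomarker*: the "not previously reported" filter removes
disease-set genes before the survival screen, so the planted biomarker plays
the novel-gene role the screen is designed to find.

Not emulated: negative-binomial count noise, library-size and batch effects,
copy-number structure, realistic degree distributions of curated
interactomes, and dependent censoring.  Passing tests therefore demonstrate
the correctness and calibration of the machinery under its own assumptions,
not performance on real cohorts.

## Problem sizes used in checks

Verification runs use test-scale problems chosen to make the statistics
sharp: walker/oracle agreement on 20-node 3-layer networks at 10⁶ steps
(L1 ≤ 0.02); community recovery over 20 planted-partition replicates
(45 genes); DE null calibration on 20 replicates of 1000 genes × 20 pairs;
log-rank size/power at 1000 replicates of 100 + 100 subjects; and 10 full
pipeline replicates at generator defaults with the walker's default 3×10⁶
moves.
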