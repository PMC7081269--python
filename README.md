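# mlwalk

Multilayer transcriptome-to-interactome network analysis for biomarker
discovery: build a three-layer gene network (co-expression, regulatory,
physical binding), rank genes with a heterogeneous personalized random
walker, grow seed-centric local communities, and validate the resulting
modules by disease-gene overlap, paired differential expression, and
survival screening.

It is written for computational biologists who have a paired tumor/normal
expression cohort plus curated interaction layers and want a reproducible,
fully scriptable version of this workflow — including a synthetic-data
generator with planted ground truth for testing every stage.

## The method in brief

**Network.**  Each layer ℓ is a graph over gene symbols; the same symbol in
two layers is the same gene (node-coupled multiplex).  The co-expression
layer keeps gene pairs with unsigned Pearson correlation |r| > τ (default
0.75) over the tumor samples, weighted by |r|; the regulatory layer is
directed and the physical layer undirected, both unweighted.

**Ranking.**  A random walker on states (gene, layer) jumps with probability
β = 0.2 to a gene drawn from the personalization distribution

    pr(i) = exp(x_i) / Σ_k exp(x_k),

a softmax over mean tumor expression, and otherwise moves to an intra-layer
neighbor (probability ∝ A_ℓ(i, j)) or to a counterpart of the same gene in
another layer, all candidates normalized jointly.  Scores are max-normalized
visit frequencies over 3×10⁶ moves; genes with score > 0.5 become seeds.
An exact stationary-distribution solver for the same chain serves as the
simulation's reference.

**Modules.**  Around each seed, a local community C grows greedily to
maximize

    LC(C) = LC_int(C) / LC_ext(C),

the layer-weighted internal degree density over the boundary's outgoing
density (layers unweighted/undirected here, ω_i = 1/3 each).

**Validation and screening.**  A module passes when ≥ 25% of its genes are
in the disease gene set (hypergeometric enrichment p, BH-adjusted across
modules, is also reported).  DEGs are genes with |log2FC| > 1 and BH-adjusted
paired-t p < 0.01.  Passing modules' DEGs that are *not* already in the
disease set are dichotomized at median tumor expression and tested by the
two-group log-rank test; genes with p < 0.05 are the reported biomarkers.

## Worked example

`examples/06_full_pipeline.py` runs the whole workflow on the synthetic
defaults (3 planted blocks of 15 genes, 49 subject pairs, one planted
biomarker with hazard ratio 3):

```
$ python examples/06_full_pipeline.py
seeds (walker score > 0.5): 25
modules (seed, size, involvement, passes, DEGs, survival candidates):
  G002   15  0.933  True   2  ['G001']
  G043   15  0.000  False  0  []
  G024   15  0.000  False  1  []
  G000   15  0.933  True   2  ['G001']
  G006   15  0.933  True   2  ['G001']
reported biomarkers: ['G001']
planted biomarker:   G001
```

Reading the output: 25 genes cleared the walker-score cutoff and seeded
modules; modules rooted in the biomarker's block contain 14 of the 15
disease-set genes (involvement 0.933, passing the 25% bar) plus the planted
biomarker G001, which is differentially expressed (planted +2 log2 tumor
shift), absent from the disease set, and retained by the log-rank screen —
exactly the planted answer.  The other examples exercise each capability in
isolation (network construction, ranking, community growth, validation, DE,
survival).

A thin CLI mirrors the library: `mlwalk synth`, `mlwalk rank`,
`mlwalk community`, `mlwalk de`, `mlwalk survive`, `mlwalk run --config
pipeline.yaml`.

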