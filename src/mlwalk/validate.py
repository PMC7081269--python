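"""Module-level validation statistics.

Detected modules are judged by (a) their *involvement* — the fraction of member
genes present in a curated disease gene set, with a pass at 25% or more; (b) a
hypergeometric enrichment p-value for that overlap, Benjamini–Hochberg adjusted
across modules (our choice of test; the convention of gene-set enrichment
portals); (c) summaries of members' walker scores; and (d) DEG-homogeneity
criteria (|mean log2FC|, sd of log2FC, one-sample t-test p) used to compare
module-detection approaches.  A one-sample proportions test with continuity
correction checks whether the DEG fraction inside modules exceeds a reference
proportion.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .de import bh_adjust
from .errors import ConfigError, GeneLookupError
from .lcd import Community
from .walker import ScoreTable

__all__ = [
    "GeneSet",
    "ModuleReport",
    "disease_overlap",
    "overlap_enrichment",
    "one_sample_prop_test",
    "module_score_summary",
    "deg_homogeneity",
    "validate_modules",
    "read_gene_set",
    "read_gmt",
]


@dataclass
class GeneSet:
    """A named gene set (e.g. disease-associated genes from a curated database)."""

    name: str
    genes: set[str]

    def __post_init__(self) -> None:
        if not self.name:
            raise ConfigError("gene set needs a nonempty name")


@dataclass
class ModuleReport:
    """One row of the module validation table."""

    seed: str
    n_genes: int
    overlap_count: int
    involvement: float
    passes: bool
    overlap_p: float | None = None
    overlap_fdr: float | None = None
    score_summary: dict[str, float] = field(default_factory=dict)


def disease_overlap(community: Community, disease: GeneSet,
                    threshold: float = 0.25) -> ModuleReport:
    """Involvement of a module in a disease gene set; passes at >= threshold.

    Involvement is kept at full precision (round for reporting); the threshold
    comparison is inclusive ("at least 25%").
    """
    if not community.members:
        raise ConfigError("empty community")
    n = len(community.members)
    overlap = len(community.members & disease.genes)
    involvement = overlap / n
    return ModuleReport(seed=community.seed, n_genes=n, overlap_count=overlap,
                        involvement=involvement, passes=involvement >= threshold)


def overlap_enrichment(module_genes: set[str], disease: GeneSet,
                       universe_size: int) -> float:
    """Hypergeometric upper-tail p-value of the module/disease-set overlap."""
    m, d = len(module_genes), len(disease.genes)
    if m > universe_size or d > universe_size:
        raise ConfigError(
            f"module ({m}) and disease set ({d}) must fit in universe ({universe_size})")
    k = len(module_genes & disease.genes)
    # P(X >= k), X ~ Hypergeom(N=universe, K=disease, n=module)
    return float(stats.hypergeom.sf(k - 1, universe_size, d, m))


def one_sample_prop_test(x: int, n: int, p0: float) -> tuple[float, float]:
    """One-sample proportions test with continuity correction (1 df).

    statistic = (max(|x - n*p0| - 0.5, 0))^2 / (n*p0*(1-p0)); the correction is
    clamped so it never over-corrects past zero, matching ``prop.test``.
    """
    if n <= 0:
        raise ConfigError("n must be positive")
    if not (0 <= x <= n):
        raise ConfigError(f"x={x} outside [0, n={n}]")
    if not (0.0 < p0 < 1.0):
        raise ConfigError("p0 must be in (0, 1)")
    corrected = max(abs(x - n * p0) - 0.5, 0.0)
    statistic = corrected ** 2 / (n * p0 * (1.0 - p0))
    p = float(stats.chi2.sf(statistic, df=1))
    return statistic, p


def module_score_summary(community: Community,
                         scores: ScoreTable) -> dict[str, float]:
    """Min/max/mean/median walker score over the module's members."""
    vals = []
    for g in sorted(community.members):
        if g not in scores.scores:
            raise GeneLookupError(f"member {g!r} has no walker score")
        vals.append(scores.scores[g])
    arr = np.array(vals)
    return {"min": float(arr.min()), "max": float(arr.max()),
            "mean": float(arr.mean()), "median": float(np.median(arr))}


def deg_homogeneity(module_genes: set[str],
                    logfc: Mapping[str, float]) -> dict[str, float]:
    """DEG-based module criteria: |mean log2FC|, sd of log2FC, t-test p vs 0."""
    vals = np.array([logfc[g] for g in sorted(module_genes) if g in logfc])
    if len(vals) < 2:
        raise ConfigError("need >= 2 module genes with log fold changes")
    sd = float(vals.std(ddof=1))
    if sd == 0.0:
        t_p = 1.0 if vals.mean() == 0.0 else 0.0
    else:
        t_p = float(stats.ttest_1samp(vals, 0.0).pvalue)
    return {"abs_mean_lfc": float(abs(vals.mean())), "sd_lfc": sd, "t_p": t_p}


def validate_modules(communities: Sequence[Community], disease: GeneSet,
                     universe_size: int, scores: ScoreTable | None = None,
                     threshold: float = 0.25) -> list[ModuleReport]:
    """Full validation table: involvement, enrichment p, BH FDR across modules."""
    if not disease.genes:
        raise ConfigError(f"disease gene set {disease.name!r} is empty")
    reports = [disease_overlap(c, disease, threshold) for c in communities]
    pvals = [overlap_enrichment(c.members, disease, universe_size)
             for c in communities]
    fdrs = bh_adjust(pvals) if pvals else []
    for rep, c, p, q in zip(reports, communities, pvals, fdrs):
        rep.overlap_p = float(p)
        rep.overlap_fdr = float(q)
        if scores is not None:
            rep.score_summary = module_score_summary(c, scores)
    return reports


# -- gene-set I/O --------------------------------------------------------


def read_gene_set(path, name: str | None = None) -> GeneSet:
    """Plain one-gene-per-line file (blank lines and ``#`` comments ignored)."""
    genes = set()
    with open(path) as fh:
        for line in fh:
            g = line.strip()
            if g and not g.startswith("#"):
                genes.add(g)
    return GeneSet(name=name or str(path), genes=genes)


def read_gmt(path) -> list[GeneSet]:
    """GMT: one set per line — name, description, then member genes (tabs)."""
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ConfigError(f"{path}:{lineno}: GMT needs name, description, genes")
            sets.append(GeneSet(name=parts[0], genes={g for g in parts[2:] if g}))
    return sets
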