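"""Paired differential-expression stage.

Per gene, the paired log2 fold change is the mean over subject pairs of
``log2(tumor + c) - log2(normal + c)`` (pseudocount ``c = 1`` by default), its
p-value a two-sided paired t-test on those per-pair differences, adjusted by
Benjamini–Hochberg across all tested genes.  A gene is called differentially
expressed (DEG) when ``|log2FC| > lfc_cut`` AND ``adj_p < p_cut``, both strict;
the defaults (1.0 and 0.01) are the selection thresholds of the surrounding
framework.  This is a deliberately simple, fully characterized stage: the rest
of the framework consumes only (log2fc, adj_p, is_deg).
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .coexpr import ExpressionMatrix
from .errors import ConfigError

__all__ = ["de_analysis", "bh_adjust"]


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, original order preserved."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ConfigError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_analysis(expr: ExpressionMatrix, lfc_cut: float = 1.0,
                p_cut: float = 0.01, pseudocount: float = 1.0) -> pd.DataFrame:
    """Paired tumor-vs-normal DE table: gene-indexed frame with columns
    ``log2fc``, ``p``, ``adj_p``, ``is_deg``."""
    pairs = expr.pairs()
    incomplete = pairs.index[pairs.isna().any(axis=1)].tolist()
    if incomplete:
        raise ConfigError(f"pair_id(s) missing a condition: {incomplete}")
    if len(pairs) < 3:
        raise ConfigError(f"need >= 3 complete pairs, found {len(pairs)}")
    pairs = pairs.sort_index()  # invariant to sample column order
    tumor = expr.values[pairs["tumor"].tolist()].to_numpy(dtype=float)
    normal = expr.values[pairs["normal"].tolist()].to_numpy(dtype=float)
    d = np.log2(tumor + pseudocount) - np.log2(normal + pseudocount)
    log2fc = d.mean(axis=1)
    sd = d.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_1samp(d, 0.0, axis=1)
        p = np.asarray(res.pvalue, dtype=float)
    # constant differences: t undefined; null holds iff the constant is 0
    const = sd == 0.0
    p[const] = np.where(log2fc[const] == 0.0, 1.0, 0.0)
    adj = bh_adjust(p)
    is_deg = (np.abs(log2fc) > lfc_cut) & (adj < p_cut)
    return pd.DataFrame(
        {"log2fc": log2fc, "p": p, "adj_p": adj, "is_deg": is_deg},
        index=pd.Index(expr.genes, name="gene"),
    )
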