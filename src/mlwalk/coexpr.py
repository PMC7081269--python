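"""Expression preprocessing and weighted co-expression layer construction.

The expression container is a genes x samples matrix with per-sample condition
(normal/tumor) and pairing metadata, as produced by a paired cancer cohort.
Gene filtering applies four conjunctive exclusion rules (missing values, excess
zeros, zero variance, low mean CPM); the co-expression layer is the unsigned
(|Pearson correlation|) adjacency hard-thresholded at tau, keeping edges with
|r| strictly above the cutoff.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, GeneLookupError
from .netmodel import Layer

__all__ = [
    "ExpressionMatrix",
    "filter_genes",
    "unsigned_correlation_adjacency",
    "hard_threshold_layer",
    "scale_free_fit_r2",
    "read_expression",
    "write_expression",
]

CONDITIONS = ("normal", "tumor")


@dataclass
class ExpressionMatrix:
    """Nonnegative genes x samples expression values plus sample metadata.

    ``sample_meta`` is indexed by sample id with columns ``condition``
    (``normal``/``tumor``) and optional ``pair_id`` (NaN when unpaired); a
    pair_id occurs at most once per condition.  ``scale`` flags whether the
    values are raw counts (the CPM filter rule applies) or already normalized
    (FPKM-like; the CPM rule is skipped with a warning).
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    scale: str = "counts"  # "counts" | "normalized"

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            raise ConfigError("duplicate gene identifiers")
        if v.columns.has_duplicates:
            raise ConfigError("duplicate sample identifiers")
        arr = v.to_numpy(dtype=float)
        if np.isinf(arr).any():
            raise ConfigError("expression values must be finite")
        if np.nanmin(arr, initial=0.0) < 0:
            raise ConfigError("expression values must be >= 0")
        if self.scale not in {"counts", "normalized"}:
            raise ConfigError(f"unknown scale {self.scale!r}")
        meta = self.sample_meta
        if set(meta.index) != set(v.columns):
            raise ConfigError("sample_meta index must match sample columns")
        bad = set(meta["condition"]) - set(CONDITIONS)
        if bad:
            raise ConfigError(f"unknown condition(s): {sorted(bad)}")
        if "pair_id" in meta.columns:
            paired = meta.dropna(subset=["pair_id"])
            counts = paired.groupby(["pair_id", "condition"]).size()
            if (counts > 1).any():
                raise ConfigError("a pair_id occurs more than once per condition")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def samples_where(self, condition: str) -> list[str]:
        mask = self.sample_meta["condition"] == condition
        return [s for s in self.samples if mask.get(s, False)]

    @property
    def tumor_samples(self) -> list[str]:
        return self.samples_where("tumor")

    @property
    def normal_samples(self) -> list[str]:
        return self.samples_where("normal")

    def pairs(self) -> pd.DataFrame:
        """Complete pairs as a frame with columns ``normal``/``tumor`` indexed by pair_id."""
        if "pair_id" not in self.sample_meta.columns:
            return pd.DataFrame(columns=["normal", "tumor"])
        meta = self.sample_meta.dropna(subset=["pair_id"])
        wide = (meta.reset_index(names="sample")
                .pivot(index="pair_id", columns="condition", values="sample"))
        for c in CONDITIONS:
            if c not in wide.columns:
                wide[c] = np.nan
        return wide[list(CONDITIONS)]

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(genes)], self.sample_meta,
                                self.scale)


def filter_genes(expr: ExpressionMatrix, zero_frac: float = 0.8,
                 min_avg_cpm: float = 1.0) -> ExpressionMatrix:
    """Remove genes failing any of the four exclusion rules.

    1. any missing value across samples;
    2. expression zero in strictly more than ``zero_frac`` of samples;
    3. zero standard deviation across samples;
    4. mean CPM strictly below ``min_avg_cpm`` (counts scale only; skipped with
       a warning on normalized data), where CPM of sample s is
       ``value * 1e6 / column_sum(s)``.

    The rules are a conjunction, so their application order is immaterial;
    surviving genes keep their original order.
    """
    if expr.values.empty:
        raise ConfigError("empty expression matrix")
    v = expr.values
    arr = v.to_numpy(dtype=float)
    n_samples = arr.shape[1]
    has_missing = np.isnan(arr).any(axis=1)
    zero_fraction = (arr == 0.0).sum(axis=1) / n_samples
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        sd = np.nanstd(arr, axis=1)
    fails = has_missing | (zero_fraction > zero_frac) | (sd == 0.0)
    if expr.scale == "counts":
        colsums = np.nansum(arr, axis=0)
        if (colsums == 0).any():
            bad = [s for s, c in zip(expr.samples, colsums) if c == 0]
            raise ConfigError(f"CPM undefined: zero column sum for sample(s) {bad}")
        cpm = arr * 1e6 / colsums
        mean_cpm = np.nanmean(cpm, axis=1)
        # genes with missing values are already excluded by rule 1
        fails |= np.where(np.isnan(mean_cpm), True, mean_cpm < min_avg_cpm)
    else:
        warnings.warn("values flagged as normalized; CPM filter rule skipped")
    keep = v.index[~fails]
    return ExpressionMatrix(v.loc[keep], expr.sample_meta, expr.scale)


def unsigned_correlation_adjacency(expr: ExpressionMatrix,
                                   sample_subset: Sequence[str],
                                   transform: str = "identity") -> pd.DataFrame:
    """Unsigned co-expression adjacency: |Pearson correlation| over a sample subset.

    ``transform`` may be ``"identity"`` (correlate the values as given) or
    ``"log2p1"`` (correlate log2(x+1), the usual choice for FPKM-like scales).
    Entry (i, j) is |PCC(i, j)|; the diagonal is 1 but is never emitted as an
    edge by :func:`hard_threshold_layer`.
    """
    subset = list(sample_subset)
    if len(subset) < 3:
        raise ConfigError("need at least 3 samples for correlation")
    missing = [s for s in subset if s not in expr.values.columns]
    if missing:
        raise GeneLookupError(f"unknown sample(s) {missing}")
    x = expr.values[subset].to_numpy(dtype=float)
    if transform == "log2p1":
        x = np.log2(x + 1.0)
    elif transform != "identity":
        raise ConfigError(f"unknown transform {transform!r}")
    sd = x.std(axis=1)
    if (sd == 0).any():
        bad = [g for g, s in zip(expr.genes, sd) if s == 0]
        raise ConfigError(f"zero-variance gene(s) over subset: {bad[:10]}")
    corr = np.corrcoef(x)
    adj = np.abs(corr)
    np.clip(adj, 0.0, 1.0, out=adj)  # guard float jitter above 1
    np.fill_diagonal(adj, 1.0)
    return pd.DataFrame(adj, index=expr.genes, columns=expr.genes)


def hard_threshold_layer(adj: pd.DataFrame, tau: float = 0.75, *,
                         layer_id: str = "coexpr",
                         keep_isolated: bool = False) -> Layer:
    """Keep edges with adjacency strictly above ``tau`` as a weighted undirected layer.

    Genes left without any surviving edge are dropped unless ``keep_isolated``.
    """
    if not (0.0 <= tau < 1.0):
        raise ConfigError(f"tau must be in [0, 1), got {tau}")
    if list(adj.index) != list(adj.columns):
        raise ConfigError("adjacency must be square with matching labels")
    a = adj.to_numpy(dtype=float)
    if not np.allclose(a, a.T, atol=1e-12):
        raise ConfigError("adjacency must be symmetric")
    genes = list(adj.index)
    iu, ju = np.triu_indices(len(genes), k=1)
    mask = a[iu, ju] > tau
    edges = [(genes[i], genes[j], float(a[i, j]))
             for i, j in zip(iu[mask], ju[mask])]
    extra = genes if keep_isolated else ()
    return Layer.from_edges(layer_id, edges, directed=False, weighted=True,
                            extra_nodes=extra)


def scale_free_fit_r2(layer: Layer, n_bins: int = 10) -> float:
    """Report-only diagnostic: R^2 of the log-log degree-distribution fit.

    Scale-free-like layers give values near 1.  Binned as in the usual
    co-expression workflow; returns NaN when there are too few occupied bins.
    """
    from collections import Counter

    deg = Counter()
    for u, v, _ in layer.edges:
        deg[u] += 1
        deg[v] += 1
    if not deg:
        return float("nan")
    degrees = np.array(sorted(deg.values()))
    edges = np.unique(np.round(np.geomspace(degrees.min(), degrees.max() + 1,
                                            n_bins + 1)).astype(int))
    if len(edges) < 3:
        return float("nan")
    counts, bins = np.histogram(degrees, bins=edges)
    centers = (bins[:-1] + bins[1:]) / 2
    occupied = counts > 0
    if occupied.sum() < 3:
        return float("nan")
    x = np.log10(centers[occupied])
    y = np.log10(counts[occupied] / counts.sum())
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


# -- I/O -----------------------------------------------------------------


def read_expression(expr_path, meta_path, *, scale: str = "counts") -> ExpressionMatrix:
    """Read an expression TSV (first column gene id) and a sample-metadata TSV
    (columns ``sample_id``, ``condition``, optional ``pair_id``)."""
    values = pd.read_csv(expr_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", dtype={"pair_id": "string"})
    if "sample_id" not in meta.columns or "condition" not in meta.columns:
        raise ConfigError(f"{meta_path}: need columns sample_id, condition")
    meta = meta.set_index("sample_id")
    return ExpressionMatrix(values, meta, scale)


def write_expression(expr: ExpressionMatrix, expr_path, meta_path) -> None:
    expr.values.to_csv(expr_path, sep="\t", index_label="gene")
    meta = expr.sample_meta.copy()
    meta.index.name = "sample_id"
    meta.to_csv(meta_path, sep="\t")
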