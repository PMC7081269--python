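"""Kaplan–Meier estimation, log-rank testing, and survival screening.

Candidate biomarker genes are screened by dichotomizing subjects at the median
tumor expression of each gene (ties to "low" — a deterministic, assumption-free
split) and comparing the two groups' survival with the two-group log-rank test
(chi-square reference, 1 df); genes with p strictly below alpha are retained.
Estimation and testing are delegated to lifelines.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .coexpr import ExpressionMatrix
from .errors import ConfigError, GeneLookupError

__all__ = ["SurvivalRecord", "km_curve", "logrank_test", "survival_screen",
           "read_clinical"]


@dataclass
class SurvivalRecord:
    """One subject's follow-up: time > 0, event (1=death, 0=censored), group."""

    subject_id: str
    time: float
    event: int
    group: str | None = None  # "high" | "low" once assigned

    def __post_init__(self) -> None:
        if not self.time > 0:
            raise ConfigError(f"subject {self.subject_id!r}: time must be > 0")
        if self.event not in (0, 1):
            raise ConfigError(f"subject {self.subject_id!r}: event must be 0 or 1")


def _arrays(records: Sequence[SurvivalRecord]) -> tuple[np.ndarray, np.ndarray]:
    t = np.array([r.time for r in records], dtype=float)
    e = np.array([r.event for r in records], dtype=int)
    return t, e


def km_curve(records: Sequence[SurvivalRecord]) -> list[tuple[float, float]]:
    """Product-limit survival estimate at each distinct event time.

    Censored-only times change the risk set but add no curve point; with no
    events at all the estimate is 1 everywhere and the list is empty.
    """
    from lifelines import KaplanMeierFitter

    if not records:
        raise ConfigError("no survival records")
    t, e = _arrays(records)
    if e.sum() == 0:
        return []
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    sf = kmf.survival_function_.iloc[:, 0]
    event_times = np.unique(t[e == 1])
    return [(float(ti), float(sf.loc[ti])) for ti in event_times]


def logrank_test(group_a: Sequence[SurvivalRecord],
                 group_b: Sequence[SurvivalRecord]) -> tuple[float, float]:
    """Two-group log-rank test: (chi-square statistic, p-value from chi2, 1 df)."""
    from lifelines.statistics import logrank_test as _lr

    if not group_a or not group_b:
        raise ConfigError("both groups must be nonempty")
    ta, ea = _arrays(group_a)
    tb, eb = _arrays(group_b)
    if ea.sum() + eb.sum() == 0:
        raise ConfigError("log-rank test undefined with zero events")
    res = _lr(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


def survival_screen(genes: Sequence[str], expr: ExpressionMatrix,
                    clinical: Sequence[SurvivalRecord], alpha: float = 0.05,
                    sample_map: Mapping[str, str] | None = None,
                    ) -> list[str]:
    """Keep genes whose median-split expression groups differ in survival.

    ``clinical`` subjects map to tumor expression samples via ``sample_map``
    (default: subject_id IS the sample id).  Subjects with expression strictly
    above the median go to "high", the rest (ties included) to "low"; genes
    with log-rank p strictly below ``alpha`` are retained, input order kept.
    Genes whose split leaves a group empty (constant expression) cannot be
    screened and are not retained.
    """
    if not (0.0 < alpha < 1.0):
        raise ConfigError("alpha must be in (0, 1)")
    if not clinical:
        raise ConfigError("no clinical records")
    samples = []
    for r in clinical:
        s = sample_map[r.subject_id] if sample_map is not None else r.subject_id
        if s not in expr.values.columns:
            raise GeneLookupError(
                f"subject {r.subject_id!r}: no expression sample {s!r}")
        samples.append(s)
    kept: list[str] = []
    for gene in genes:
        if gene not in expr.values.index:
            raise GeneLookupError(f"gene {gene!r} has no expression")
        vals = expr.values.loc[gene, samples].to_numpy(dtype=float)
        median = float(np.median(vals))
        high = [r for r, v in zip(clinical, vals) if v > median]
        low = [r for r, v in zip(clinical, vals) if v <= median]
        if not high or not low:
            continue
        try:
            _, p = logrank_test(high, low)
        except ConfigError:  # zero events in this cohort slice
            continue
        if p < alpha:
            kept.append(gene)
    return kept


def read_clinical(path) -> list[SurvivalRecord]:
    """Clinical TSV with columns subject_id, time, event."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    needed = {"subject_id", "time", "event"}
    if not needed <= set(df.columns):
        raise ConfigError(f"{path}: need columns {sorted(needed)}")
    return [SurvivalRecord(str(r.subject_id), float(r.time), int(r.event))
            for r in df.itertuples(index=False)]
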