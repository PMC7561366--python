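"""Cohort-level statistics: descriptives, pooled t-tests with Cohen's d,
two-tailed Pearson correlations, Kolmogorov-Smirnov normality diagnostics,
and the cohort x subgroup x feature x outcome correlation table.

The two-sample comparison is Student's pooled-variance t (df = n1 + n2 - 2).
Cohen's d divides the mean difference by a pooled SD whose denominator is,
by default, the total sample size n1 + n2 (switchable to n1 + n2 - 2).
Missing outcomes are dropped pairwise per analysis; alpha is 0.05 with no
multiple-comparison correction.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import CorrelationResult, Descriptives, TTestResult

__all__ = [
    "descriptives",
    "pooled_t_test",
    "summary_t_test",
    "pearson",
    "ks_normality",
    "run_correlation_table",
    "cohort_descriptives_table",
]

OUTCOMES = ("orienting_latency_ms", "dwell_index")
FEATURES = ("f0_hz", "f0var_hz")


class InsufficientDataError(ValueError):
    pass


class DegenerateVarianceError(ValueError):
    pass


def _finite(values) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    return v[np.isfinite(v)]


def descriptives(values: Sequence[float]) -> Descriptives:
    """n, mean and sample SD (denominator n - 1) of the finite values."""
    v = _finite(values)
    if v.size < 2:
        raise InsufficientDataError("descriptives need at least 2 finite values")
    return Descriptives(n=int(v.size), mean=float(v.mean()),
                        sd=float(v.std(ddof=1)))


def summary_t_test(d1: Descriptives, d2: Descriptives,
                   d_denominator: str = "total") -> TTestResult:
    """Pooled-variance Student t and Cohen's d from summary statistics.

    ``d_denominator`` selects the pooled-SD denominator for Cohen's d:
    "total" (n1 + n2) or "df" (n1 + n2 - 2). The t statistic always pools
    with df = n1 + n2 - 2.
    """
    n1, n2 = d1.n, d2.n
    df = n1 + n2 - 2
    ss = (n1 - 1) * d1.sd**2 + (n2 - 1) * d2.sd**2
    sp2_t = ss / df
    if sp2_t == 0:
        if d1.mean != d2.mean:
            raise DegenerateVarianceError(
                "zero pooled variance with unequal means"
            )
        return TTestResult(t=0.0, df=df, p_two_tailed=1.0, cohen_d=0.0)
    t = (d1.mean - d2.mean) / math.sqrt(sp2_t * (1 / n1 + 1 / n2))
    p = 2 * sps.t.sf(abs(t), df)
    denom = n1 + n2 if d_denominator == "total" else df
    sp_d = math.sqrt(ss / denom)
    d = (d1.mean - d2.mean) / sp_d
    return TTestResult(t=float(t), df=df, p_two_tailed=float(p), cohen_d=float(d))


def pooled_t_test(a: Sequence[float], b: Sequence[float],
                  d_denominator: str = "total") -> TTestResult:
    """Independent-samples Student t with pooled variance, plus Cohen's d."""
    va, vb = _finite(a), _finite(b)
    if va.size < 2 or vb.size < 2:
        raise InsufficientDataError("each group needs at least 2 finite values")
    return summary_t_test(descriptives(va), descriptives(vb), d_denominator)


def pearson(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Two-tailed Pearson correlation with pairwise deletion of missing pairs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = int(x.size)
    if n < 3:
        raise InsufficientDataError("Pearson correlation needs >= 3 complete pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateVarianceError("correlation undefined for constant input")
    res = sps.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic),
                             p_two_tailed=float(res.pvalue), n=n)


def ks_normality(values: Sequence[float]) -> tuple[float, float]:
    """One-sample KS test against a normal with the sample's mean and SD.

    Diagnostic only (mirrors the usual reporting practice); nothing in the
    pipeline is gated on it.
    """
    v = _finite(values)
    if v.size < 5:
        raise InsufficientDataError("KS normality check needs >= 5 values")
    sd = v.std(ddof=1)
    if sd == 0:
        raise DegenerateVarianceError("KS normality undefined for constant input")
    stat, p = sps.kstest(v, "norm", args=(v.mean(), sd))
    return float(stat), float(p)


_SUBSETS = {
    "tampere": (("all", None), ("bout_start", "bout_start_captured")),
    "cape_town": (("all", None), ("ssri_excluded", "ssri_exposed")),
}


def _apply_subset(df: pd.DataFrame, flag: Optional[str]) -> pd.DataFrame:
    if flag is None:
        return df
    if flag == "bout_start_captured":
        return df[df[flag].astype(bool)]
    return df[~df[flag].astype(bool)]  # ssri_exposed: keep non-exposed


def run_correlation_table(records: pd.DataFrame,
                          alpha: float = 0.05) -> pd.DataFrame:
    """Correlations between cry features and attention outcomes per cohort.

    For each cohort, each subgroup (all; Tampere beginning-of-bout; Cape
    Town SSRI-excluded), each feature (F0, F0var) and each outcome
    (orienting latency, dwell index): Pearson r, two-tailed p, per-cell n,
    and a significance flag at ``alpha`` (no multiple-comparison
    correction). Cells with fewer than 3 complete pairs are marked
    not-computable (NaN r/p).
    """
    rows = []
    for cohort, subsets in _SUBSETS.items():
        cohort_df = records[records["cohort"] == cohort]
        for subset_name, flag in subsets:
            sub = _apply_subset(cohort_df, flag) if len(cohort_df) else cohort_df
            for feature in FEATURES:
                for outcome in OUTCOMES:
                    try:
                        res = pearson(sub[feature], sub[outcome]) if len(sub) else None
                        if res is None:
                            raise InsufficientDataError("empty cell")
                        r, p, n = res.r, res.p_two_tailed, res.n
                        computable = True
                    except (InsufficientDataError, DegenerateVarianceError, KeyError):
                        pairs = 0
                        if len(sub) and feature in sub and outcome in sub:
                            pairs = int(
                                (np.isfinite(sub[feature].astype(float))
                                 & np.isfinite(sub[outcome].astype(float))).sum()
                            )
                        r, p, n, computable = math.nan, math.nan, pairs, False
                    rows.append(
                        {
                            "cohort": cohort,
                            "subset": subset_name,
                            "feature": feature,
                            "outcome": outcome,
                            "r": r,
                            "p_two_tailed": p,
                            "n": n,
                            "significant": bool(computable and p < alpha),
                            "computable": computable,
                        }
                    )
    return pd.DataFrame(rows)


def cohort_descriptives_table(records: pd.DataFrame) -> pd.DataFrame:
    """Per-cohort n/mean/SD of the four main study variables."""
    rows = []
    for cohort, df in records.groupby("cohort"):
        for var in FEATURES + OUTCOMES:
            try:
                d = descriptives(df[var])
                rows.append({"cohort": cohort, "variable": var,
                             "n": d.n, "mean": d.mean, "sd": d.sd})
            except (InsufficientDataError, KeyError):
                rows.append({"cohort": cohort, "variable": var,
                             "n": 0, "mean": math.nan, "sd": math.nan})
    return pd.DataFrame(rows)
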