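"""Survival and group-difference statistics for the two strata.

Kaplan-Meier product-limit curves and medians (via lifelines), a hand-rolled
Mantel-Haenszel log-rank test that also exposes the observed/expected event
table, an O/E hazard ratio with a log-scale normal confidence interval, and
Welch / Mann-Whitney two-sample comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

__all__ = [
    "KMCurve",
    "LogrankResult",
    "km_estimate",
    "logrank_test",
    "hazard_ratio_oe",
    "group_compare",
    "survival_summary",
    "score_group_summary",
]


@dataclass
class KMCurve:
    """Kaplan-Meier step function: S(t) at each distinct observed time.

    ``median`` is the smallest event time with S(t) <= 0.5, or ``math.inf``
    when the curve never reaches 0.5 (the undefined-median sentinel).
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    median: float
    n: int
    n_events: int

    @property
    def median_defined(self) -> bool:
        return math.isfinite(self.median)


@dataclass
class LogrankResult:
    chi2: float
    pvalue: float
    observed_a: float
    expected_a: float
    observed_b: float
    expected_b: float
    variance: float


def km_estimate(times, events) -> KMCurve:
    """Product-limit survival estimate for one group."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("no survival records")
    if (times <= 0).any() or not np.isfinite(times).all():
        raise ValueError("times must be finite and positive")

    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    # drop the t=0 anchor row; keep observed time grid
    grid = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    keep = grid > 0
    at_risk = np.array([int((times >= t).sum()) for t in grid[keep]])
    # median convention: smallest observed time with S(t) <= 0.5 (inf if never)
    crossed = np.flatnonzero(surv[keep] <= 0.5 + 1e-12)
    median = float(grid[keep][crossed[0]]) if crossed.size else math.inf
    return KMCurve(times=grid[keep], survival=surv[keep], at_risk=at_risk,
                   median=median, n=int(times.size), n_events=int(events.sum()))


def _logrank_table(times_a, events_a, times_b, events_b):
    """Accumulate O-E and hypergeometric variance over distinct event times.

    Ties between an event and a censoring at the same time are handled by the
    standard convention: events are processed first (censored subjects at t
    still count as at risk at t).
    """
    ta = np.asarray(times_a, dtype=float)
    ea = np.asarray(events_a, dtype=int)
    tb = np.asarray(times_b, dtype=float)
    eb = np.asarray(events_b, dtype=int)

    event_times = np.unique(np.concatenate([ta[ea == 1], tb[eb == 1]]))
    if event_times.size == 0:
        raise ValueError("no events in either group")

    O_a = E_a = V = 0.0
    O_b = E_b = 0.0
    for t in event_times:
        na = int((ta >= t).sum())
        nb = int((tb >= t).sum())
        n = na + nb
        da = int(((ta == t) & (ea == 1)).sum())
        db = int(((tb == t) & (eb == 1)).sum())
        d = da + db
        if n == 0 or d == 0:
            continue
        O_a += da
        O_b += db
        E_a += d * na / n
        E_b += d * nb / n
        if n > 1:
            V += d * (n - d) * na * nb / (n ** 2 * (n - 1))
    return O_a, E_a, O_b, E_b, V


def logrank_test(times_a, events_a, times_b, events_b) -> LogrankResult:
    """Mantel-Haenszel log-rank test between two groups.

    chi2 = (sum O_a - sum E_a)^2 / sum V with p from chi-square(1).  Symmetric
    in group order.
    """
    O_a, E_a, O_b, E_b, V = _logrank_table(times_a, events_a, times_b, events_b)
    if V <= 0:
        raise ValueError("zero log-rank variance; risk sets degenerate")
    chi2 = (O_a - E_a) ** 2 / V
    pvalue = float(stats.chi2.sf(chi2, df=1))
    return LogrankResult(chi2=float(chi2), pvalue=pvalue,
                         observed_a=O_a, expected_a=E_a,
                         observed_b=O_b, expected_b=E_b, variance=V)


def hazard_ratio_oe(times_a, events_a, times_b, events_b, alpha: float = 0.05):
    """O/E hazard ratio of group A vs group B with a normal log-scale CI.

    HR = (O_a/E_a) / (O_b/E_b); CI = exp(ln HR +/- z * sqrt(1/E_a + 1/E_b)).
    """
    O_a, E_a, O_b, E_b, _ = _logrank_table(times_a, events_a, times_b, events_b)
    if E_a <= 0 or E_b <= 0:
        raise ValueError("expected event counts must be positive in both groups")
    if O_a == 0 or O_b == 0:
        raise ValueError("observed events required in both groups for the O/E ratio")
    hr = (O_a / E_a) / (O_b / E_b)
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * math.sqrt(1 / E_a + 1 / E_b)
    ci = (hr * math.exp(-half), hr * math.exp(half))
    return hr, ci


def group_compare(a, b, method: str = "welch"):
    """Two-sample comparison: Welch's t or Mann-Whitney U, two-sided.

    Mann-Whitney uses the exact null distribution when sample sizes permit
    (no ties, small n) and the tie-corrected normal approximation otherwise.
    Returns (statistic, pvalue).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if method == "welch":
        if a.size < 2 or b.size < 2:
            raise ValueError("Welch's t needs n >= 2 per sample")
        if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
            if np.allclose(a.mean(), b.mean()):
                return 0.0, 1.0
            raise ValueError("zero variance in both samples with unequal means")
        res = stats.ttest_ind(a, b, equal_var=False)
        return float(res.statistic), float(res.pvalue)
    if method == "mannwhitney":
        if a.size < 1 or b.size < 1:
            raise ValueError("Mann-Whitney needs n >= 1 per sample")
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
        return float(res.statistic), float(res.pvalue)
    raise ValueError("method must be 'welch' or 'mannwhitney'")


def survival_summary(records: pd.DataFrame, group_col: str = "group",
                     time_col: str = "time_months", event_col: str = "event",
                     group_a: str = "MYC-high", group_b: str = "MYC-low") -> dict:
    """Per-group KM medians plus log-rank and O/E hazard ratio, as a dict."""
    sub_a = records[records[group_col] == group_a]
    sub_b = records[records[group_col] == group_b]
    km_a = km_estimate(sub_a[time_col], sub_a[event_col])
    km_b = km_estimate(sub_b[time_col], sub_b[event_col])
    lr = logrank_test(sub_a[time_col], sub_a[event_col], sub_b[time_col], sub_b[event_col])
    hr, ci = hazard_ratio_oe(sub_a[time_col], sub_a[event_col],
                             sub_b[time_col], sub_b[event_col])
    return {
        "median_a": None if not km_a.median_defined else km_a.median,
        "median_b": None if not km_b.median_defined else km_b.median,
        "chi2": lr.chi2,
        "pvalue": lr.pvalue,
        "hazard_ratio": hr,
        "hr_ci95": [ci[0], ci[1]],
        "n_a": km_a.n,
        "n_b": km_b.n,
        "events_a": km_a.n_events,
        "events_b": km_b.n_events,
    }


def score_group_summary(scores: pd.DataFrame, value_col: str,
                        group_col: str = "group") -> pd.DataFrame:
    """Per-group mean, SEM and n of an ordinal score column.

    Matches the histology-score reporting convention (mean +/- SEM per
    stratum); SEM is NaN for single-observation groups.
    """
    if value_col not in scores.columns or group_col not in scores.columns:
        raise KeyError(f"need columns {value_col!r} and {group_col!r}")
    grouped = scores.groupby(group_col)[value_col]
    out = grouped.agg(mean="mean", n="count")
    out["sem"] = grouped.agg(lambda v: v.std(ddof=1) / math.sqrt(len(v)) if len(v) > 1 else np.nan)
    return out
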