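"""Cohort-level statistics.

Driver-gene consensus voting across significantly-mutated-gene (SMG)
tools, Kaplan–Meier estimation and log-rank (Mantel–Cox) comparison of
overall survival, quantile stratification of expression values, and
Wilcoxon rank-sum group comparisons.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

__all__ = [
    "DEFAULT_TOOL_THRESHOLDS",
    "consensus_vote",
    "samples_with_driver",
    "km_estimator",
    "logrank_test",
    "stratify_expression",
    "wilcoxon_compare",
]

# Per-tool significance thresholds on the reported q-value / FDR.
DEFAULT_TOOL_THRESHOLDS = {
    "OncodriveFML": 0.05,
    "MutSigCV": 0.05,
    "MutPanning": 0.05,
}

DEFAULT_EXCEPTION_GENES = frozenset({"PBRM1"})


def consensus_vote(
    qvalues: pd.DataFrame,
    thresholds: dict[str, float] | None = None,
    min_tools: int = 2,
    exception_genes=DEFAULT_EXCEPTION_GENES,
) -> pd.DataFrame:
    """Vote genes into the driver consensus.

    ``qvalues`` is a gene x tool table of q-values/FDR (NaN = not
    reported).  A gene is a consensus driver when at least ``min_tools``
    tools call it significant (q strictly below the tool's threshold), or
    when it belongs to the exception set and at least one tool calls it.
    Returns a gene-indexed frame with per-gene vote counts and inclusion.
    """
    thresholds = dict(DEFAULT_TOOL_THRESHOLDS if thresholds is None else thresholds)
    for tool in qvalues.columns:
        if tool not in thresholds:
            thresholds[tool] = 0.05
    vals = qvalues.to_numpy(dtype=float)
    if np.nanmin(vals, initial=0.0) < 0 or np.nanmax(vals, initial=0.0) > 1:
        raise ValueError("q-values must lie in [0, 1]")
    votes = pd.Series(0, index=qvalues.index)
    for tool in qvalues.columns:
        votes += (qvalues[tool] < thresholds[tool]).fillna(False).astype(int)
    included = (votes >= min_tools) | (
        qvalues.index.isin(exception_genes) & (votes >= 1)
    )
    return pd.DataFrame({"votes": votes, "consensus": included})


def samples_with_driver(
    indicator: pd.DataFrame, drivers
) -> tuple[int, float]:
    """(count, fraction) of samples with >= 1 mutated consensus driver.

    ``indicator`` is a boolean sample x gene mutation table.
    """
    drivers = [g for g in drivers if g in indicator.columns]
    if not len(indicator):
        return 0, 0.0
    if not drivers:
        return 0, 0.0
    hit = indicator[drivers].astype(bool).any(axis=1)
    count = int(hit.sum())
    return count, count / len(indicator)


def km_estimator(times, events) -> pd.DataFrame:
    """Kaplan–Meier product-limit estimate.

    Returns a step function as a frame with columns ``time`` and
    ``survival`` (right-continuous; S(0) = 1; drops only at event times).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("survival data must contain at least one subject")
    if (times <= 0).any():
        raise ValueError("survival times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    return pd.DataFrame(
        {"time": sf.index.to_numpy(dtype=float), "survival": sf.iloc[:, 0].to_numpy()}
    )


def logrank_test(times, events, groups) -> tuple[float, float]:
    """Two-group log-rank (Mantel–Cox) test.

    Returns (chi-square statistic with 1 df, p-value).  Raises if either
    group is empty or more than two group labels are present.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"log-rank test requires exactly 2 groups, got {len(labels)}")
    a = groups == labels[0]
    if a.sum() == 0 or (~a).sum() == 0:
        raise ValueError("both groups must be non-empty")
    res = _ll_logrank(times[a], times[~a], events[a], events[~a])
    return float(res.test_statistic), float(res.p_value)


def stratify_expression(values, mode: str = "tertile") -> pd.Series:
    """Rank-based quantile stratification.

    ``mode='tertile'`` returns labels low/mid/high; ``mode='quartile'``
    returns q1..q4, where (q1, q4) is the designated low/high comparison
    pair.  Ties are broken by stable rank so tied boundary values fall in
    the lower stratum; strata sizes differ by at most one (larger strata
    first).
    """
    values = pd.Series(values)
    if mode == "tertile":
        names = ["low", "mid", "high"]
    elif mode == "quartile":
        names = ["q1", "q2", "q3", "q4"]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    n = len(values)
    if n < len(names):
        raise ValueError(f"{mode} stratification needs >= {len(names)} samples")
    order = np.argsort(values.to_numpy(), kind="stable")
    bins = np.array_split(np.arange(n), len(names))
    labels = np.empty(n, dtype=object)
    for name, idx in zip(names, bins):
        labels[order[idx]] = name
    return pd.Series(labels, index=values.index)


def wilcoxon_compare(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum comparison of two samples.

    Exact null distribution when both groups have <= 10 observations and
    no ties; otherwise the normal approximation with continuity
    correction.  Returns (Mann–Whitney U statistic, p-value).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < pooled.size
    if a.size <= 10 and b.size <= 10 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(min(res.pvalue, 1.0))
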