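"""Nonparametric time-course statistics for condition comparisons.

The study design compares a control and a senescent (TIS) population of
per-FOV (NLO) or per-cell (QPI) metric values at each time point with a
two-sided Mann-Whitney U test at significance level 0.05, plus
within-group tests of every later time point against the 0-hour
baseline. Colocalization coefficients (M1 vs M2, n = 10 each) are
compared with a pooled two-sample Student's t test.

Significance labels follow the conventional star mapping:
ns (p > 0.05), * (0.01 < p ≤ 0.05), ** (0.001 < p ≤ 0.01),
*** (0.0001 < p ≤ 0.001), **** (p ≤ 0.0001).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


class MannWhitneyResult(NamedTuple):
    u: float
    p: float
    method: str  # "exact" or "asymptotic"


class TTestResult(NamedTuple):
    t: float
    p: float
    degenerate: bool


@dataclass
class TestResult:
    metric: str
    comparison: str  # "control_vs_tis" or "vs_baseline"
    group_a: str
    group_b: str
    time_point: str
    n_a: int
    n_b: int
    statistic: float
    p_two_sided: float
    stars: str
    skipped: str = ""  # non-empty reason when the test was not run


def _as_array(x: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(list(x), dtype=float)
    if arr.size == 0:
        raise ValueError(f"empty sample {name!r}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"non-finite values in sample {name!r}")
    return arr


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    The null distribution is enumerated exactly when the pooled sample
    is small (n + m ≤ 16) and untied; otherwise the normal
    approximation with tie and continuity corrections is used. The
    method actually applied is recorded in the result.
    """
    xa, ya = _as_array(x, "x"), _as_array(y, "y")
    pooled = np.concatenate([xa, ya])
    ties = np.unique(pooled).size < pooled.size
    exact = (xa.size + ya.size) <= 16 and not ties
    res = sps.mannwhitneyu(
        xa, ya, alternative="two-sided", method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return MannWhitneyResult(float(res.statistic), float(res.pvalue), "exact" if exact else "asymptotic")


def students_t_two_sided(x: Sequence[float], y: Sequence[float]) -> TTestResult:
    """Pooled-variance two-sample t test, two-sided.

    Zero pooled variance is degenerate: identical means give p = 1,
    different means give p = 0 with the degenerate flag set.
    """
    xa, ya = _as_array(x, "x"), _as_array(y, "y")
    if xa.size < 2 or ya.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if np.ptp(xa) == 0 and np.ptp(ya) == 0:
        if xa.mean() == ya.mean():
            return TTestResult(0.0, 1.0, True)
        return TTestResult(np.inf, 0.0, True)
    res = sps.ttest_ind(xa, ya, equal_var=True)
    return TTestResult(float(res.statistic), float(res.pvalue), False)


def significance_stars(p: float) -> str:
    """Map a p-value to its star label (boundaries inclusive toward stars)."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p-value {p} outside [0, 1]")
    if p > 0.05:
        return "ns"
    if p > 0.01:
        return "*"
    if p > 0.001:
        return "**"
    if p > 0.0001:
        return "***"
    return "****"


REQUIRED_COLUMNS = ("condition", "time_point", "unit_id", "metric", "value")


def _run_test(metric, comparison, label_a, label_b, time_point, xa, xb, min_n=3) -> TestResult:
    n_a, n_b = len(xa), len(xb)
    if n_a < min_n or n_b < min_n:
        return TestResult(metric, comparison, label_a, label_b, time_point, n_a, n_b,
                          float("nan"), float("nan"), "", skipped=f"group n < {min_n}")
    res = mann_whitney_u(xa, xb)
    return TestResult(metric, comparison, label_a, label_b, time_point, n_a, n_b,
                      res.u, res.p, significance_stars(res.p))


def timecourse_report(
    table: pd.DataFrame,
    baseline: str | None = None,
    time_order: Sequence[str] | None = None,
    min_n: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Condition and time-point comparisons for a long-format metrics table.

    ``table`` needs columns (condition, time_point, unit_id, metric,
    value); conditions are 'control' and 'TIS'. For every metric the
    report contains the control-vs-TIS Mann-Whitney test at each time
    point and, within each condition, each later time point against the
    baseline (first time point unless given). Returns (tests, summary)
    where summary holds mean, SD and n per condition × time × metric.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"metrics table lacks columns {missing}")
    if len(table) == 0:
        raise ValueError("empty metrics table")
    table = table.dropna(subset=["value"])
    if time_order is None:
        time_order = list(pd.unique(table["time_point"]))
    if baseline is None:
        baseline = time_order[0]
    conditions = list(pd.unique(table["condition"]))
    if len(conditions) < 2:
        raise ValueError("need at least two conditions to compare")

    results: list[TestResult] = []
    for metric, sub in table.groupby("metric", sort=False):
        groups = {
            (c, t): g["value"].to_numpy()
            for (c, t), g in sub.groupby(["condition", "time_point"], sort=False)
        }
        for t in time_order:
            a = groups.get(("control", t))
            b = groups.get(("TIS", t))
            if a is None or b is None:
                continue
            results.append(_run_test(metric, "control_vs_tis", f"control@{t}", f"TIS@{t}", t, a, b, min_n))
        for cond in conditions:
            base = groups.get((cond, baseline))
            if base is None:
                continue
            for t in time_order:
                if t == baseline:
                    continue
                cur = groups.get((cond, t))
                if cur is None:
                    continue
                results.append(
                    _run_test(metric, "vs_baseline", f"{cond}@{baseline}", f"{cond}@{t}", t, base, cur, min_n)
                )
    tests = pd.DataFrame([r.__dict__ for r in results])
    summary = (
        table.groupby(["metric", "condition", "time_point"], sort=False)["value"]
        .agg(["mean", "std", "count"])
        .reset_index()
        .rename(columns={"count": "n", "std": "sd"})
    )
    return tests, summary


def benjamini_hochberg(pvals: Sequence[float]) -> np.ndarray:
    """Optional BH-adjusted p-values (off by default in reports)."""
    p = np.asarray(pvals, dtype=float)
    order = np.argsort(p)
    ranked = p[order] * p.size / (np.arange(p.size) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(adj)
    out[order] = np.clip(adj, 0, 1)
    return out
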