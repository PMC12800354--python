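"""Cohort statistics: contingency tests, Student t, Kaplan-Meier, log-rank.

The conventions match standard clinical-table practice for this kind of
cohort description:

* Pearson chi-squared without continuity correction (reproduces the printed
  three-decimal p-values of the cohort comparison tables);
* Fisher's exact test (two-sided, point-probability rule) for 2x2 tables,
  preferred automatically when any expected cell is below 5;
* pooled-variance two-sided Student t for continuous variables;
* Kaplan-Meier product-limit curves compared by the log-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats as sps


class StatsError(ValueError):
    """Invalid input to a statistical test."""


@dataclass
class TestResult:
    statistic: float
    df: int
    p: float


def _as_table(table) -> np.ndarray:
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2:
        raise StatsError("contingency table must be 2-dimensional")
    if np.any(arr < 0) or not np.allclose(arr, np.rint(arr)):
        raise StatsError("contingency table needs non-negative integer counts")
    return arr


def pearson_chi2(table) -> TestResult:
    """Pearson chi-squared on an r x c table, no continuity correction."""
    arr = _as_table(table)
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise StatsError("all table margins must be positive")
    stat, p, df, _ = sps.chi2_contingency(arr, correction=False)
    return TestResult(statistic=float(stat), df=int(df), p=float(p))


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table (point-probability rule).

    Sums the hypergeometric probabilities of all tables with the observed
    margins whose point probability does not exceed the observed table's.
    """
    arr = _as_table(table)
    if arr.shape != (2, 2):
        raise StatsError("Fisher exact test implemented for 2x2 tables only")
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise StatsError("all table margins must be positive")
    return float(sps.fisher_exact(arr.astype(int), alternative="two-sided")[1])


def choose_categorical_test(table) -> str:
    """'fisher' for a 2x2 with any expected cell < 5, else 'chi2'."""
    arr = _as_table(table)
    expected = np.outer(arr.sum(axis=1), arr.sum(axis=0)) / arr.sum()
    if arr.shape == (2, 2) and np.any(expected < 5):
        return "fisher"
    return "chi2"


def student_t(x, y) -> TestResult:
    """Pooled-variance two-sided Student t test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise StatsError("each group needs n >= 2")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        if np.mean(x) == np.mean(y):
            return TestResult(statistic=0.0, df=len(x) + len(y) - 2, p=1.0)
        raise StatsError("zero pooled variance with unequal means: t undefined")
    stat, p = sps.ttest_ind(x, y, equal_var=True)
    return TestResult(statistic=float(stat), df=len(x) + len(y) - 2, p=float(p))


@dataclass
class KMEstimate:
    """Right-continuous product-limit survival curve with S(0) = 1."""

    times: np.ndarray  # event/censor times in ascending order
    survival: np.ndarray  # S(t) just after each time

    def evaluate(self, t) -> np.ndarray:
        """S(t) for scalar or array t (step function, right-continuous)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx < 0, 1.0, self.survival[np.clip(idx, 0, None)])
        return out if out.size > 1 else out[0]


def km_estimator(times, events) -> KMEstimate:
    """Kaplan-Meier product-limit estimator."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) < 1:
        raise StatsError("need at least one subject")
    if np.any(times <= 0) or not np.all(np.isfinite(times)):
        raise StatsError("survival times must be positive and finite")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    t = sf.index.to_numpy(dtype=float)
    s = sf.iloc[:, 0].to_numpy(dtype=float)
    keep = t > 0
    return KMEstimate(times=t[keep], survival=s[keep])


def logrank_test(times, events, groups) -> TestResult:
    """Log-rank comparison of >= 2 groups; chi-squared with df = groups - 1."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) < 2:
        raise StatsError("log-rank needs at least two groups")
    if events.sum() == 0:
        raise StatsError("log-rank undefined without any observed event")
    res = multivariate_logrank_test(times, groups, events)
    return TestResult(
        statistic=float(res.test_statistic),
        df=len(labels) - 1,
        p=float(res.p_value),
    )


def survival_by_group(df: pd.DataFrame, group_col: str) -> dict[str, KMEstimate]:
    """KM curve per level of ``group_col`` (expects time_months/event columns)."""
    return {
        str(level): km_estimator(
            sub["time_months"].to_numpy(), sub["event"].to_numpy()
        )
        for level, sub in df.groupby(group_col)
    }
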