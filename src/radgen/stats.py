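"""Cohort-level statistics: contingency-table tests, Kaplan-Meier /
log-rank survival comparison, and robust linear regression.

These wrap the standard scipy / lifelines / statsmodels routines behind the
conventions used throughout the analysis: Pearson chi-square without
continuity correction, Fisher's exact test when any expected cell count is
below 5, Mantel-Cox log-rank, and bisquare IRLS regression.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats as sps
import statsmodels.api as sm


@dataclasses.dataclass
class TestResult:
    statistic: float | None
    df: int | None
    p_value: float
    test: str  # "chi-square" | "fisher"


def _validate_table(table) -> np.ndarray:
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("table must contain non-negative integer counts")
    if t.sum() == 0:
        raise ValueError("empty table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero row or column margin")
    return t


def expected_counts(table) -> np.ndarray:
    t = _validate_table(table)
    return np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()


def chi_square_test(table) -> TestResult:
    """Pearson chi-square without continuity correction."""
    t = _validate_table(table)
    stat, p, df, _ = sps.chi2_contingency(t, correction=False)
    return TestResult(float(stat), int(df), float(p), "chi-square")


def fisher_exact_test(table) -> TestResult:
    """Two-sided Fisher exact test on a 2x2 table (sum of hypergeometric
    probabilities no larger than the observed table's)."""
    t = _validate_table(table)
    if t.shape != (2, 2):
        raise ValueError("Fisher exact test requires a 2x2 table")
    _, p = sps.fisher_exact(t.astype(int), alternative="two-sided")
    return TestResult(None, None, float(p), "fisher")


def select_test(table) -> TestResult:
    """Chi-square unless any expected cell count is < 5, then Fisher."""
    t = _validate_table(table)
    if t.shape == (2, 2) and expected_counts(t).min() < 5:
        return fisher_exact_test(t)
    return chi_square_test(t)


def format_p(p: float, decimals: int = 3) -> str:
    """Printing convention of the cohort tables: round to 3 decimals;
    '<0.001' only when the rounded value would print as 0.000 (so that
    e.g. p = 5.7e-4 prints as 0.001, matching the published tables)."""
    threshold = 10 ** (-decimals)
    if round(p, decimals) < threshold:
        return f"<{threshold:.{decimals}f}"
    return f"{p:.{decimals}f}"


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------

def _check_survival(time, event) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    if t.size == 0:
        raise ValueError("need at least one record")
    if (t < 0).any():
        raise ValueError("negative survival time")
    if not np.isin(e, (0, 1)).all():
        raise ValueError("event flags must be 0/1")
    return t, e


def km_estimate(time, event) -> KaplanMeierFitter:
    """Product-limit survival estimator (ties handled by simultaneous
    multiplication at tied event times)."""
    t, e = _check_survival(time, event)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    return kmf


def km_survival_at(kmf: KaplanMeierFitter, times) -> np.ndarray:
    return kmf.survival_function_at_times(np.asarray(times, dtype=float)).to_numpy()


@dataclasses.dataclass
class LogrankResult:
    statistic: float
    df: int
    p_value: float


def logrank_test(time, event, group) -> LogrankResult:
    """Mantel-Cox log-rank test across >= 2 groups (df = groups - 1)."""
    t, e = _check_survival(time, event)
    g = np.asarray(group)
    groups = np.unique(g)
    if groups.size < 2:
        raise ValueError("need at least two non-empty groups")
    if e.sum() == 0:
        warnings.warn("all records censored: log-rank statistic 0, p = 1", UserWarning)
        return LogrankResult(0.0, int(groups.size - 1), 1.0)
    res = multivariate_logrank_test(t, g, e)
    return LogrankResult(float(res.test_statistic), int(groups.size - 1),
                         float(res.p_value))


# ---------------------------------------------------------------------------
# Robust regression
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RobustFit:
    slope: float
    intercept: float
    slope_p: float


def robust_regression(x, y) -> RobustFit:
    """IRLS linear fit with Tukey bisquare weights (tuning constant 4.685)
    and an intercept; the slope p-value comes from the final weighted fit."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate constant x")
    X = sm.add_constant(x)
    fit = sm.RLM(y, X, M=sm.robust.norms.TukeyBiweight(c=4.685)).fit()
    return RobustFit(float(fit.params[1]), float(fit.params[0]),
                     float(fit.pvalues[1]))
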