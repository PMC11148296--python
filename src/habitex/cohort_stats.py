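"""Group comparison of features between high and low Ki-67 cohorts, plus
the clinicopathological summary statistics computable from printed tables.

Per feature, a Shapiro-Wilk normality gate (alpha 0.05 on each group)
routes the comparison to an independent two-sample t-test when both groups
look normal, else to the Mann-Whitney U test; p-values are two-sided and
deliberately unadjusted (the screen keeps raw p < 0.05; a
Benjamini-Hochberg option exists but is off by default).  The Manhattan
data are -log10 p per feature with the significance line at
-log10(0.05) ~ 1.301.

Contingency comparisons use the chi-square test with Yates continuity
correction for 2x2 tables and the plain chi-square for larger tables.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidCohortError, UndefinedTestError

logger = logging.getLogger(__name__)

__all__ = [
    "ScreenResult",
    "GroupSummary",
    "compare_feature",
    "screen_table",
    "pooled_mean_sd",
    "categorical_test",
    "summary_t_test",
    "MANHATTAN_LINE",
]

MANHATTAN_LINE = -np.log10(0.05)


@dataclass
class ScreenResult:
    feature: str
    test: str  # "t" or "mann-whitney"
    p_value: float
    neg_log10_p: float
    significant: bool


@dataclass
class GroupSummary:
    """Printed per-group summary of a continuous variable."""

    n: int
    mean: float
    sd: float


def _is_normal(sample: np.ndarray, alpha: float) -> bool:
    if np.ptp(sample) == 0 or sample.size < 3:
        return False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return stats.shapiro(sample).pvalue > alpha


def compare_feature(high: np.ndarray, low: np.ndarray,
                    alpha_normality: float = 0.05,
                    feature: str = "") -> ScreenResult:
    """Normality-gated two-sample comparison, two-sided."""
    high = np.asarray(high, dtype=np.float64)
    low = np.asarray(low, dtype=np.float64)
    if high.size < 3 or low.size < 3:
        raise ValueError("need at least 3 subjects per group")
    if np.ptp(high) == 0 and np.ptp(low) == 0 and high[0] == low[0]:
        logger.warning("feature %s constant in both groups; p = 1", feature)
        return ScreenResult(feature, "t", 1.0, 0.0, False)
    if _is_normal(high, alpha_normality) and _is_normal(low, alpha_normality):
        test = "t"
        p = float(stats.ttest_ind(high, low, equal_var=True).pvalue)
    else:
        test = "mann-whitney"
        p = float(stats.mannwhitneyu(high, low, alternative="two-sided").pvalue)
    p = min(max(p, np.finfo(float).tiny), 1.0)
    return ScreenResult(feature, test, p, float(-np.log10(p)), p < 0.05)


def screen_table(features: pd.DataFrame, labels,
                 alpha_normality: float = 0.05,
                 adjust: str | None = None) -> pd.DataFrame:
    """Screen every feature column; returns a tidy results frame.

    Columns: feature, test, p_value, neg_log10_p, significant.  ``adjust``
    may be "bh" for Benjamini-Hochberg (off by default).
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise InvalidCohortError(f"need exactly 2 classes, got {classes}")
    hi, lo = ("high", "low") if set(classes) == {"high", "low"} else classes[::-1]
    mask_hi = labels == hi
    results = [
        compare_feature(features[c].to_numpy()[mask_hi],
                        features[c].to_numpy()[~mask_hi],
                        alpha_normality, feature=c)
        for c in features.columns
    ]
    df = pd.DataFrame([r.__dict__ for r in results])
    if adjust == "bh":
        from statsmodels.stats.multitest import multipletests
        rej, p_adj, _, _ = multipletests(df["p_value"], method="fdr_bh")
        df["p_adjusted"] = p_adj
        df["significant"] = rej
    return df


def pooled_mean_sd(groups: list[GroupSummary]) -> tuple[float, float]:
    """Combine per-group (n, mean, SD) into the overall mean and SD.

    Within-group and between-group sums of squares are pooled with
    denominator (sum n_i - 1), so the result equals the SD of the
    concatenated raw samples.
    """
    if not groups:
        raise ValueError("need at least one group")
    n_tot = sum(g.n for g in groups)
    mean = sum(g.n * g.mean for g in groups) / n_tot
    ss = sum((g.n - 1) * g.sd ** 2 + g.n * (g.mean - mean) ** 2 for g in groups)
    return float(mean), float(np.sqrt(ss / (n_tot - 1)))


def categorical_test(table) -> float:
    """Chi-square p-value for an r x c contingency table.

    2x2 tables use the Yates continuity correction; larger tables the
    plain chi-square.  Zero marginals are undefined.
    """
    tab = np.asarray(table, dtype=np.float64)
    if tab.ndim != 2 or min(tab.shape) < 2:
        raise UndefinedTestError("need at least a 2x2 table")
    if (tab < 0).any():
        raise UndefinedTestError("counts must be nonnegative")
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        raise UndefinedTestError("zero marginal; chi-square undefined")
    correction = tab.shape == (2, 2)
    res = stats.chi2_contingency(tab, correction=correction)
    return float(res.pvalue)


def summary_t_test(a: GroupSummary, b: GroupSummary) -> tuple[float, float]:
    """Pooled-variance two-sample t-test from printed summaries."""
    if a.n < 2 or b.n < 2:
        raise ValueError("need n >= 2 per group")
    res = stats.ttest_ind_from_stats(a.mean, a.sd, a.n, b.mean, b.sd, b.n,
                                     equal_var=True)
    return float(res.statistic), float(res.pvalue)
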