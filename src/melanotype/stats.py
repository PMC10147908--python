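"""The statistical battery applied to typed cohorts.

Test selection follows the analysis protocol: two-group comparisons are
gated on a Shapiro–Wilk normality check (both groups p > 0.05 → Student's
t; otherwise Mann–Whitney U), three or more groups use Kruskal–Wallis,
categorical contingency tables use Pearson chi-square, and OD-vs-feature
associations use ordinary least squares with a two-sided slope test. All p
values are two-sided; no multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "compare_two_groups",
    "kruskal_wallis",
    "chi_square_table",
    "linreg_feature_vs_od",
    "compare_by_group",
]

SHAPIRO_MAX_N = 5_000  # the test is unstable for very large n; subsample cap


@dataclass
class TestResult:
    test: str
    statistic: float
    p_value: float
    group_sizes: tuple[int, ...]
    effect: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError("p value outside [0, 1]")


def _shapiro_p(x, rng) -> float:
    x = np.asarray(x, dtype=float)
    if len(x) > SHAPIRO_MAX_N:
        x = rng.choice(x, size=SHAPIRO_MAX_N, replace=False)
    if np.ptp(x) == 0:
        return 0.0  # a constant sample is maximally non-normal
    return float(sps.shapiro(x).pvalue)


def compare_two_groups(x, y, alpha_normality: float = 0.05, seed: int = 0) -> TestResult:
    """Two-sided two-group comparison with a normality gate.

    Both samples pass Shapiro–Wilk (p > alpha, subsampled to 5,000 for
    large n) → Student's t test; otherwise Mann–Whitney U (exact when both
    n <= 20 and tie-free, normal approximation with continuity and tie
    correction otherwise).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("each sample needs n >= 3")
    rng = np.random.default_rng(seed)
    normal = _shapiro_p(x, rng) > alpha_normality and _shapiro_p(y, rng) > alpha_normality
    if normal:
        res = sps.ttest_ind(x, y)
        name = "student_t"
    else:
        exact = (
            len(x) <= 20
            and len(y) <= 20
            and len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
        )
        res = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
        )
        name = "mann_whitney_u"
    return TestResult(
        test=name,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        group_sizes=(len(x), len(y)),
        effect={
            "mean_x": float(np.mean(x)),
            "mean_y": float(np.mean(y)),
            "median_x": float(np.median(x)),
            "median_y": float(np.median(y)),
        },
    )


def kruskal_wallis(groups) -> TestResult:
    """Kruskal–Wallis H (tie-corrected, chi-square approximation) for >= 3 groups."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 3:
        raise ValueError("Kruskal-Wallis requires at least 3 groups")
    if any(len(g) < 1 for g in groups) or sum(len(g) for g in groups) < 5:
        raise ValueError("each group needs n >= 1 and total n >= 5")
    res = sps.kruskal(*groups)
    return TestResult(
        test="kruskal_wallis",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        group_sizes=tuple(len(g) for g in groups),
        effect={"medians": [float(np.median(g)) for g in groups]},
    )


def chi_square_table(counts) -> TestResult:
    """Pearson chi-square (no continuity correction) on an r x c table."""
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("table has a zero marginal")
    chi2, p, dof, _ = sps.chi2_contingency(table, correction=False)
    return TestResult(
        test="pearson_chi2",
        statistic=float(chi2),
        p_value=float(p),
        group_sizes=tuple(int(s) for s in table.sum(axis=1)),
        effect={"dof": int(dof)},
    )


def linreg_feature_vs_od(x, y) -> TestResult:
    """OLS of y on x with a two-sided slope test (e.g. nucleus area vs BAP-1 OD)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need n >= 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope undefined")
    res = sps.linregress(x, y)
    return TestResult(
        test="ols_slope",
        statistic=float(res.slope),
        p_value=float(res.pvalue),
        group_sizes=(len(x),),
        effect={"intercept": float(res.intercept), "r": float(res.rvalue)},
    )


def compare_by_group(
    table: pd.DataFrame, feature: str, by: str, seed: int = 0
) -> TestResult:
    """Dispatch on the number of groups: 2 → gated t/U test, >= 3 → Kruskal–Wallis."""
    groups = [g[feature].to_numpy() for _, g in table.groupby(by, observed=True)]
    if len(groups) < 2:
        raise ValueError(f"column {by!r} has fewer than 2 groups")
    if len(groups) == 2:
        return compare_two_groups(groups[0], groups[1], seed=seed)
    return kruskal_wallis(groups)
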