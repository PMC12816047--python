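"""Two-group and multi-group comparisons with automatic test selection.

The decision procedure mirrors common practice for small biological group
comparisons at alpha = 0.05: Shapiro-Wilk normality on each group; if
either rejects, a two-sided Mann-Whitney U test; otherwise Levene's test
(median-centered) for equal variances; if it rejects, Welch's t, else
Student's t. Every intermediate outcome is recorded in a decision trail so
the selected test is fully auditable. One-way ANOVA covers multi-group
designs, and percent-positive converts cell counts into the percentages
used for immunofluorescence quantification. No multiple-testing correction
is applied by default; a Bonferroni helper is provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import DegenerateInputError, InsufficientDataError, ValidationError

__all__ = [
    "TestResult",
    "select_and_compare",
    "one_way_anova",
    "percent_positive",
    "bonferroni",
]

DEFAULT_ALPHA = 0.05


@dataclass
class TestResult:
    test_name: str  # student_t | welch_t | mann_whitney | anova
    statistic: float
    p_value: float
    alpha: float = DEFAULT_ALPHA
    decision_trail: dict = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    def to_dict(self) -> dict:
        return {
            "test_name": self.test_name,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "alpha": self.alpha,
            "significant": self.significant,
            "decision_trail": self.decision_trail,
        }


def _shapiro_p(x: np.ndarray) -> float:
    # Shapiro-Wilk is undefined on constant data; treat it as non-normal so
    # the comparison falls through to the rank test, which tolerates ties.
    if np.ptp(x) == 0:
        return 0.0
    return float(stats.shapiro(x).pvalue)


def select_and_compare(
    group_a, group_b, alpha: float = DEFAULT_ALPHA
) -> TestResult:
    """Compare two groups with the appropriate two-sided test.

    Selection: Shapiro-Wilk on each group at ``alpha``; any rejection ->
    Mann-Whitney U. Otherwise Levene (median-centered) at ``alpha``;
    rejection -> Welch's t, else Student's t.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise InsufficientDataError(
            f"each group needs >= 3 observations (got {len(a)}, {len(b)})"
        )
    trail: dict = {"alpha": alpha}
    trail["shapiro_p_a"] = _shapiro_p(a)
    trail["shapiro_p_b"] = _shapiro_p(b)
    nonnormal = trail["shapiro_p_a"] < alpha or trail["shapiro_p_b"] < alpha
    trail["normality_rejected"] = bool(nonnormal)
    if nonnormal:
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        return TestResult("mann_whitney", float(res.statistic),
                          float(res.pvalue), alpha, trail)
    lev = stats.levene(a, b, center="median")
    trail["levene_p"] = float(lev.pvalue)
    heteroscedastic = lev.pvalue < alpha
    trail["equal_variance_rejected"] = bool(heteroscedastic)
    res = stats.ttest_ind(a, b, equal_var=not heteroscedastic)
    name = "welch_t" if heteroscedastic else "student_t"
    return TestResult(name, float(res.statistic), float(res.pvalue), alpha, trail)


def one_way_anova(groups, alpha: float = DEFAULT_ALPHA) -> TestResult:
    """Ordinary one-way ANOVA across two or more groups."""
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise InsufficientDataError("ANOVA needs at least 2 groups")
    for i, g in enumerate(arrs):
        if len(g) < 2:
            raise InsufficientDataError(f"group {i} has fewer than 2 observations")
    ssw = sum(((g - g.mean()) ** 2).sum() for g in arrs)
    if ssw == 0:
        raise DegenerateInputError("zero within-group variance in every group")
    res = stats.f_oneway(*arrs)
    trail = {"n_groups": len(arrs), "group_sizes": [len(g) for g in arrs]}
    return TestResult("anova", float(res.statistic), float(res.pvalue), alpha, trail)


def percent_positive(n_positive: int, n_total: int) -> float:
    """Percentage of positive cells among all cells counted."""
    if n_total <= 0:
        raise ValidationError("n_total must be positive")
    if not 0 <= n_positive <= n_total:
        raise ValidationError(
            f"n_positive must be in [0, {n_total}], got {n_positive}"
        )
    return 100.0 * n_positive / n_total


def bonferroni(p_values) -> np.ndarray:
    """Bonferroni-adjusted p-values: min(1, m * p)."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    return np.minimum(1.0, p * p.size)
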