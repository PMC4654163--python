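"""Group comparisons for clinical variables.

Continuous variables: Welch t-test (default), one-way ANOVA, or the exact
Wilcoxon rank-sum test (exact enumeration, appropriate at these group sizes
of 4-10), followed by Bonferroni correction over the stated number of
comparisons. Categorical variables: two-sided Fisher's exact test on 2x2
counts. All tests are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import ValidationError

__all__ = ["GroupComparison", "compare_continuous", "compare_categorical",
           "bonferroni"]


@dataclass
class GroupComparison:
    variable: str
    groups: tuple[str, ...]
    method: str
    statistic: float
    p: float
    p_adjusted: float
    n_per_group: tuple[int, ...]


def bonferroni(p: float, n_comparisons: int) -> float:
    if n_comparisons < 1:
        raise ValidationError("n_comparisons must be >= 1")
    return min(1.0, p * n_comparisons)


def compare_continuous(values_by_group: dict[str, list[float]],
                       method: str = "t",
                       n_comparisons: int = 1,
                       variable: str = "") -> GroupComparison:
    """Two-group t/Wilcoxon or multi-group ANOVA with Bonferroni adjustment."""
    groups = tuple(values_by_group)
    samples = [np.asarray(values_by_group[g], dtype=float) for g in groups]
    if method in ("t", "wilcoxon") and len(samples) != 2:
        raise ValidationError(f"{method} test needs exactly 2 groups")
    if method == "anova" and len(samples) < 2:
        raise ValidationError("ANOVA needs >=2 groups")
    if method in ("t", "anova") and any(len(s) < 2 for s in samples):
        small = groups[[len(s) < 2 for s in samples].index(True)]
        raise ValidationError(
            f"group {small!r} has <2 values for a variance-based test")
    if method == "t":
        res = stats.ttest_ind(samples[0], samples[1], equal_var=False)
        stat, p = float(res.statistic), float(res.pvalue)
        if np.isnan(stat):  # identical constant groups -> no evidence
            stat, p = 0.0, 1.0
    elif method == "anova":
        res = stats.f_oneway(*samples)
        stat, p = float(res.statistic), float(res.pvalue)
        if np.isnan(stat):
            stat, p = 0.0, 1.0
    elif method == "wilcoxon":
        if any(len(s) < 1 for s in samples):
            raise ValidationError("wilcoxon needs >=1 value per group")
        # exact enumeration of the rank-sum null at these small sizes
        res = stats.mannwhitneyu(samples[0], samples[1],
                                 alternative="two-sided", method="exact")
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        raise ValidationError(f"unknown method {method!r}")
    return GroupComparison(
        variable=variable, groups=groups, method=method,
        statistic=stat, p=p, p_adjusted=bonferroni(p, n_comparisons),
        n_per_group=tuple(len(s) for s in samples))


def compare_categorical(table: list[list[int]] | np.ndarray,
                        n_comparisons: int = 1,
                        variable: str = "",
                        groups: tuple[str, ...] = ("A", "B")) -> GroupComparison:
    """Two-sided Fisher's exact test on a 2x2 contingency table.

    Two-sidedness follows the point-probability rule: the p-value sums the
    probabilities of all tables (under the hypergeometric null with the
    observed margins) whose probability does not exceed that of the observed
    table.
    """
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValidationError("contingency table must be 2x2")
    if (arr < 0).any() or not np.issubdtype(arr.dtype, np.integer):
        raise ValidationError("cells must be non-negative integers")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValidationError("both margins must be positive")
    odds, p = stats.fisher_exact(arr, alternative="two-sided")
    return GroupComparison(
        variable=variable, groups=groups, method="fisher",
        statistic=float(odds), p=float(p),
        p_adjusted=bonferroni(float(p), n_comparisons),
        n_per_group=tuple(int(x) for x in arr.sum(axis=0)))
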