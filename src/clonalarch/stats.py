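"""Group comparisons: rank-sum test, Fisher's exact test on a 2x2 table, and
Tukey HSD all-pairs mean comparison with a compact letter display."""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats as sps


@dataclass
class GroupComparison:
    """Outcome of a two-group (or pairwise) hypothesis test."""

    test: str
    statistic: float
    p_value: float
    effect: Optional[float]          # difference of means, or odds ratio
    effect_name: str
    group_labels: tuple[str, ...]
    group_sizes: tuple[int, ...]
    extra: dict = field(default_factory=dict)


@dataclass
class TukeyResult:
    """All-pairs Tukey HSD comparison with compact letter display."""

    labels: tuple[str, ...]
    means: dict[str, float]
    pairwise: list[GroupComparison]
    letters: dict[str, str]
    alpha: float


def _has_ties(pooled: Sequence[float]) -> bool:
    return len(set(pooled)) < len(pooled)


def rank_sum_test(
    x: Sequence[float],
    y: Sequence[float],
    labels: tuple[str, str] = ("x", "y"),
) -> GroupComparison:
    """Two-sided Mann-Whitney / Wilcoxon rank-sum test.

    Uses the exact null distribution when both groups have n <= 10 and there
    are no ties, otherwise the normal approximation with midrank tie
    correction (and continuity correction).
    """
    x = list(map(float, x))
    y = list(map(float, y))
    if not x or not y:
        raise ValueError("both groups must be non-empty")
    pooled = x + y
    if len(set(pooled)) == 1:
        warnings.warn("all values identical across both groups", stacklevel=2)
        return GroupComparison(
            "rank_sum", float(len(x) * len(y) / 2), 1.0,
            0.0, "mean_difference", labels, (len(x), len(y)),
        )
    exact = len(x) <= 10 and len(y) <= 10 and not _has_ties(pooled)
    method = "exact" if exact else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return GroupComparison(
        test="rank_sum",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        effect=float(np.mean(x) - np.mean(y)),
        effect_name="mean_difference",
        group_labels=labels,
        group_sizes=(len(x), len(y)),
        extra={"method": method},
    )


def fisher_exact_2x2(
    table: Sequence[Sequence[int]],
    labels: tuple[str, str] = ("group1", "group2"),
) -> GroupComparison:
    """Two-sided Fisher's exact test on a 2x2 table of counts.

    The p-value sums hypergeometric probabilities of all tables (at fixed
    margins) no more likely than the observed one.  Reports the sample odds
    ratio ``ad/bc`` with a Woolf (log) 95% CI; a zero margin gives p = 1 and
    an undefined odds ratio.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of non-negative integer counts")
    (a, b), (c, d) = t
    if 0 in t.sum(axis=0) or 0 in t.sum(axis=1):
        return GroupComparison(
            "fisher_exact", float("nan"), 1.0, None, "odds_ratio",
            labels, (int(a + b), int(c + d)),
            extra={"or_ci_low": None, "or_ci_high": None},
        )
    _, p = sps.fisher_exact(t, alternative="two-sided")
    odds = (a * d) / (b * c) if b * c > 0 else float("inf")
    if min(a, b, c, d) > 0:
        se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        log_or = math.log(odds)
        ci = (math.exp(log_or - 1.96 * se), math.exp(log_or + 1.96 * se))
    else:
        ci = (None, None)
    return GroupComparison(
        test="fisher_exact",
        statistic=float(odds),
        p_value=float(p),
        effect=float(odds),
        effect_name="odds_ratio",
        group_labels=labels,
        group_sizes=(int(a + b), int(c + d)),
        extra={"or_ci_low": ci[0], "or_ci_high": ci[1]},
    )


def _compact_letter_display(
    labels: Sequence[str], significant: set[tuple[str, str]]
) -> dict[str, str]:
    """Insert-absorb compact letter display.

    Groups sharing a letter are statistically indistinguishable; the
    ``significant`` set holds unordered label pairs that differ.  Group order
    (and therefore letter assignment) follows the given label order.
    """
    columns: list[set[str]] = [set(labels)]
    for g1, g2 in sorted(significant):
        new_columns: list[set[str]] = []
        for col in columns:
            if g1 in col and g2 in col:
                new_columns.append(col - {g1})
                new_columns.append(col - {g2})
            else:
                new_columns.append(col)
        # absorb: drop columns contained in another
        columns = []
        for col in new_columns:
            if any(col < other for other in new_columns if other is not col):
                continue
            if col not in columns:
                columns.append(col)
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {label: "" for label in labels}
    for i, col in enumerate(columns):
        for label in labels:
            if label in col:
                letters[label] += alphabet[i % len(alphabet)]
    return letters


def all_pairs_mean_comparison(
    groups: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
) -> TukeyResult:
    """Tukey HSD on a one-way layout, with compact letter display.

    Family-wise-adjusted p-values come from the studentized-range
    distribution; groups whose adjusted p >= alpha share a letter.
    """
    labels = tuple(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(groups[g], dtype=float) for g in labels]
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least two observations")
    if all(float(a.var(ddof=1)) == 0.0 for a in arrays):
        warnings.warn("zero within-group variance in every group", stacklevel=2)
    res = sps.tukey_hsd(*arrays)
    means = {g: float(a.mean()) for g, a in zip(labels, arrays)}
    pairwise: list[GroupComparison] = []
    significant: set[tuple[str, str]] = set()
    for i, j in itertools.combinations(range(len(labels)), 2):
        p = float(res.pvalue[i, j])
        diff = means[labels[i]] - means[labels[j]]
        pairwise.append(
            GroupComparison(
                test="tukey_hsd",
                statistic=float(res.statistic[i, j]),
                p_value=p,
                effect=diff,
                effect_name="mean_difference",
                group_labels=(labels[i], labels[j]),
                group_sizes=(arrays[i].size, arrays[j].size),
            )
        )
        if p < alpha:
            significant.add(tuple(sorted((labels[i], labels[j]))))
    letters = _compact_letter_display(labels, significant)
    return TukeyResult(labels, means, pairwise, letters, alpha)
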