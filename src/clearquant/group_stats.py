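"""Group comparison statistics: mean +/- SEM, one-way ANOVA, Bonferroni.

Implements the classic fixed-effects one-way ANOVA decomposition and the
matching pairwise post-test in which every two-sample t statistic uses the
pooled within-group mean square from the full ANOVA, with p-values multiplied
by the number of pairs (capped at 1).  A Welch alternative (per-pair
variances, Welch–Satterthwaite df) is available as a switch.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import InvalidInputError, UndefinedStatisticError

__all__ = [
    "ConditionGroup",
    "AnovaResult",
    "PairwiseComparison",
    "GroupSummary",
    "GroupComparisonResult",
    "one_way_anova",
    "bonferroni_pairwise",
    "summarize_groups",
    "compare_conditions",
]


@dataclass
class ConditionGroup:
    """Attenuation values (region measurements or sample means) for one label."""

    condition: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        if self.values.size == 0:
            raise InvalidInputError(f"group {self.condition!r} is empty")
        if not np.isfinite(self.values).all():
            raise InvalidInputError(f"group {self.condition!r} has non-finite values")

    @property
    def n(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float


@dataclass(frozen=True)
class PairwiseComparison:
    condition_a: str
    condition_b: str
    t_statistic: float
    raw_p: float
    bonferroni_p: float


@dataclass(frozen=True)
class GroupSummary:
    condition: str
    mean: float
    sem: float
    n: int
    single_value: bool = False  # n == 1: SEM reported as 0 by convention


@dataclass
class GroupComparisonResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    pairwise: list[PairwiseComparison]
    summaries: list[GroupSummary]


def _check_groups(groups: Sequence[ConditionGroup], min_per_group: int = 2) -> None:
    if len(groups) < 2:
        raise InvalidInputError("need at least 2 groups")
    for g in groups:
        if g.n < min_per_group:
            raise InvalidInputError(
                f"group {g.condition!r} needs >= {min_per_group} values, has {g.n}"
            )


def _decompose(groups: Sequence[ConditionGroup]) -> tuple[float, float, int, int]:
    """Between/within sums of squares and their degrees of freedom."""
    all_values = np.concatenate([g.values for g in groups])
    grand_mean = all_values.mean()
    ss_between = sum(g.n * (g.values.mean() - grand_mean) ** 2 for g in groups)
    ss_within = sum(((g.values - g.values.mean()) ** 2).sum() for g in groups)
    k = len(groups)
    n_total = all_values.size
    return float(ss_between), float(ss_within), k - 1, n_total - k


def one_way_anova(groups: Sequence[ConditionGroup]) -> AnovaResult:
    """Fixed-effects one-way ANOVA: F = MS_between / MS_within.

    The p-value is the upper tail of the F distribution with
    ``(k - 1, N - k)`` degrees of freedom.
    """
    _check_groups(groups)
    ss_b, ss_w, df_b, df_w = _decompose(groups)
    ms_b = ss_b / df_b
    ms_w = ss_w / df_w
    if ms_w == 0.0:
        if ms_b == 0.0:
            raise UndefinedStatisticError(
                "all values identical: F statistic undefined"
            )
        return AnovaResult(math.inf, df_b, df_w, 0.0)
    f = ms_b / ms_w
    p = float(stats.f.sf(f, df_b, df_w))
    return AnovaResult(float(f), df_b, df_w, p)


def bonferroni_pairwise(
    groups: Sequence[ConditionGroup],
    pooled_variance: bool = True,
) -> list[PairwiseComparison]:
    """Two-sided pairwise t-tests with Bonferroni adjustment.

    With ``pooled_variance`` (the classic post-test form) each t statistic
    uses the pooled within-group mean square from the full ANOVA and its
    ``N - k`` degrees of freedom; otherwise Welch's unequal-variance t-test
    is run per pair.  Adjusted p = min(1, m * raw_p), m = k(k-1)/2.
    """
    _check_groups(groups)
    m = len(groups) * (len(groups) - 1) // 2
    results: list[PairwiseComparison] = []
    if pooled_variance:
        _, ss_w, _, df_w = _decompose(groups)
        ms_w = ss_w / df_w
        if ms_w == 0.0:
            raise UndefinedStatisticError(
                "zero pooled within-group variance: t statistics undefined"
            )
        for ga, gb in itertools.combinations(groups, 2):
            se = math.sqrt(ms_w * (1.0 / ga.n + 1.0 / gb.n))
            t = (ga.values.mean() - gb.values.mean()) / se
            raw_p = float(2.0 * stats.t.sf(abs(t), df_w))
            results.append(
                PairwiseComparison(ga.condition, gb.condition, float(t),
                                   raw_p, min(1.0, m * raw_p))
            )
    else:
        for ga, gb in itertools.combinations(groups, 2):
            t, raw_p = stats.ttest_ind(ga.values, gb.values, equal_var=False)
            results.append(
                PairwiseComparison(ga.condition, gb.condition, float(t),
                                   float(raw_p), min(1.0, float(m * raw_p)))
            )
    return results


def summarize_groups(groups: Sequence[ConditionGroup]) -> list[GroupSummary]:
    """Per-condition mean and SEM (sd / sqrt(n), (n-1) denominator).

    A single-value group gets SEM 0 with ``single_value=True`` and a warning.
    """
    if not groups:
        raise InvalidInputError("no groups to summarize")
    out = []
    for g in groups:
        if g.n == 1:
            warnings.warn(
                f"group {g.condition!r} has a single value; SEM reported as 0",
                stacklevel=2,
            )
            out.append(GroupSummary(g.condition, float(g.values[0]), 0.0, 1, True))
        else:
            sem = float(g.values.std(ddof=1) / math.sqrt(g.n))
            out.append(GroupSummary(g.condition, float(g.values.mean()), sem, g.n))
    return out


def compare_conditions(
    groups: Sequence[ConditionGroup],
    pooled_variance: bool = True,
) -> GroupComparisonResult:
    """Full comparison: ANOVA, Bonferroni pairwise table and group summaries."""
    anova = one_way_anova(groups)
    pairwise = bonferroni_pairwise(groups, pooled_variance=pooled_variance)
    summaries = summarize_groups(groups)
    return GroupComparisonResult(
        f_statistic=anova.f_statistic,
        df_between=anova.df_between,
        df_within=anova.df_within,
        p_value=anova.p_value,
        pairwise=pairwise,
        summaries=summaries,
    )
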