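"""Group-level inference: planned contrasts, directional one-sample tests,
Bonferroni families, assumption-dispatched two-group comparisons, and
Pearson correlations.

The workhorse is the planned one-way contrast with pooled within-group
variance: estimate = sum(c_i * mean_i), SE = sqrt(MSE * sum(c_i^2 / n_i)),
t on df = N - k.  Effect sizes follow the conventions d = 2t/sqrt(df) for
contrasts and d = t/sqrt(n) for one-sample tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ContrastResult",
    "TestResult",
    "FamilyCorrection",
    "GroupStatsError",
    "planned_contrast",
    "one_sample_test",
    "two_group_compare",
    "bonferroni_alpha",
    "correlate",
]


class GroupStatsError(ValueError):
    pass


@dataclass(frozen=True)
class ContrastResult:
    estimate: float
    se: float
    t: float
    df: int
    p: float
    d: float
    weights: dict
    group_ns: dict


@dataclass(frozen=True)
class TestResult:
    method: str  # one_sample_t | wilcoxon_rank_sum | welch_t | student_t
    statistic: float
    df: Optional[float]
    p: float
    tail: str  # two | less | greater
    d: Optional[float]
    detail: str = ""


@dataclass(frozen=True)
class FamilyCorrection:
    family_alpha: float
    k: int

    @property
    def adjusted_alpha(self) -> float:
        return self.family_alpha / self.k


def planned_contrast(
    values_by_group: Mapping[str, Sequence[float]],
    weights: Mapping[str, float],
) -> ContrastResult:
    """One-way planned contrast with pooled within-group variance.

    MSE pools the group variances (Sum (n_i - 1) s_i^2 / (N - k)); df = N - k;
    two-tailed p; d = 2t / sqrt(df).
    """
    groups = list(values_by_group)
    if len(groups) < 2:
        raise GroupStatsError("need >= 2 groups")
    missing = set(groups) - set(weights)
    if missing:
        raise GroupStatsError(f"weights missing for groups {sorted(missing)}")
    arrs = {g: np.asarray(values_by_group[g], dtype=float) for g in groups}
    ns = {g: len(a) for g, a in arrs.items()}
    if any(n < 2 for n in ns.values()):
        raise GroupStatsError("every group needs n >= 2")
    n_total = sum(ns.values())
    k = len(groups)
    df = n_total - k
    mse = sum((ns[g] - 1) * arrs[g].var(ddof=1) for g in groups) / df
    if mse == 0:
        raise GroupStatsError("zero pooled variance")
    estimate = sum(weights[g] * arrs[g].mean() for g in groups)
    se = math.sqrt(mse * sum(weights[g] ** 2 / ns[g] for g in groups))
    t = estimate / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return ContrastResult(
        estimate=float(estimate),
        se=float(se),
        t=float(t),
        df=df,
        p=float(p),
        d=float(2.0 * t / math.sqrt(df)),
        weights=dict(weights),
        group_ns=ns,
    )


_TAILS = {"two": "two-sided", "less": "less", "greater": "greater"}


def one_sample_test(values: Sequence[float], mu: float = 0.0, tail: str = "two") -> TestResult:
    """One-sample t test against ``mu``; d = t / sqrt(n)."""
    x = np.asarray(values, dtype=float)
    if len(x) < 2 or not np.all(np.isfinite(x)):
        raise GroupStatsError("need >= 2 finite values")
    if x.std(ddof=1) == 0:
        raise GroupStatsError("zero variance")
    if tail not in _TAILS:
        raise GroupStatsError(f"tail must be one of {list(_TAILS)}")
    res = stats.ttest_1samp(x, mu, alternative=_TAILS[tail])
    n = len(x)
    return TestResult(
        method="one_sample_t",
        statistic=float(res.statistic),
        df=float(n - 1),
        p=float(res.pvalue),
        tail=tail,
        d=float(res.statistic / math.sqrt(n)),
    )


def two_group_compare(
    a: Sequence[float],
    b: Sequence[float],
    normality_alpha: float = 0.05,
    variance_alpha: float = 0.05,
) -> TestResult:
    """Two-sample comparison with the dispatch used for sleep metrics.

    Shapiro-Wilk per group at ``normality_alpha``: if either group departs
    from normality, a Wilcoxon rank-sum test is reported (exact when there
    are no ties, normal approximation with continuity correction
    otherwise).  Otherwise a median-centered Levene test decides between
    Student's and Welch's t.  Cohen's d (t-based branches) is
    t * sqrt(1/n1 + 1/n2).
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise GroupStatsError("each group needs n >= 3")
    if np.ptp(np.concatenate([x, y])) == 0:
        raise GroupStatsError("all observations tied; comparison undefined")
    sw_x = stats.shapiro(x).pvalue
    sw_y = stats.shapiro(y).pvalue
    if sw_x < normality_alpha or sw_y < normality_alpha:
        combined = np.concatenate([x, y])
        if np.ptp(combined) == 0:
            raise GroupStatsError("all observations tied; rank test undefined")
        ties = len(np.unique(combined)) < len(combined)
        method = "asymptotic" if ties else "exact"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        return TestResult(
            method="wilcoxon_rank_sum",
            statistic=float(res.statistic),
            df=None,
            p=float(res.pvalue),
            tail="two",
            d=None,
            detail=f"shapiro p=({sw_x:.3g},{sw_y:.3g}); {method}",
        )
    lev_p = stats.levene(x, y, center="median").pvalue
    equal_var = lev_p >= variance_alpha
    res = stats.ttest_ind(x, y, equal_var=equal_var)
    d = float(res.statistic) * math.sqrt(1.0 / len(x) + 1.0 / len(y))
    return TestResult(
        method="student_t" if equal_var else "welch_t",
        statistic=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
        tail="two",
        d=d,
        detail=f"shapiro p=({sw_x:.3g},{sw_y:.3g}); levene p={lev_p:.3g}",
    )


def bonferroni_alpha(family_alpha: float, k: int) -> FamilyCorrection:
    """Per-test alpha for a family of k tests."""
    if k < 1:
        raise GroupStatsError("k must be >= 1")
    return FamilyCorrection(family_alpha=family_alpha, k=k)


def correlate(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson r with its two-tailed p (t distribution, df = n - 2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise GroupStatsError("need matched vectors of length >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise GroupStatsError("non-finite values")
    if x.std() == 0 or y.std() == 0:
        raise GroupStatsError("zero variance")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)
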