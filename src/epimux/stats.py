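"""Group statistics implemented from the defining formulas.

F statistics, Tukey studentized-range comparisons, repeated-measures ANOVA
and Pearson correlation are computed directly from sums of squares; only
the reference distributions (F, t, studentized range, normal) come from
scipy.  The Shapiro–Wilk W statistic is computed with the Royston
coefficient approximation.  All p-values are two-sided / upper-tail as
appropriate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "StatResult",
    "PairwiseComparisons",
    "one_way_anova",
    "tukey_hsd",
    "rm_one_way_anova",
    "pearson",
    "shapiro_wilk",
]


@dataclass
class StatResult:
    statistic: float
    df: tuple
    p_value: float
    method: str
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError(f"p-value out of range: {self.p_value}")


@dataclass
class PairwiseComparisons:
    """Tukey-adjusted pairwise mean differences."""

    family: str
    comparisons: list[dict]  # keys: pair, mean_difference, q, p_adjusted


def _clean_groups(groups: Sequence[Sequence[float]]) -> list[np.ndarray]:
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    for i, a in enumerate(arrs):
        if a.ndim != 1 or a.size < 2:
            raise ValueError(f"group {i} must be a 1-D sample with n >= 2")
        if not np.all(np.isfinite(a)):
            raise ValueError(f"group {i} has non-finite values")
    return arrs


def _anova_decomposition(arrs: list[np.ndarray]):
    all_values = np.concatenate(arrs)
    grand = all_values.mean()
    n_total = all_values.size
    k = len(arrs)
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrs)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrs)
    if ss_within == 0:
        raise ValueError("zero within-group variance: F undefined")
    df_between, df_within = k - 1, n_total - k
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    return ms_between, ms_within, df_between, df_within


def one_way_anova(groups: Sequence[Sequence[float]]) -> StatResult:
    """F = MS_between / MS_within with df (k-1, N-k)."""
    arrs = _clean_groups(groups)
    ms_b, ms_w, df_b, df_w = _anova_decomposition(arrs)
    f = ms_b / ms_w
    p = float(sps.f.sf(f, df_b, df_w))
    return StatResult(statistic=float(f), df=(df_b, df_w), p_value=p, method="one-way ANOVA",
                      extras={"ms_within": ms_w})


def tukey_hsd(
    groups: Sequence[Sequence[float]], labels: Sequence[str] | None = None
) -> PairwiseComparisons:
    """All-pairs comparisons via the studentized range distribution.

    q = |mean_i - mean_j| / sqrt(MSW/2 * (1/n_i + 1/n_j)) (Tukey–Kramer;
    reduces to |diff| / sqrt(MSW/n) under equal n), with adjusted p from
    the studentized range distribution on (k, N-k).
    """
    arrs = _clean_groups(groups)
    if labels is None:
        labels = [f"group{i}" for i in range(len(arrs))]
    _, ms_w, _, df_w = _anova_decomposition(arrs)
    k = len(arrs)
    comparisons = []
    for i, j in combinations(range(k), 2):
        diff = arrs[i].mean() - arrs[j].mean()
        se = math.sqrt(ms_w / 2.0 * (1.0 / arrs[i].size + 1.0 / arrs[j].size))
        q = abs(diff) / se
        p = float(sps.studentized_range.sf(q, k, df_w))
        comparisons.append(
            {
                "pair": (labels[i], labels[j]),
                "mean_difference": float(diff),
                "q": float(q),
                "p_adjusted": min(1.0, max(0.0, p)),
            }
        )
    return PairwiseComparisons(family="tukey_hsd", comparisons=comparisons)


def rm_one_way_anova(table: np.ndarray) -> StatResult:
    """Repeated-measures one-way ANOVA on a complete subjects x conditions table.

    The subject effect is partitioned out; F = MS_condition / MS_error with
    df (k-1, (k-1)(n-1)).
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2:
        raise ValueError("expected a 2-D subjects x conditions table")
    if not np.all(np.isfinite(table)):
        raise ValueError("incomplete table: non-finite entries present (no imputation)")
    n, k = table.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 conditions")
    grand = table.mean()
    cond_means = table.mean(axis=0)
    subj_means = table.mean(axis=1)
    ss_cond = n * ((cond_means - grand) ** 2).sum()
    ss_subj = k * ((subj_means - grand) ** 2).sum()
    ss_total = ((table - grand) ** 2).sum()
    ss_err = ss_total - ss_cond - ss_subj
    df_cond = k - 1
    df_err = (k - 1) * (n - 1)
    ms_err = ss_err / df_err
    if ms_err <= 0:
        raise ValueError("zero error variance: F undefined")
    f = (ss_cond / df_cond) / ms_err
    p = float(sps.f.sf(f, df_cond, df_err))
    return StatResult(
        statistic=float(f),
        df=(df_cond, df_err),
        p_value=p,
        method="repeated-measures one-way ANOVA",
        extras={"ss_condition": ss_cond, "ss_subject": ss_subj, "ss_error": ss_err},
    )


def pearson(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Product-moment correlation with a two-sided t-based p-value.

    Slope and intercept of the least-squares line are reported alongside r.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and the same length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    dx = x - x.mean()
    dy = y - y.mean()
    sxx = (dx**2).sum()
    syy = (dy**2).sum()
    if sxx == 0 or syy == 0:
        raise ValueError("zero variance in x or y")
    sxy = (dx * dy).sum()
    r = sxy / math.sqrt(sxx * syy)
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1 - r**2))
        p = float(2 * sps.t.sf(abs(t), n - 2))
    slope = sxy / sxx
    return StatResult(
        statistic=float(r),
        df=(n - 2,),
        p_value=p,
        method="Pearson correlation",
        extras={"slope": float(slope), "intercept": float(y.mean() - slope * x.mean())},
    )


# ---------------------------------------------------------------------------
# Shapiro-Wilk (Royston approximation)

# Polynomial corrections for the two largest coefficients, in u = 1/sqrt(n).
_C1 = (-2.706056, 4.434685, -2.071190, -0.147981, 0.221157, 0.0)
_C2 = (-3.582633, 5.682633, -1.752461, -0.293762, 0.042981, 0.0)


def _sw_coefficients(n: int) -> np.ndarray:
    m = sps.norm.ppf((np.arange(1, n + 1) - 0.375) / (n + 0.25))
    mm = (m**2).sum()
    c = m / math.sqrt(mm)
    u = 1.0 / math.sqrt(n)
    a = np.empty(n)
    if n == 3:  # exact: avoids a 0/0 in the scaling term
        s = math.sqrt(0.5)
        return np.array([-s, 0.0, s])
    if n <= 5:
        a_n = c[-1] + np.polyval(_C1, u)
        phi = (mm - 2 * m[-1] ** 2) / (1 - 2 * a_n**2)
        a[1:-1] = m[1:-1] / math.sqrt(phi)
        a[-1] = a_n
        a[0] = -a_n
    else:
        a_n = c[-1] + np.polyval(_C1, u)
        a_n1 = c[-2] + np.polyval(_C2, u)
        phi = (mm - 2 * m[-1] ** 2 - 2 * m[-2] ** 2) / (1 - 2 * a_n**2 - 2 * a_n1**2)
        a[2:-2] = m[2:-2] / math.sqrt(phi)
        a[-1] = a_n
        a[-2] = a_n1
        a[0] = -a_n
        a[1] = -a_n1
    return a


def shapiro_wilk(x: Sequence[float]) -> StatResult:
    """Shapiro-Wilk W with the Royston coefficient/p-value approximation.

    Valid for 3 <= n <= 5000. Raises on zero sample variance.
    """
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    if not (3 <= n <= 5000):
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values")
    ss = ((x - x.mean()) ** 2).sum()
    if ss == 0:
        raise ValueError("zero variance sample")
    a = _sw_coefficients(n)
    w = float((a @ x) ** 2 / ss)
    w = min(w, 1.0)

    if n == 3:
        p = 6.0 / math.pi * (math.asin(math.sqrt(w)) - math.asin(math.sqrt(0.75)))
        p = min(1.0, max(0.0, p))
    elif n <= 11:
        gamma = -2.273 + 0.459 * n
        if gamma - math.log1p(-w) <= 0:
            p = 1e-99
        else:
            y = -math.log(gamma - math.log1p(-w))
            mu = 0.5440 - 0.39978 * n + 0.025054 * n**2 - 0.0006714 * n**3
            sigma = math.exp(1.3822 - 0.77857 * n + 0.062767 * n**2 - 0.0020322 * n**3)
            p = float(sps.norm.sf((y - mu) / sigma))
    else:
        ln_n = math.log(n)
        y = math.log1p(-w)
        mu = 0.0038915 * ln_n**3 - 0.083751 * ln_n**2 - 0.31082 * ln_n - 1.5861
        sigma = math.exp(0.0030302 * ln_n**2 - 0.082676 * ln_n - 0.4803)
        p = float(sps.norm.sf((y - mu) / sigma))
    return StatResult(statistic=w, df=(n,), p_value=p, method="Shapiro-Wilk")
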