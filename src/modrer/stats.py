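"""Hypothesis tests for the cohort analysis, implemented from first principles.

Each procedure is written out explicitly (pooled-variance t, midrank
Mann-Whitney with tie correction, uncorrected Pearson chi-square,
probability-mass two-sided Fisher, 2-group x 2-time mixed-model ANOVA) so
that its exact conventions are pinned down and testable against brute-force
oracles; scipy supplies only the reference distributions.

Conventions that matter downstream:

* Pearson chi-square carries NO Yates continuity correction — the
  uncorrected statistic is what standard clinical-stats software reports
  for 2x2 group comparisons of this size.
* Fisher's two-sided p is the probability-mass rule: the sum of the
  probabilities of all tables (same margins) no more probable than the
  observed one.
* The Mann-Whitney U reported is U1 = #{pairs with x > y} + half-ties, so
  U1/(n1*n2) is exactly the empirical AUC of group membership.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps


@dataclass(frozen=True)
class TwoByTwo:
    """A 2x2 count table: rows exposure yes/no, columns event yes/no."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"cell {name}={v} must be a non-negative integer")
        if self.total == 0:
            raise ValueError("empty 2x2 table")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)

    @property
    def min_expected(self) -> float:
        t = self.as_array()
        e = np.outer(t.sum(1), t.sum(0)) / t.sum()
        return float(e.min())


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p: float
    df: float | None = None
    name: str = ""


def student_t_two_sample(group1, group2) -> TestResult:
    """Two-sided pooled-variance (equal-variance) two-sample t-test.

    Degenerate inputs with zero pooled variance return p=1 when the means
    agree and p=0 when they differ, the limiting behaviour of the test.
    """
    x = np.asarray(group1, dtype=float)
    y = np.asarray(group2, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / df
    diff = x.mean() - y.mean()
    if sp2 == 0:
        if diff == 0:
            return TestResult(0.0, 1.0, df, "student_t")
        return TestResult(math.copysign(math.inf, diff), 0.0, df, "student_t")
    t = diff / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2 * _sps.t.sf(abs(t), df)
    return TestResult(float(t), float(p), df, "student_t")


def paired_t(pre, post) -> TestResult:
    """Two-sided paired t-test on post - pre differences."""
    d = np.asarray(post, dtype=float) - np.asarray(pre, dtype=float)
    n = len(d)
    if n < 2:
        raise ValueError("paired t needs n >= 2 pairs")
    sd = d.std(ddof=1)
    if sd == 0:
        return TestResult(0.0, 1.0 if d.mean() == 0 else 0.0, n - 1, "paired_t")
    t = d.mean() / (sd / math.sqrt(n))
    return TestResult(float(t), float(2 * _sps.t.sf(abs(t), n - 1)), n - 1, "paired_t")


def mann_whitney_u(group1, group2) -> TestResult:
    """Mann-Whitney U with midranks, tie-corrected normal approximation.

    Returns U1 (pairs where group1 exceeds group2, ties counting one half),
    so U1/(n1*n2) equals the empirical AUC for 'belongs to group1'.  All
    values identical gives p=1.
    """
    x = np.asarray(group1, dtype=float)
    y = np.asarray(group2, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = _sps.rankdata(pooled)  # midranks
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float((counts**3 - counts).sum())
    if tie_term == n**3 - n:  # every value identical
        return TestResult(float(u1), 1.0, None, "mann_whitney")
    mu = n1 * n2 / 2.0
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    z = (u1 - mu) / math.sqrt(sigma2)
    p = min(1.0, 2 * _sps.norm.sf(abs(z)))
    return TestResult(float(u1), float(p), None, "mann_whitney")


def pearson_chi2_2x2(table: TwoByTwo) -> TestResult:
    """Pearson chi-square on a 2x2 table, 1 df, no continuity correction."""
    o = table.as_array()
    rows, cols = o.sum(1), o.sum(0)
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("chi-square undefined with a zero marginal")
    e = np.outer(rows, cols) / o.sum()
    chi2 = float(((o - e) ** 2 / e).sum())
    return TestResult(chi2, float(_sps.chi2.sf(chi2, 1)), 1, "pearson_chi2")


def fisher_exact_2x2(table: TwoByTwo) -> float:
    """Two-sided Fisher exact p by the probability-mass rule.

    Conditioning on both margins, the first cell follows a hypergeometric
    law; the p-value sums the probabilities of every table whose
    probability does not exceed (up to a 1+1e-7 rounding guard) that of
    the observed table.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.total
    r1, c1 = a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    if lo == hi:
        return 1.0
    dist = _sps.hypergeom(n, c1, r1)
    support = np.arange(lo, hi + 1)
    pmf = dist.pmf(support)
    p_obs = dist.pmf(a)
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    return min(1.0, p)


@dataclass(frozen=True)
class RmAnovaResult:
    """Two-group, two-time repeated-measurements ANOVA summary.

    ``interaction_p`` tests whether the mean pre-to-post change differs
    between groups (for two time points it coincides with the two-sample t
    on per-trial change scores).  ``time_p_group1``/``time_p_group2`` are
    the within-group time effects (paired t).  ``group_p`` is the
    between-subjects main effect on subject means.
    """

    group_f: float
    group_p: float
    time_f: float
    time_p: float
    interaction_f: float
    interaction_p: float
    time_p_group1: float
    time_p_group2: float


def rm_anova_2x2(pre_g1, post_g1, pre_g2, post_g2) -> RmAnovaResult:
    """Mixed-model ANOVA: between factor group, within factor time (2 levels).

    With exactly two time points the design separates exactly into two
    strata: the between-subjects stratum (subject means, testing the group
    effect against subjects-within-groups) and the within-subjects stratum
    (per-subject change scores, whose pooled variance is the
    time x subject(group) error term for both the time main effect and the
    group x time interaction).  Effects are the unweighted (Type III)
    contrasts, so the decomposition is exact for unbalanced groups, and
    the interaction F equals the square of the two-sample t on change
    scores.
    """
    pre1, post1 = np.asarray(pre_g1, float), np.asarray(post_g1, float)
    pre2, post2 = np.asarray(pre_g2, float), np.asarray(post_g2, float)
    n1, n2 = len(pre1), len(pre2)
    if n1 < 2 or n2 < 2 or len(post1) != n1 or len(post2) != n2:
        raise ValueError("each group needs >= 2 paired pre/post observations")
    n = n1 + n2
    c2 = 1.0 / n1 + 1.0 / n2

    def contrast_f(estimate, var, df_err):
        if var == 0:
            return (0.0, 1.0) if estimate == 0 else (math.inf, 0.0)
        f = estimate**2 / var
        return float(f), float(_sps.f.sf(f, 1, df_err))

    # between-subjects stratum: subject means
    m1, m2 = (pre1 + post1) / 2.0, (pre2 + post2) / 2.0
    sm2 = ((n1 - 1) * m1.var(ddof=1) + (n2 - 1) * m2.var(ddof=1)) / (n - 2)
    group_f, group_p = contrast_f(m1.mean() - m2.mean(), sm2 * c2, n - 2)

    # within-subjects stratum: change scores
    d1, d2 = post1 - pre1, post2 - pre2
    sd2 = ((n1 - 1) * d1.var(ddof=1) + (n2 - 1) * d2.var(ddof=1)) / (n - 2)
    inter_f, inter_p = contrast_f(d1.mean() - d2.mean(), sd2 * c2, n - 2)
    time_f, time_p = contrast_f((d1.mean() + d2.mean()) / 2.0, sd2 * c2 / 4.0, n - 2)

    return RmAnovaResult(
        group_f=group_f,
        group_p=group_p,
        time_f=time_f,
        time_p=time_p,
        interaction_f=inter_f,
        interaction_p=inter_p,
        time_p_group1=paired_t(pre1, post1).p,
        time_p_group2=paired_t(pre2, post2).p,
    )


def skewness(values) -> float:
    """Adjusted Fisher-Pearson sample skewness (g1 with bias correction)."""
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 3:
        return 0.0
    s = x.std(ddof=1)
    if s == 0:
        return 0.0
    g1 = ((x - x.mean()) ** 3).mean() / x.std(ddof=0) ** 3
    return float(g1 * math.sqrt(n * (n - 1)) / (n - 2))
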