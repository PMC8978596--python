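"""Two-group and paired comparisons with normality routing and effect sizes.

Group comparisons follow the conventional small-sample workflow: Shapiro-Wilk
per group routes to a pooled-variance Student t test (both groups consistent
with normality) or to the Mann-Whitney U test with the *exact* null
distribution of U; significant parametric outcomes are accompanied by
Hedges' g (pooled-SD standardized mean difference with small-sample bias
correction) and a normal-approximation confidence interval.  Paired
stress-response tests route Shapiro-Wilk on the differences to a paired t
or an exact Wilcoxon signed-rank test.

The exact null distributions are computed in-package (dynamic programming
over rank configurations); Shapiro-Wilk and the t tests are delegated to
scipy as vetted infrastructure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as sps

_Z975 = sps.norm.ppf(0.975)

#: largest number of labelings enumerated for an exact tie-aware permutation p
_MAX_EXACT_LABELINGS = 200_000


# ---------------------------------------------------------------------------
# effect size
# ---------------------------------------------------------------------------

@dataclass
class EffectSize:
    """Hedges' g with a 95% normal-approximation CI."""

    g: float
    ci_low: float
    ci_high: float

    def to_dict(self) -> dict:
        return {"g": self.g, "ci_low": self.ci_low, "ci_high": self.ci_high}


def hedges_g_from_summary(m1: float, s1: float, n1: int,
                          m2: float, s2: float, n2: int) -> EffectSize:
    """Hedges' g from group summaries.

    d = (m1 - m2) / s_pooled with the (n-1)-weighted pooled SD;
    g = d * J with J = 1 - 3 / (4 df - 1), df = n1 + n2 - 2.
    CI: g +/- 1.96 * SE, SE^2 = (n1+n2)/(n1 n2) + g^2 / (2 (n1+n2)).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    df = n1 + n2 - 2
    s_pooled = math.sqrt(((n1 - 1) * s1 ** 2 + (n2 - 1) * s2 ** 2) / df)
    if s_pooled == 0:
        raise ValueError("zero pooled standard deviation")
    d = (m1 - m2) / s_pooled
    j = 1.0 - 3.0 / (4.0 * df - 1.0)
    g = d * j
    se = math.sqrt((n1 + n2) / (n1 * n2) + g ** 2 / (2 * (n1 + n2)))
    return EffectSize(g=g, ci_low=g - _Z975 * se, ci_high=g + _Z975 * se)


def hedges_g(x1, x2) -> EffectSize:
    """Hedges' g from raw samples (see :func:`hedges_g_from_summary`)."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    return hedges_g_from_summary(x1.mean(), x1.std(ddof=1), x1.size,
                                 x2.mean(), x2.std(ddof=1), x2.size)


# ---------------------------------------------------------------------------
# exact Mann-Whitney U
# ---------------------------------------------------------------------------

def _u_null_counts(n1: int, n2: int) -> np.ndarray:
    """Counts of labelings by U value under the tie-free null.

    counts[u] = number of the C(n1+n2, n1) group assignments yielding U = u,
    by the standard recurrence c(u; n1, n2) = c(u - n2; n1-1, n2) +
    c(u; n1, n2-1) computed with exact integer arithmetic.
    """
    prev_row = [np.array([1], dtype=object) for _ in range(n2 + 1)]  # n1 = 0
    for i in range(1, n1 + 1):
        row: list[np.ndarray] = [np.array([1], dtype=object)]  # j = 0
        for j in range(1, n2 + 1):
            cur = np.zeros(i * j + 1, dtype=object)
            a = prev_row[j]          # c(.; i-1, j), shifted by j
            cur[j:j + a.size] += a
            b = row[j - 1]           # c(.; i, j-1)
            cur[: b.size] += b
            row.append(cur)
        prev_row = row
    return prev_row[n2]


def _rank_u(x1: np.ndarray, x2: np.ndarray) -> float:
    """U statistic for group 1 from mid-ranks (ties get 0.5 credit)."""
    n1 = x1.size
    ranks = sps.rankdata(np.concatenate([x1, x2]))
    r1 = ranks[:n1].sum()
    return float(r1 - n1 * (n1 + 1) / 2)


@dataclass
class MwuResult:
    u: float
    p: float
    method: str          # "exact", "exact_permutation", "normal_tie_corrected"
    has_ties: bool

    def to_dict(self) -> dict:
        return {"u": self.u, "p": self.p, "method": self.method,
                "has_ties": self.has_ties}


def exact_mwu(x1, x2) -> MwuResult:
    """Mann-Whitney U with the exact sampling distribution of U.

    Without ties, the two-sided p is min(1, 2 * min(P(U <= u), P(U >= u)))
    from the full dynamic-programming null distribution.  With ties, U uses
    mid-ranks and the p-value comes from exhaustive enumeration of all group
    labelings when feasible, else from the tie-corrected normal
    approximation; the method used is always recorded.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    n1, n2 = x1.size, x2.size
    if n1 == 0 or n2 == 0:
        raise ValueError("empty group")
    pooled = np.concatenate([x1, x2])
    has_ties = np.unique(pooled).size < pooled.size
    u = _rank_u(x1, x2)

    if not has_ties:
        counts = _u_null_counts(n1, n2)
        total = counts.sum()
        ui = int(round(u))
        p_le = int(counts[: ui + 1].sum()) / int(total)
        p_ge = int(counts[ui:].sum()) / int(total)
        return MwuResult(u=u, p=min(1.0, 2 * min(p_le, p_ge)),
                         method="exact", has_ties=False)

    n = n1 + n2
    if math.comb(n, n1) <= _MAX_EXACT_LABELINGS:
        ranks = sps.rankdata(pooled)
        offset = n1 * (n1 + 1) / 2
        us = np.fromiter(
            (ranks[list(c)].sum() - offset for c in combinations(range(n), n1)),
            dtype=float, count=math.comb(n, n1))
        p_le = float((us <= u + 1e-9).mean())
        p_ge = float((us >= u - 1e-9).mean())
        return MwuResult(u=u, p=min(1.0, 2 * min(p_le, p_ge)),
                         method="exact_permutation", has_ties=True)

    # tie-corrected normal approximation (large samples with ties)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts ** 3 - counts).sum()
    mu = n1 * n2 / 2
    sigma = math.sqrt(n1 * n2 / 12 * ((n + 1) - tie_term / (n * (n - 1))))
    z = (u - mu - 0.5 * np.sign(u - mu)) / sigma if sigma > 0 else 0.0
    return MwuResult(u=u, p=float(2 * sps.norm.sf(abs(z))),
                     method="normal_tie_corrected", has_ties=True)


# ---------------------------------------------------------------------------
# normality routing + group comparison
# ---------------------------------------------------------------------------

def shapiro_p(x) -> float | None:
    """Shapiro-Wilk p-value, or None when undefined (n < 3 or constant)."""
    x = np.asarray(x, dtype=float)
    if x.size < 3 or np.ptp(x) == 0:
        return None
    return float(sps.shapiro(x).pvalue)


def normality_route(x_high, x_low, alpha: float = 0.05) -> str:
    """Choose ``student_t`` when both groups pass Shapiro-Wilk at ``alpha``,
    else ``mann_whitney_exact`` (also the fallback when the test is
    undefined for a group)."""
    for x in (x_high, x_low):
        p = shapiro_p(x)
        if p is None or p < alpha:
            return "mann_whitney_exact"
    return "student_t"


def _median_iqr(x: np.ndarray) -> dict:
    # quartiles by the weighted-average percentile convention ((n+1)p position)
    q1, q3 = np.percentile(x, [25, 75], method="weibull")
    return {"median": float(np.median(x)), "iqr": float(q3 - q1),
            "q1": float(q1), "q3": float(q3), "n": int(x.size)}


def _mean_sd(x: np.ndarray) -> dict:
    return {"mean": float(x.mean()),
            "sd": float(x.std(ddof=1)) if x.size >= 2 else float("nan"),
            "n": int(x.size)}


@dataclass
class GroupComparison:
    variable: str
    test: str            # "student_t" | "mann_whitney_exact"
    statistic: float
    p: float
    summaries: dict = field(default_factory=dict)
    effect: EffectSize | None = None
    mwu_method: str | None = None
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {"variable": self.variable, "test": self.test,
                "statistic": self.statistic, "p": self.p,
                "summaries": self.summaries,
                "effect": self.effect.to_dict() if self.effect else None,
                "mwu_method": self.mwu_method, "degenerate": self.degenerate}


def compare_groups(x_high, x_low, alpha: float = 0.05,
                   variable: str = "", equal_var: bool = True) -> GroupComparison:
    """Normality-routed two-group comparison.

    Student t is the pooled-variance test (``equal_var=False`` switches to
    Welch); Hedges' g is attached for significant parametric outcomes, and
    median [IQR] summaries accompany nonparametric ones.  Identical constant
    groups are reported as degenerate with p = 1.
    """
    x_high = np.asarray(x_high, dtype=float)
    x_low = np.asarray(x_low, dtype=float)
    if x_high.size == 0 or x_low.size == 0:
        raise ValueError("empty group")
    pooled = np.concatenate([x_high, x_low])
    if np.ptp(pooled) == 0:
        return GroupComparison(
            variable=variable, test="mann_whitney_exact", statistic=float("nan"),
            p=1.0, degenerate=True,
            summaries={"high": _median_iqr(x_high), "low": _median_iqr(x_low)})

    test = normality_route(x_high, x_low, alpha)
    if test == "student_t":
        res = sps.ttest_ind(x_high, x_low, equal_var=equal_var)
        cmp_ = GroupComparison(
            variable=variable, test="student_t",
            statistic=float(res.statistic), p=float(res.pvalue),
            summaries={"high": _mean_sd(x_high), "low": _mean_sd(x_low)})
        if cmp_.p < alpha:
            cmp_.effect = hedges_g(x_high, x_low)
        return cmp_
    mwu = exact_mwu(x_high, x_low)
    return GroupComparison(
        variable=variable, test="mann_whitney_exact",
        statistic=mwu.u, p=mwu.p, mwu_method=mwu.method,
        summaries={"high": _median_iqr(x_high), "low": _median_iqr(x_low)})


# ---------------------------------------------------------------------------
# exact Wilcoxon signed-rank + paired routing
# ---------------------------------------------------------------------------

def _signed_rank_exact_p(d: np.ndarray) -> tuple[float, float]:
    """(W+, two-sided exact p) for nonzero differences ``d``.

    DP over the 2^m sign assignments: mid-ranks are doubled to integers and
    the distribution of the positive-rank sum is accumulated exactly.
    """
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    r2 = np.rint(2 * ranks).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=object)
    counts[0] = 1
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    denom = int(counts.sum())  # 2^m
    w2 = int(round(2 * w_plus))
    p_le = int(counts[: w2 + 1].sum()) / denom
    p_ge = int(counts[w2:].sum()) / denom
    return w_plus, min(1.0, 2 * min(p_le, p_ge))


@dataclass
class PairedResult:
    test: str            # "paired_t" | "wilcoxon_exact"
    statistic: float
    p: float
    n: int
    mean_change: float
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {"test": self.test, "statistic": self.statistic, "p": self.p,
                "n": self.n, "mean_change": self.mean_change,
                "degenerate": self.degenerate}


def paired_change_test(pre, post, alpha: float = 0.05) -> PairedResult:
    """Paired stress-effect test on post - pre differences.

    Shapiro-Wilk on the differences routes to the paired t test (normal) or
    the exact Wilcoxon signed-rank test; all-zero differences are reported
    as degenerate with p = 1.  Zero differences are dropped for the
    signed-rank test (standard convention).
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.size != post.size:
        raise ValueError("pre/post must be paired (equal length)")
    if pre.size < 3:
        raise ValueError("need at least 3 pairs")
    d = post - pre
    if np.all(d == 0):
        return PairedResult(test="wilcoxon_exact", statistic=float("nan"),
                            p=1.0, n=int(d.size), mean_change=0.0,
                            degenerate=True)
    p_sw = shapiro_p(d)
    if p_sw is not None and p_sw >= alpha:
        res = sps.ttest_rel(post, pre)
        return PairedResult(test="paired_t", statistic=float(res.statistic),
                            p=float(res.pvalue), n=int(d.size),
                            mean_change=float(d.mean()))
    nz = d[d != 0]
    w, p = _signed_rank_exact_p(nz)
    return PairedResult(test="wilcoxon_exact", statistic=w, p=p,
                        n=int(d.size), mean_change=float(d.mean()))
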