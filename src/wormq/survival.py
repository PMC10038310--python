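"""Starvation-survival curve fitting and the statistical battery.

Survival of L1-arrested larvae is scored as the fraction alive (or the
fraction able to resume development after refeeding, the "recovery"
endpoint) out of the worms counted on each day.  Curves are summarized by a
three-parameter logistic fit, strains are compared with Fisher's exact test
on the alive/dead counts at the day the reference strain drops to 50%, and
families of comparisons are corrected with the Benjamini-Hochberg step-up
at a 5% false discovery rate.  Welch's t-test (between strains) and the
Wilcoxon signed-rank test (within-strain paired pre/post comparisons) serve
the imaging arm.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core_io import LinearFit, LogisticFit, SurvivalTable

__all__ = [
    "fit_logistic3", "day_at_fraction", "fisher_exact_2x2",
    "compare_survival_at_reference", "bh_fdr", "welch_test",
    "wilcoxon_signed_rank", "linear_fit",
]


# ---------------------------------------------------------------------------
# Logistic survival fit
# ---------------------------------------------------------------------------

def _logistic3(day, A, t50, k):
    return A / (1.0 + np.exp(k * (day - t50)))


def fit_logistic3(table: SurvivalTable, strain: str,
                  endpoint: str = "survival") -> LogisticFit:
    """Least-squares fit of S(t) = A / (1 + exp(k (t - t50))) to fractions.

    The decreasing logistic with a free upper asymptote A describes survival
    fractions that start near 1 and decay around a midpoint day t50 with
    steepness k (1/days).  Initialization is multistart: A0 = max fraction,
    t50_0 = first day the fraction falls below A0/2, k0 in {0.1, 0.5, 1.0};
    the best residual sum of squares wins.
    """
    df = table.for_strain(strain, endpoint=endpoint)
    days = df["day"].to_numpy(dtype=float)
    frac = df["fraction"].to_numpy(dtype=float)
    if np.unique(days).size < 4:
        raise ValueError("need observations on >= 4 distinct days to fit")
    if np.allclose(frac, frac[0]):
        return LogisticFit(A=np.nan, t50=np.nan, k=np.nan, rss=np.nan, converged=False)

    A0 = max(frac.max(), 1e-6)
    below = days[frac < A0 / 2.0]
    t50_0 = float(below.min()) if below.size else float(np.median(days))
    lo = np.array([1e-6, days.min() - (days.max() - days.min()), 1e-6])
    hi = np.array([1.05, days.max() + (days.max() - days.min()), 10.0])

    best = None
    for k0 in (0.1, 0.5, 1.0):
        x0 = np.clip(np.array([A0, t50_0, k0]), lo, hi)
        res = optimize.least_squares(
            lambda p: _logistic3(days, *p) - frac, x0, bounds=(lo, hi))
        rss = float(2.0 * res.cost)
        if best is None or rss < best[0]:
            best = (rss, res)
    rss, res = best
    A, t50, k = res.x
    return LogisticFit(A=float(A), t50=float(t50), k=float(k), rss=rss,
                       converged=bool(res.success))


def day_at_fraction(source: SurvivalTable | LogisticFit, strain: str | None = None,
                    fraction: float = 0.5, endpoint: str = "survival",
                    mode: str = "empirical") -> float:
    """Day at which a strain's survival reaches a target fraction.

    ``mode='empirical'`` (the convention used to pick the Fisher test day)
    returns the first observed day whose empirical fraction is <= target.
    ``mode='fitted'`` inverts the logistic: t = t50 + ln(A/f - 1)/k.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    if isinstance(source, LogisticFit) or mode == "fitted":
        fit = source if isinstance(source, LogisticFit) else fit_logistic3(source, strain, endpoint)
        if not fit.converged:
            raise ValueError("cannot invert a non-converged fit")
        if fraction >= fit.A:
            raise ValueError("endpoint not reached: target fraction above asymptote")
        return float(fit.t50 + math.log(fit.A / fraction - 1.0) / fit.k)
    df = source.for_strain(strain, endpoint=endpoint)
    hit = df[df["fraction"] <= fraction]
    if hit.empty:
        raise ValueError(f"endpoint not reached: {strain!r} never falls to {fraction}")
    return float(hit["day"].iloc[0])


# ---------------------------------------------------------------------------
# Fisher's exact test (integer-arithmetic enumeration)
# ---------------------------------------------------------------------------

def fisher_exact_2x2(a: int, b: int, c: int, d: int, sided: str = "two") -> float:
    """Exact hypergeometric p-value for the 2x2 table [[a, b], [c, d]].

    Two-sided convention: sum the probabilities of every table with the same
    margins whose point probability is <= that of the observed table
    (point-probability ordering, the common default).  All comparisons are
    done on exact integer numerators -- every table in a margin family
    shares the denominator C(n, a+c) -- so ties are decided exactly.
    A zero margin leaves only one possible table: p = 1 with a warning.
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("cell counts must be nonnegative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        warnings.warn("degenerate table (zero margin): p = 1 by convention")
        return 1.0
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    # exact numerators of the hypergeometric pmf over the support
    nums = [math.comb(r1, i) * math.comb(r2, c1 - i) for i in range(lo, hi + 1)]
    total = math.comb(n, c1)
    obs = nums[a - lo]
    if sided == "two":
        p_num = sum(v for v in nums if v <= obs)
    elif sided == "less":       # P(A <= a)
        p_num = sum(nums[: a - lo + 1])
    elif sided == "greater":    # P(A >= a)
        p_num = sum(nums[a - lo:])
    else:
        raise ValueError("sided must be 'two', 'less' or 'greater'")
    return min(1.0, p_num / total)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg FDR
# ---------------------------------------------------------------------------

def bh_fdr(pvalues, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (adjusted p-values, rejection mask).

    Sort the m p-values ascending, find the largest i with
    p(i) <= i q / m, and reject hypotheses 1..i.  Adjusted p-values are
    the running minimum of m p(j) / j from the largest rank down, capped
    at 1, mapped back to input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    ranks = np.arange(1, m + 1)
    adj = np.minimum.accumulate((m * ranked / ranks)[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    passed = ranked <= ranks * q / m
    k = ranks[passed].max() if passed.any() else 0
    reject_sorted = ranks <= k
    adjusted = np.empty(m)
    reject = np.empty(m, dtype=bool)
    adjusted[order] = adj
    reject[order] = reject_sorted
    return adjusted, reject


# ---------------------------------------------------------------------------
# Strain comparison at the reference-strain 50% day
# ---------------------------------------------------------------------------

def compare_survival_at_reference(table: SurvivalTable, reference_strain: str,
                                  target_fraction: float = 0.5, q: float = 0.05,
                                  endpoint: str = "survival") -> pd.DataFrame:
    """Fisher tests of each strain against the reference at its 50% day.

    The test day d is the first day the reference strain's empirical
    fraction drops to ``target_fraction``.  For every other strain the 2x2
    table (alive, dead) at day d versus the reference is tested two-sided,
    and the family of p-values is BH-corrected at rate ``q``.  A strain not
    scored on day d contributes its nearest earlier day (recorded in the
    output column ``day_tested``).
    """
    day = day_at_fraction(table, reference_strain, target_fraction, endpoint=endpoint)

    def counts_at(strain):
        df = table.for_strain(strain, endpoint=endpoint)
        at = df[df["day"] <= day]
        if at.empty:
            raise ValueError(f"strain {strain!r} has no observation at or before day {day:g}")
        row = at.iloc[-1]
        return int(row["day"]), int(row["n_alive"]), int(row["n_scored"] - row["n_alive"])

    _, ref_alive, ref_dead = counts_at(reference_strain)
    others = [s for s in table.strains
              if s != reference_strain
              and not table.data[(table.data["strain"] == s)
                                 & (table.data["endpoint"] == endpoint)].empty]
    if not others:
        raise ValueError("need at least one non-reference strain")
    rows = []
    for strain in others:
        d_used, alive, dead = counts_at(strain)
        p = fisher_exact_2x2(ref_alive, ref_dead, alive, dead)
        rows.append(dict(strain=strain, day_tested=d_used, alive=alive, dead=dead,
                         p_raw=p))
    out = pd.DataFrame(rows)
    adjusted, reject = bh_fdr(out["p_raw"].to_numpy(), q=q)
    out["p_adj"] = adjusted
    out["significant"] = reject
    out.attrs["reference_strain"] = reference_strain
    out.attrs["reference_day"] = day
    out.attrs["reference_counts"] = (ref_alive, ref_dead)
    return out


# ---------------------------------------------------------------------------
# Welch's t-test
# ---------------------------------------------------------------------------

def welch_test(sample_a, sample_b) -> tuple[float, float, float]:
    """Unequal-variance t-test: returns (t, Welch-Satterthwaite df, two-sided p)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
        warnings.warn("zero variance in both samples with unequal means: p = 0")
        return math.inf, float(a.size + b.size - 2), 0.0
    sa, sb = va / a.size, vb / b.size
    t = (a.mean() - b.mean()) / math.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (sa ** 2 / (a.size - 1) + sb ** 2 / (b.size - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank test
# ---------------------------------------------------------------------------

def wilcoxon_signed_rank(paired_a, paired_b, exact_max_n: int = 12) -> tuple[float, float]:
    """Paired signed-rank test: returns (W = sum of positive ranks, two-sided p).

    Zero differences are dropped (Wilcoxon's original convention).  For
    n_effective <= ``exact_max_n`` the p-value is exact, from full
    enumeration of all 2^n sign assignments over the (tie-averaged) ranks:
    p = 2 min(P(W <= w), P(W >= w)), capped at 1.  Larger n uses the normal
    approximation with tie correction and no continuity correction.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.size != b.size:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("degenerate pairing: all differences are zero")
    ranks = stats.rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        # distribution of W over all sign patterns (handles tied ranks)
        sums = np.zeros(1)
        for r in ranks:
            sums = np.concatenate([sums, sums + r])
        p_le = np.mean(sums <= w + 1e-12)
        p_ge = np.mean(sums >= w - 1e-12)
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return w, float(p)
    mean = n * (n + 1) / 4.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = (counts ** 3 - counts).sum() / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    z = (w - mean) / math.sqrt(var)
    return w, float(2.0 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# Linear regression (inactivity-vs-quiescence panels)
# ---------------------------------------------------------------------------

def linear_fit(x, y) -> LinearFit:
    """Ordinary least squares y = a + b x with R^2.

    Used for the across-strain regressions of mean neuronal (or RIM)
    inactivity fraction on mean mobility-quiescence fraction.  A constant y
    gives slope 0 with R^2 defined as 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need equal-length x, y with n >= 2")
    if np.all(x == x[0]):
        raise ValueError("x must not be constant")
    xm, ym = x.mean(), y.mean()
    sxx = ((x - xm) ** 2).sum()
    sxy = ((x - xm) * (y - ym)).sum()
    slope = sxy / sxx
    intercept = ym - slope * xm
    ss_tot = ((y - ym) ** 2).sum()
    ss_res = ((y - intercept - slope * x) ** 2).sum()
    if ss_tot == 0:
        r2 = 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
        if ss_res <= 1e-12 * max(ss_tot, 1.0):
            r2 = 1.0
    return LinearFit(intercept=float(intercept), slope=float(slope),
                     r_squared=float(min(max(r2, 0.0), 1.0)))
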