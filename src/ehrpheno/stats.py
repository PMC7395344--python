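"""Matched-pair and two-sample tests for the case-control analysis.

Implements the study's statistical battery directly:

* Wilcoxon matched-pair signed-rank test (exact by enumeration for small n,
  normal approximation with tie and continuity corrections otherwise);
* the 1:1 matched-pair conditional odds ratio (the conditional-ML estimate
  n10/n01 over discordant pairs) with Wald CI and McNemar score test —
  equivalent to univariate conditional logistic regression on 1:1 pairs;
* Wilcoxon rank-sum (Mann-Whitney) test for unpaired comparisons;
* Pearson chi-square / Fisher's exact test for 2x2 tables, choosing Fisher
  when any expected cell is below 5.

scipy supplies only reference distributions (normal, chi-square,
hypergeometric) and midranks; the test logic itself lives here.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

#: Exact-enumeration thresholds.
SIGNED_RANK_EXACT_MAX_N = 25
RANK_SUM_EXACT_MAX_N = 12


@dataclass
class TestResult:
    """A statistic with effect size, 95% CI, and two-sided p-value."""

    name: str
    statistic: float
    p_value: float
    estimate: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    n: int = 0
    method: str = ""
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "estimate": self.estimate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n": self.n,
            "method": self.method,
            "flags": list(self.flags),
        }


@dataclass(frozen=True)
class PairExposureCounts:
    """Matched-pair 2x2 exposure counts for one binary variable."""

    n11: int  # both exposed
    n10: int  # case only
    n01: int  # control only
    n00: int  # neither

    def __post_init__(self):
        for v in (self.n11, self.n10, self.n01, self.n00):
            if v < 0 or int(v) != v:
                raise ValueError("pair counts must be non-negative integers")

    @property
    def n_pairs(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00

    @classmethod
    def from_pairs(cls, case_exposed: Sequence[bool], control_exposed: Sequence[bool]) -> "PairExposureCounts":
        if len(case_exposed) != len(control_exposed):
            raise ValueError("mismatched pair arrays")
        a = np.asarray(case_exposed, dtype=bool)
        b = np.asarray(control_exposed, dtype=bool)
        return cls(
            n11=int((a & b).sum()),
            n10=int((a & ~b).sum()),
            n01=int((~a & b).sum()),
            n00=int((~a & ~b).sum()),
        )


def _two_sided_from_distribution(values: np.ndarray, weights: np.ndarray, observed: float) -> float:
    """Two-sided p as 2*min(P(T <= t), P(T >= t)), capped at 1."""
    total = weights.sum()
    lower = weights[values <= observed + 1e-9].sum() / total
    upper = weights[values >= observed - 1e-9].sum() / total
    return float(min(1.0, 2.0 * min(lower, upper)))


def _signed_rank_distribution(ranks2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Distribution of 2*W+ over all sign assignments, by convolution.

    ``ranks2`` are the midranks doubled so they are integers even with ties.
    Returns (support, counts).
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    return np.arange(total + 1), counts


def signed_rank_test(
    case_values: Sequence[float],
    control_values: Sequence[float],
) -> TestResult:
    """Wilcoxon matched-pair signed-rank test on case - control differences.

    Zero differences are discarded (classical Wilcoxon).  Exact two-sided p
    by enumeration of sign assignments when the effective n is at most 25,
    otherwise a normal approximation with tie and continuity corrections.
    Pairs with a missing member are dropped (pairwise-complete).
    """
    a = np.asarray(case_values, dtype=float)
    b = np.asarray(control_values, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    keep = ~(np.isnan(a) | np.isnan(b))
    d = a[keep] - b[keep]
    if d.size == 0:
        raise ValueError("no complete pairs")
    n_complete = int(d.size)
    d = d[d != 0.0]
    n = int(d.size)
    if n == 0:
        return TestResult(
            name="signed_rank", statistic=0.0, p_value=1.0, n=n_complete,
            method="degenerate", flags=["all_differences_zero"],
        )
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= SIGNED_RANK_EXACT_MAX_N:
        ranks2 = np.round(2.0 * ranks).astype(int)
        support, counts = _signed_rank_distribution(ranks2)
        p = _two_sided_from_distribution(support.astype(float), counts, 2.0 * w_plus)
        method = "exact"
    else:
        mean = n * (n + 1) / 4.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        tie_term = float(((tie_counts**3 - tie_counts)).sum()) / 48.0
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        if var <= 0:
            return TestResult(
                name="signed_rank", statistic=w_plus, p_value=1.0, n=n_complete,
                method="degenerate", flags=["zero_variance"],
            )
        z = (abs(w_plus - mean) - 0.5) / math.sqrt(var)
        z = max(z, 0.0)
        p = float(min(1.0, 2.0 * sps.norm.sf(z)))
        method = "normal_approx"
    return TestResult(
        name="signed_rank", statistic=w_plus, p_value=p, n=n_complete, method=method
    )


def conditional_log_likelihood(beta: float, n10: int, n01: int) -> float:
    """Conditional likelihood of 1:1 matched pairs with one binary covariate:
    only discordant pairs contribute, each case-exposed pair with probability
    e^beta/(1+e^beta)."""
    logp1 = beta - math.log1p(math.exp(beta))
    logp0 = -math.log1p(math.exp(beta))
    return n10 * logp1 + n01 * logp0


def matched_pairs_or(counts: PairExposureCounts) -> TestResult:
    """Conditional-ML odds ratio for 1:1 matched pairs: OR = n10/n01.

    95% CI is the Wald interval on the log scale; the p-value is the
    continuity-corrected McNemar (conditional score) test.  Boundary counts
    give a zero/infinite OR with a one-sided interval, flagged.
    """
    n10, n01 = counts.n10, counts.n01
    n_disc = n10 + n01
    flags: list[str] = []
    if n_disc == 0:
        return TestResult(
            name="matched_pairs_or", statistic=float("nan"), p_value=float("nan"),
            estimate=float("nan"), n=counts.n_pairs, method="degenerate",
            flags=["no_discordant_pairs"],
        )
    chi = max(abs(n10 - n01) - 1.0, 0.0) ** 2 / n_disc
    p = float(sps.chi2.sf(chi, df=1))
    if n10 > 0 and n01 > 0:
        or_hat = n10 / n01
        se = math.sqrt(1.0 / n10 + 1.0 / n01)
        lo = math.exp(math.log(or_hat) - 1.959963984540054 * se)
        hi = math.exp(math.log(or_hat) + 1.959963984540054 * se)
    elif n10 == 0:
        or_hat, flags = 0.0, ["boundary_zero"]
        se = math.sqrt(1.0 / (n10 + 0.5) + 1.0 / (n01 + 0.5))
        lo = 0.0
        hi = math.exp(math.log((n10 + 0.5) / (n01 + 0.5)) + 1.959963984540054 * se)
    else:
        or_hat, flags = float("inf"), ["boundary_infinite"]
        se = math.sqrt(1.0 / (n10 + 0.5) + 1.0 / (n01 + 0.5))
        lo = math.exp(math.log((n10 + 0.5) / (n01 + 0.5)) - 1.959963984540054 * se)
        hi = float("inf")
    return TestResult(
        name="matched_pairs_or", statistic=chi, p_value=p, estimate=or_hat,
        ci_low=lo, ci_high=hi, n=counts.n_pairs, method="mcnemar_cc", flags=flags,
    )


def rank_sum_test(group_a: Sequence[float], group_b: Sequence[float]) -> TestResult:
    """Wilcoxon rank-sum (Mann-Whitney) test with midranks.

    Exact two-sided p by enumeration of all C(N, n_a) rank splits when
    N <= 12, otherwise a normal approximation with tie and continuity
    corrections.
    """
    a = np.asarray([v for v in group_a if not (isinstance(v, float) and math.isnan(v))], dtype=float)
    b = np.asarray([v for v in group_b if not (isinstance(v, float) and math.isnan(v))], dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    na, nb = int(a.size), int(b.size)
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    w_a = float(ranks[:na].sum())
    u = w_a - na * (na + 1) / 2.0
    n_total = na + nb
    if n_total <= RANK_SUM_EXACT_MAX_N:
        sums = np.array(
            [sum(comb) for comb in itertools.combinations(ranks, na)], dtype=float
        )
        p = _two_sided_from_distribution(sums, np.ones_like(sums), w_a)
        method = "exact"
    else:
        mean_u = na * nb / 2.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        tie_term = float((tie_counts**3 - tie_counts).sum()) / (n_total * (n_total - 1))
        var_u = na * nb / 12.0 * ((n_total + 1) - tie_term)
        if var_u <= 0:
            return TestResult(
                name="rank_sum", statistic=u, p_value=1.0, n=n_total,
                method="degenerate", flags=["zero_variance"],
            )
        z = (abs(u - mean_u) - 0.5) / math.sqrt(var_u)
        z = max(z, 0.0)
        p = float(min(1.0, 2.0 * sps.norm.sf(z)))
        method = "normal_approx"
    return TestResult(name="rank_sum", statistic=u, p_value=p, n=n_total, method=method)


def categorical_test(table: Sequence[Sequence[float]]) -> TestResult:
    """Pearson chi-square or Fisher's exact test for a 2x2 table.

    Fisher's exact (two-sided, summing hypergeometric probabilities no larger
    than the observed table's) is used when any expected cell is below 5,
    Pearson chi-square without continuity correction otherwise.  The rule
    applied is reported in ``method``.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0) or np.any(t != np.round(t)):
        raise ValueError("table must be 2x2 with non-negative integer cells")
    t = t.astype(int)
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    n = int(t.sum())
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    or_hat = (a * d) / (b * c) if b * c > 0 else (float("inf") if a * d > 0 else float("nan"))
    ci_low = ci_high = None
    if min(a, b, c, d) > 0:
        se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        ci_low = math.exp(math.log(or_hat) - 1.959963984540054 * se)
        ci_high = math.exp(math.log(or_hat) + 1.959963984540054 * se)
    if n == 0 or 0 in row or 0 in col:
        return TestResult(
            name="categorical", statistic=0.0, p_value=1.0, estimate=or_hat,
            n=n, method="degenerate", flags=["zero_margin"],
        )
    expected = np.outer(row, col) / n
    if (expected < 5).any():
        rv = sps.hypergeom(n, row[0], col[0])
        support = np.arange(max(0, col[0] - row[1]), min(row[0], col[0]) + 1)
        pmf = rv.pmf(support)
        p_obs = rv.pmf(a)
        p = float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-7)].sum()))
        return TestResult(
            name="categorical", statistic=float(a), p_value=p, estimate=or_hat,
            ci_low=ci_low, ci_high=ci_high, n=n, method="fisher_exact",
        )
    chi = float(((t - expected) ** 2 / expected).sum())
    p = float(sps.chi2.sf(chi, df=1))
    return TestResult(
        name="categorical", statistic=chi, p_value=p, estimate=or_hat,
        ci_low=ci_low, ci_high=ci_high, n=n, method="chi_square",
    )


def benjamini_hochberg(p_values: Sequence[float]) -> list[float]:
    """BH-adjusted p-values (optional; the primary analysis reports raw
    two-sided p-values with a 0.05 threshold)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p)
    adjusted = np.empty(m)
    running = 1.0
    for rank_idx in range(m - 1, -1, -1):
        i = order[rank_idx]
        running = min(running, p[i] * m / (rank_idx + 1))
        adjusted[i] = running
    return adjusted.tolist()
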