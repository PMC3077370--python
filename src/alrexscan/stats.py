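"""Core statistics.

The exact hypergeometric tail used throughout the motif-threshold machinery
is authored here from the closed-form pmf

    P(i | N, m, n) = C(m, i) C(N-m, n-i) / C(N, n)

with the enrichment p-value P(overlap >= k) obtained by direct summation of
the pmf over the upper tail (log-gamma arithmetic for stability). Fisher's
exact test (two-sided by pmf ordering), the Wilcoxon rank-sum test (exact
enumeration for small samples, tie-corrected normal approximation
otherwise), a bootstrap standard error for the median and Welch-t /
Kolmogorov-Smirnov distribution comparisons round out the module.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from math import lgamma
from typing import Sequence

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 counts in the threshold-selection layout.

    a = 5UI- and motif-containing, b = 5UI+ and motif-containing,
    c = 5UI- and not motif-containing, d = 5UI+ and not motif-containing.
    Derived margins: N total, m = a+c (5UI- genes), n = a+b
    (motif-containing sequences), k = a (the overlap).
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise ValueError("contingency counts must be non-negative integers")

    @property
    def N(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def m(self) -> int:
        return self.a + self.c

    @property
    def n(self) -> int:
        return self.a + self.b

    @property
    def k(self) -> int:
        return self.a


@dataclass
class TestResult:
    """Serializable outcome of a statistical test."""

    statistic: float
    p_value: float
    effect: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    tail: str = "two_sided"
    method: str = ""

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0 + 1e-12):
            raise ValueError(f"p-value out of range: {self.p_value}")
        self.p_value = min(self.p_value, 1.0)

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "p_value": self.p_value,
            "effect": self.effect,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "tail": self.tail,
            "method": self.method,
        }


def _log_hyper_pmf(i: int, N: int, m: int, n: int) -> float:
    """log P(i overlaps | N, m, n) via log-gamma."""
    return (
        lgamma(m + 1) - lgamma(i + 1) - lgamma(m - i + 1)
        + lgamma(N - m + 1) - lgamma(n - i + 1) - lgamma(N - m - n + i + 1)
        - (lgamma(N + 1) - lgamma(n + 1) - lgamma(N - n + 1))
    )


def hypergeom_pmf(i: int, N: int, m: int, n: int) -> float:
    lo = max(0, n - (N - m))
    hi = min(m, n)
    if i < lo or i > hi:
        return 0.0
    return math.exp(_log_hyper_pmf(i, N, m, n))


def hypergeom_tail(table: ContingencyTable2x2, tail: str = "greater") -> float:
    """Exact hypergeometric tail probability by pmf summation.

    tail='greater' gives P(overlap >= k), the enrichment p-value; 'less'
    gives P(overlap <= k).
    """
    N, m, n, k = table.N, table.m, table.n, table.k
    lo = max(0, n - (N - m))
    hi = min(m, n)
    if not lo <= k <= hi:
        raise ValueError(f"inconsistent margins: k={k} outside [{lo},{hi}]")
    if tail == "greater":
        if k <= lo:  # tail covers the entire support
            return 1.0
        terms = [math.exp(_log_hyper_pmf(i, N, m, n)) for i in range(k, hi + 1)]
    elif tail == "less":
        if k >= hi:
            return 1.0
        terms = [math.exp(_log_hyper_pmf(i, N, m, n)) for i in range(lo, k + 1)]
    else:
        raise ValueError(f"unknown tail: {tail}")
    return min(1.0, math.fsum(terms))


_PMF_REL_GATE = 1.0 + 1e-7  # relative tolerance when comparing pmf values


def fisher_exact_2x2(table: ContingencyTable2x2, tail: str = "two_sided") -> TestResult:
    """Fisher's exact test on a 2x2 table.

    Two-sided p sums the probabilities of all margin-fixed tables whose pmf
    does not exceed the observed table's pmf. The odds ratio is the sample
    ad/bc; its 95% CI uses the Woolf log-OR formula, with the Haldane +0.5
    correction applied only when the table contains a zero cell. A zero
    margin yields p = 1 with a missing effect.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    N, m, n, k = table.N, table.m, table.n, table.k
    if min(N, m, n) == 0 or m == N or n == N:
        return TestResult(
            statistic=float("nan"), p_value=1.0, effect=None, tail=tail,
            method="fisher_exact",
        )
    if tail in ("greater", "less"):
        p = hypergeom_tail(table, tail)
    elif tail == "two_sided":
        lo = max(0, n - (N - m))
        hi = min(m, n)
        obs = hypergeom_pmf(k, N, m, n)
        p = math.fsum(
            pm
            for i in range(lo, hi + 1)
            if (pm := hypergeom_pmf(i, N, m, n)) <= obs * _PMF_REL_GATE
        )
        p = min(1.0, p)
    else:
        raise ValueError(f"unknown tail: {tail}")

    if b * c == 0 and a * d == 0:
        odds = float("nan")
    elif b * c == 0:
        odds = float("inf")
    else:
        odds = (a * d) / (b * c)

    if 0 in (a, b, c, d):
        aa, bb, cc, dd = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        aa, bb, cc, dd = a, b, c, d
    log_or = math.log((aa * dd) / (bb * cc))
    se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    ci_low = math.exp(log_or - 1.959963984540054 * se)
    ci_high = math.exp(log_or + 1.959963984540054 * se)
    return TestResult(
        statistic=odds, p_value=p, effect=odds, ci_low=ci_low, ci_high=ci_high,
        tail=tail, method="fisher_exact",
    )


def _midranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def wilcoxon_rank_sum(
    x: Sequence[float],
    y: Sequence[float],
    mode: str = "auto",
    tail: str = "two_sided",
) -> TestResult:
    """Wilcoxon rank-sum (Mann-Whitney) test.

    The exact path enumerates all assignments of the pooled midranks to the
    two samples (feasible for nx + ny <= ~12, the default switch point);
    otherwise a normal approximation with tie and continuity corrections is
    used. The effect reported is the difference of sample medians.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    nx, ny = x.size, y.size
    N = nx + ny
    ranks = _midranks(np.concatenate([x, y]))
    w_obs = float(ranks[:nx].sum())
    mu = nx * (N + 1) / 2.0
    effect = float(np.median(x) - np.median(y))

    if mode == "auto":
        mode = "exact" if N <= 12 else "normal_approx"

    if mode == "exact":
        dev = abs(w_obs - mu)
        total = math.comb(N, nx)
        count_ge = 0
        count_low = 0  # W <= w_obs, for one-sided tails
        count_high = 0
        for combo in itertools.combinations(range(N), nx):
            w = sum(ranks[i] for i in combo)
            if abs(w - mu) >= dev - 1e-9:
                count_ge += 1
            if w <= w_obs + 1e-9:
                count_low += 1
            if w >= w_obs - 1e-9:
                count_high += 1
        if tail == "two_sided":
            p = count_ge / total
        elif tail == "less":
            p = count_low / total
        elif tail == "greater":
            p = count_high / total
        else:
            raise ValueError(f"unknown tail: {tail}")
        return TestResult(
            statistic=w_obs, p_value=p, effect=effect, tail=tail,
            method="wilcoxon_exact",
        )

    if mode != "normal_approx":
        raise ValueError(f"unknown mode: {mode}")
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (N * (N - 1)))
    var = nx * ny / 12.0 * ((N + 1) - tie_term)
    if var <= 0:
        return TestResult(statistic=w_obs, p_value=1.0, effect=effect, tail=tail,
                          method="wilcoxon_normal")
    sd = math.sqrt(var)
    delta = w_obs - mu
    # continuity correction shrinks |delta| by 0.5
    if tail == "two_sided":
        z = (abs(delta) - 0.5) / sd
        p = 2.0 * sps.norm.sf(max(z, 0.0))
    elif tail == "greater":
        z = (delta - 0.5) / sd
        p = sps.norm.sf(z)
    elif tail == "less":
        z = (delta + 0.5) / sd
        p = sps.norm.cdf(z)
    else:
        raise ValueError(f"unknown tail: {tail}")
    return TestResult(
        statistic=w_obs, p_value=min(1.0, float(p)), effect=effect, tail=tail,
        method="wilcoxon_normal",
    )


def bootstrap_median_se(
    values: Sequence[float], B: int = 1000, seed: int | None = 0
) -> float:
    """Bootstrap standard error of the median (B seeded resamples)."""
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise ValueError("values must be non-empty")
    if B < 100:
        raise ValueError("B must be >= 100")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(B, values.size))
    medians = np.median(values[idx], axis=1)
    return float(np.std(medians, ddof=1))


def bootstrap_ci(
    statistic,
    samples: Sequence[np.ndarray],
    B: int = 2000,
    seed: int | None = 0,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Percentile bootstrap CI of ``statistic(*resampled_samples)``."""
    rng = np.random.default_rng(seed)
    arrays = [np.asarray(s, dtype=float) for s in samples]
    reps = np.empty(B)
    for b in range(B):
        res = [a[rng.integers(0, a.size, a.size)] for a in arrays]
        reps[b] = statistic(*res)
    return (
        float(np.quantile(reps, alpha / 2)),
        float(np.quantile(reps, 1 - alpha / 2)),
    )


def distribution_compare(
    x: Sequence[float],
    y: Sequence[float] | None = None,
    mode: str = "welch_t",
) -> TestResult:
    """Welch two-sample t-test or Kolmogorov-Smirnov comparison.

    mode='welch_t' requires two samples. mode='ks' with one sample tests
    against a normal distribution whose mean and sd are estimated from the
    data (the estimated-parameter caveat applies: the nominal p is
    conservative only as a descriptive device); with two samples it runs the
    two-sample KS test.
    """
    x = np.asarray(list(x), dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 observations in x")
    if mode == "welch_t":
        if y is None:
            raise ValueError("welch_t needs two samples")
        y = np.asarray(list(y), dtype=float)
        if y.size < 3:
            raise ValueError("need at least 3 observations in y")
        if np.var(x) == 0 and np.var(y) == 0:
            if float(np.mean(x)) == float(np.mean(y)):
                return TestResult(statistic=0.0, p_value=1.0,
                                  effect=0.0, method="welch_t")
            raise ValueError("zero variance in both samples")
        res = sps.ttest_ind(x, y, equal_var=False)
        return TestResult(
            statistic=float(res.statistic), p_value=float(res.pvalue),
            effect=float(np.mean(x) - np.mean(y)), method="welch_t",
        )
    if mode == "ks":
        if y is None:
            mean, sd = float(np.mean(x)), float(np.std(x, ddof=1))
            res = sps.kstest(x, "norm", args=(mean, sd))
            method = "ks_one_sample_vs_fitted_normal"
        else:
            y = np.asarray(list(y), dtype=float)
            res = sps.ks_2samp(x, y)
            method = "ks_two_sample"
        return TestResult(
            statistic=float(res.statistic), p_value=float(res.pvalue),
            method=method,
        )
    raise ValueError(f"unknown mode: {mode}")
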