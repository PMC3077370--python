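"""Exact hypergeometric/Fisher machinery, Wilcoxon, bootstrap, Welch/KS."""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from alrexscan.stats import (
    ContingencyTable2x2,
    bootstrap_ci,
    bootstrap_median_se,
    distribution_compare,
    fisher_exact_2x2,
    hypergeom_tail,
    wilcoxon_rank_sum,
)


def exact_tail(N, m, n, k, tail):
    """Independent oracle: binomial-coefficient enumeration with Fractions."""
    lo, hi = max(0, n - (N - m)), min(m, n)
    denom = math.comb(N, n)
    if tail == "greater":
        num = sum(math.comb(m, i) * math.comb(N - m, n - i) for i in range(k, hi + 1))
    else:
        num = sum(math.comb(m, i) * math.comb(N - m, n - i) for i in range(lo, k + 1))
    return Fraction(num, denom)


def exact_two_sided(N, m, n, k):
    """Oracle two-sided Fisher p by exact integer pmf ordering."""
    lo, hi = max(0, n - (N - m)), min(m, n)
    weights = {i: math.comb(m, i) * math.comb(N - m, n - i) for i in range(lo, hi + 1)}
    obs = weights[k]
    return Fraction(sum(w for w in weights.values() if w <= obs), math.comb(N, n))


def table_from_margins(N, m, n, k):
    return ContingencyTable2x2(a=k, b=n - k, c=m - k, d=N - m - n + k)


class TestHypergeomTail:
    def test_full_overlap_small_table(self):
        # N=10, m=n=k=5: only 1 of C(10,5)=252 draws overlaps completely
        t = table_from_margins(10, 5, 5, 5)
        assert hypergeom_tail(t, "greater") == pytest.approx(1 / 252, abs=1e-15)

    def test_partial_overlap(self):
        t = table_from_margins(8, 4, 4, 3)
        assert hypergeom_tail(t, "greater") == pytest.approx(17 / 70, abs=1e-15)

    def test_k_zero_greater_is_one(self):
        t = table_from_margins(20, 8, 5, 0)
        assert hypergeom_tail(t, "greater") == 1.0

    @given(
        st.integers(1, 40),
        st.data(),
    )
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_tail_identity(self, N, data):
        m = data.draw(st.integers(0, N))
        n = data.draw(st.integers(0, N))
        lo, hi = max(0, n - (N - m)), min(m, n)
        if hi < lo + 1:
            return
        k = data.draw(st.integers(lo + 1, hi))
        t_k = table_from_margins(N, m, n, k)
        t_k1 = table_from_margins(N, m, n, k - 1)
        assert hypergeom_tail(t_k, "greater") + hypergeom_tail(
            t_k1, "less"
        ) == pytest.approx(1.0, abs=1e-12)

    def test_matches_scipy_sf(self, rng):
        for _ in range(50):
            N = int(rng.integers(2, 200))
            m = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            lo, hi = max(0, n - (N - m)), min(m, n)
            k = int(rng.integers(lo, hi + 1))
            ours = hypergeom_tail(table_from_margins(N, m, n, k), "greater")
            scipy_p = sps.hypergeom.sf(k - 1, N, m, n)
            assert ours == pytest.approx(scipy_p, rel=1e-10, abs=1e-300)


class TestFisherExact:
    def test_symmetric_table(self):
        res = fisher_exact_2x2(ContingencyTable2x2(5, 5, 5, 5))
        assert res.effect == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self):
        t = ContingencyTable2x2(8, 2, 2, 8)
        res = fisher_exact_2x2(t)
        oracle = float(exact_two_sided(t.N, t.m, t.n, t.k))
        assert res.p_value == pytest.approx(oracle, abs=1e-12)

    def test_zero_cells_haldane(self):
        t = ContingencyTable2x2(0, 10, 10, 0)
        res = fisher_exact_2x2(t)
        assert res.effect == 0.0
        assert res.ci_low is not None and res.ci_low > 0
        less = fisher_exact_2x2(t, "less")
        assert less.p_value == pytest.approx(hypergeom_tail(t, "less"), abs=1e-15)

    def test_zero_margin_reports_missing_effect(self):
        res = fisher_exact_2x2(ContingencyTable2x2(0, 0, 5, 7))
        assert res.p_value == 1.0 and res.effect is None

    def test_two_sided_at_least_the_smaller_one_sided(self, rng):
        # pmf-ordering two-sided p always dominates the matching (smaller)
        # one-sided tail; the opposite tail can of course be near 1
        for _ in range(30):
            t = ContingencyTable2x2(*(int(x) for x in rng.integers(0, 12, 4)))
            if min(t.N, t.m, t.n) == 0 or t.m == t.N or t.n == t.N:
                continue
            two = fisher_exact_2x2(t).p_value
            ones = [fisher_exact_2x2(t, tail).p_value for tail in ("greater", "less")]
            assert 0.0 <= two <= 1.0
            assert two >= min(ones) - 1e-12

    def test_matches_scipy_on_random_tables(self, rng):
        for _ in range(40):
            a, b, c, d = (int(x) for x in rng.integers(0, 25, 4))
            t = ContingencyTable2x2(a, b, c, d)
            if min(t.N, t.m, t.n) == 0 or t.m == t.N or t.n == t.N:
                continue
            ours = fisher_exact_2x2(t).p_value
            theirs = sps.fisher_exact([[a, b], [c, d]])[1]
            assert ours == pytest.approx(theirs, rel=1e-8)


class TestWilcoxonRankSum:
    def test_exact_separated_triples(self):
        res = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6], mode="exact")
        assert res.p_value == pytest.approx(0.1)

    def test_identical_multisets_give_p_one(self):
        res = wilcoxon_rank_sum([1, 2, 2, 5], [1, 2, 2, 5], mode="exact")
        assert res.p_value == pytest.approx(1.0)

    def test_large_shift_detected(self, rng):
        x = rng.normal(0, 1, 200)
        y = rng.normal(1, 1, 200)
        res = wilcoxon_rank_sum(x, y, mode="normal_approx")
        assert res.p_value < 1e-15

    def test_normal_approx_matches_scipy(self, rng):
        x = rng.normal(0, 1, 40)
        y = rng.normal(0.4, 1.2, 55)
        ours = wilcoxon_rank_sum(x, y, mode="normal_approx")
        theirs = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert ours.p_value == pytest.approx(theirs.pvalue, rel=1e-6)

    def test_exact_matches_permutation_monte_carlo(self, rng):
        for _ in range(10):
            nx, ny = int(rng.integers(3, 6)), int(rng.integers(3, 6))
            x = rng.normal(0, 1, nx).round(1)
            y = rng.normal(0.5, 1, ny).round(1)
            res = wilcoxon_rank_sum(x, y, mode="exact")
            ranks = sps.rankdata(np.concatenate([x, y]))
            mu = nx * (len(ranks) + 1) / 2
            dev = abs(ranks[:nx].sum() - mu)
            B = 20000
            perm = np.array([
                rng.permutation(ranks)[:nx].sum() for _ in range(B)
            ])
            p_mc = float(np.mean(np.abs(perm - mu) >= dev - 1e-9))
            sd = math.sqrt(max(p_mc * (1 - p_mc), 1e-6) / B)
            assert abs(res.p_value - p_mc) < 3 * sd + 1e-9

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestBootstrapMedianSe:
    def test_constant_vector(self):
        assert bootstrap_median_se([3.0] * 25, B=200, seed=0) == 0.0

    def test_seed_reproducibility(self, rng):
        values = rng.normal(0, 1, 100)
        assert bootstrap_median_se(values, B=500, seed=9) == bootstrap_median_se(
            values, B=500, seed=9
        )

    def test_matches_asymptotic_closed_form(self, rng):
        n = 400
        values = rng.normal(0, 1, n)
        se = bootstrap_median_se(values, B=2000, seed=1)
        expected = 1.2533 / math.sqrt(n)
        assert abs(se - expected) / expected < 0.25

    def test_b_too_small_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_median_se([1.0, 2.0], B=50)


class TestDistributionCompare:
    def test_identical_samples_welch(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = distribution_compare(x, list(x), mode="welch_t")
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_welch_matches_direct_formula(self):
        x = np.array([2.1, 3.4, 1.9, 2.8, 3.1])
        y = np.array([4.0, 3.6, 4.4, 5.1, 3.9, 4.8, 4.2])
        res = distribution_compare(x, y, mode="welch_t")
        vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
        t = (x.mean() - y.mean()) / math.sqrt(vx + vy)
        df = (vx + vy) ** 2 / (vx**2 / (len(x) - 1) + vy**2 / (len(y) - 1))
        p = 2 * sps.t.sf(abs(t), df)
        assert res.statistic == pytest.approx(t)
        assert res.p_value == pytest.approx(p)

    def test_ks_of_normal_quantiles_near_one(self):
        # exact normal quantiles against the fitted normal: maximal agreement
        q = sps.norm.ppf((np.arange(1, 200) - 0.5) / 199)
        res = distribution_compare(q, mode="ks")
        assert res.p_value > 0.9

    def test_zero_variance_both_sides_is_error(self):
        with pytest.raises(ValueError):
            distribution_compare([1.0] * 5, [2.0] * 5, mode="welch_t")


def test_bootstrap_ci_covers_true_median(rng):
    x = rng.normal(5, 2, 300)
    lo, hi = bootstrap_ci(np.median, [x], B=500, seed=3)
    assert lo < 5.5 and hi > 4.5 and lo < hi
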