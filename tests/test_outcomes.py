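"""Exact binomial intervals, exact conditional response tests, KM/Cox machinery."""

import numpy as np
import pytest
from scipy import stats
from scipy.optimize import brentq

from clonarch import (
    compare_orr,
    compare_survival,
    fisher_exact_2x2,
    km_curve,
    orr_with_exact_ci,
    simulate_survival_groups,
)


def clopper_pearson_oracle(r, n, level=0.95):
    """Independent interval from direct root-finding on the binomial tails."""
    alpha = 1 - level
    lo = 0.0 if r == 0 else brentq(
        lambda p: stats.binom.sf(r - 1, n, p) - alpha / 2, 1e-12, 1 - 1e-12
    )
    hi = 1.0 if r == n else brentq(
        lambda p: stats.binom.cdf(r, n, p) - alpha / 2, 1e-12, 1 - 1e-12
    )
    return lo, hi


class TestOrrExactCi:
    @pytest.mark.parametrize(
        "r,n,pct_lo,pct_hi",
        [
            (0, 5, 0.0, 52),  # upper bound is 1 - 0.025**(1/5)
            (14, 47, 17, 45),
            (1, 19, 0.13, 26),
            (2, 18, 1.4, 35),
            (12, 29, 24, 61),
            (1, 14, 0.18, 34),
        ],
    )
    def test_reproduces_reported_bounds(self, r, n, pct_lo, pct_hi):
        res = orr_with_exact_ci(r, n)
        # reported values carry two significant figures
        assert res.ci_low * 100 == pytest.approx(pct_lo, abs=0.6)
        assert res.ci_high * 100 == pytest.approx(pct_hi, abs=0.6)

    def test_all_responders_boundary(self):
        res = orr_with_exact_ci(19, 19)
        assert res.orr == 1.0 and res.ci_high == 1.0
        assert res.ci_low < 1.0

    def test_matches_tail_inversion_oracle(self):
        for r, n in [(5, 10), (0, 5), (3, 8), (7, 7), (1, 50)]:
            res = orr_with_exact_ci(r, n)
            lo, hi = clopper_pearson_oracle(r, n)
            assert res.ci_low == pytest.approx(lo, abs=1e-9)
            assert res.ci_high == pytest.approx(hi, abs=1e-9)

    def test_bounds_monotone_in_responders(self):
        n = 23
        lows = [orr_with_exact_ci(r, n).ci_low for r in range(n + 1)]
        highs = [orr_with_exact_ci(r, n).ci_high for r in range(n + 1)]
        assert all(b >= a for a, b in zip(lows, lows[1:]))
        assert all(b >= a for a, b in zip(highs, highs[1:]))

    def test_display_two_significant_figures(self):
        assert orr_with_exact_ci(0, 5).display() == "0.0% (95% CI, 0.0-52)"
        assert orr_with_exact_ci(14, 47).display() == "30% (95% CI, 17-45)"

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            orr_with_exact_ci(1, 0)
        with pytest.raises(ValueError):
            orr_with_exact_ci(6, 5)

    def test_empirical_coverage_at_nominal_level(self):
        rng = np.random.default_rng(2024)
        reps = 10_000
        for n in (5, 19, 47):
            for p in (0.05, 0.3):
                draws = rng.binomial(n, p, size=reps)
                covered = 0
                # interval depends only on r: precompute per count
                intervals = [orr_with_exact_ci(r, n) for r in range(n + 1)]
                for r in draws:
                    res = intervals[r]
                    covered += res.ci_low <= p <= res.ci_high
                coverage = covered / reps
                mc_se = np.sqrt(0.95 * 0.05 / reps)
                assert coverage >= 0.95 - 3 * mc_se, (n, p, coverage)


class TestCompareOrr:
    def test_unstratified_equals_fisher_bit_for_bit(self):
        a = [True] * 14 + [False] * 33
        b = [True] * 1 + [False] * 18
        assert compare_orr(a, b) == fisher_exact_2x2([[14, 33], [1, 18]])

    def test_single_stratum_reduces_to_fisher(self):
        a = [True] * 3 + [False] * 7
        b = [True] * 1 + [False] * 9
        p_strat = compare_orr(a, b, ["s1"] * 10, ["s1"] * 10)
        assert p_strat == fisher_exact_2x2([[3, 7], [1, 9]])

    def test_reported_within_arm_comparisons(self):
        # placebo arm: 2/18 vs 0/5 responders
        assert compare_orr(
            [True] * 2 + [False] * 16, [False] * 5
        ) == pytest.approx(1.0)
        # experimental arm: 12/29 vs 1/14
        p = compare_orr([True] * 12 + [False] * 17, [True] + [False] * 13)
        assert round(p, 3) == 0.033

    def test_stratified_matches_brute_force_enumeration(self):
        # two strata; enumerate the joint null over per-stratum tables
        a = np.array([True, True, False, False, True, False, False])
        b = np.array([True, False, False, False, False])
        sa = np.array(["x", "x", "x", "x", "y", "y", "y"])
        sb = np.array(["x", "x", "x", "y", "y"])
        p = compare_orr(a, b, sa, sb)

        def stratum_pmf(resp_a, resp_b):
            n_a, n_b = len(resp_a), len(resp_b)
            k = int(resp_a.sum() + resp_b.sum())
            lo = max(0, k - n_b)
            hi = min(k, n_a)
            return {
                x: stats.hypergeom.pmf(x, n_a + n_b, k, n_a)
                for x in range(lo, hi + 1)
            }

        pmf_x = stratum_pmf(a[sa == "x"], b[sb == "x"])
        pmf_y = stratum_pmf(a[sa == "y"], b[sb == "y"])
        joint: dict[int, float] = {}
        for x, px in pmf_x.items():
            for y, py in pmf_y.items():
                joint[x + y] = joint.get(x + y, 0.0) + px * py
        observed = int(a.sum())
        p_obs = joint[observed]
        expected = sum(q for q in joint.values() if q <= p_obs * (1 + 1e-7))
        assert p == pytest.approx(expected, rel=1e-10)

    def test_stratum_missing_in_one_group_dropped_with_warning(self):
        a = [True, False, False, True]
        b = [False, False]
        with pytest.warns(UserWarning, match="dropped"):
            p = compare_orr(a, b, ["x", "x", "y", "z"], ["x", "y"])
        assert 0 < p <= 1

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_orr([], [True])


class TestKmCurve:
    def test_no_censoring_equals_empirical_survival(self):
        curve = km_curve([1, 2, 3], [True, True, True])
        assert curve.survival_at(1) == pytest.approx(2 / 3)
        assert curve.survival_at(2) == pytest.approx(1 / 3)
        assert curve.survival_at(3) == pytest.approx(0.0)
        assert curve.median == 2

    def test_no_censoring_matches_one_minus_ecdf_generally(self):
        rng = np.random.default_rng(1)
        times = rng.exponential(5.0, size=40)
        curve = km_curve(times, np.ones(40, dtype=bool))
        for t in np.quantile(times, [0.1, 0.5, 0.9]):
            ecdf = (times <= t).mean()
            assert curve.survival_at(t) == pytest.approx(1 - ecdf, abs=1e-12)

    def test_all_censored_flat_curve_no_median(self):
        curve = km_curve([1, 2, 3], [False, False, False])
        assert (curve.survival == 1.0).all()
        assert curve.median is None

    def test_exponential_median_closed_form(self):
        rng = np.random.default_rng(7)
        lam = 0.2
        times = rng.exponential(1 / lam, size=2000)
        curve = km_curve(times, np.ones_like(times, dtype=bool))
        assert curve.median == pytest.approx(np.log(2) / lam, rel=0.05)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            km_curve([], [])


class TestCompareSurvival:
    def test_identical_groups_null_result(self):
        t = [2.0, 4.0, 6.0, 8.0, 10.0]
        e = [True, True, False, True, False]
        res = compare_survival(t, e, t, e)
        assert res.hazard_ratio == pytest.approx(1.0, abs=1e-6)
        assert res.logrank_p == pytest.approx(1.0, abs=1e-6)

    def test_hand_computed_logrank_statistic(self):
        # A=[1,3,5], B=[2,4,6], all events: O_A=3, E_A=2.2333, V=1.21222
        res = compare_survival([1, 3, 5], [1, 1, 1], [2, 4, 6], [1, 1, 1])
        chi2 = (3 - 2.2333333333) ** 2 / 1.2122222222
        assert res.logrank_p == pytest.approx(stats.chi2.sf(chi2, 1), rel=1e-6)

    def test_weibull_groups_recover_true_hazard_ratio(self):
        ta, ea, tb, eb = simulate_survival_groups(
            500, hazard_ratio=0.37, shape=1.2, scale=8.0, seed=99
        )
        res = compare_survival(ta, ea, tb, eb)
        assert res.hazard_ratio == pytest.approx(0.37, rel=0.15)
        assert res.hr_ci_low < 0.37 < res.hr_ci_high
        assert res.logrank_p < 1e-6

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            compare_survival([1, 2], [False, False], [3], [False])
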