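"""MR estimators against independent oracles and exact identities."""

import math

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, strategies as st

from medimr.mr_core import (
    EstimationError,
    estimate_to_or,
    ivw,
    mr_egger,
    wald_ratio,
    weighted_median,
)
from medimr.mr_core import _weighted_median_point

from conftest import make_hset


class TestWaldRatio:
    @pytest.mark.parametrize(
        "beta_exp, beta_out, se_out, ratio, se",
        [
            (0.2, 0.0, 0.04, 0.0, 0.2),       # zero numerator
            (1.0, 0.05, 0.01, 0.05, 0.01),    # unit denominator
            (-0.3, 0.06, 0.03, -0.2, 0.1),    # hand arithmetic
        ],
    )
    def test_ratio_and_first_order_se(self, beta_exp, beta_out, se_out, ratio, se):
        hset = make_hset([beta_exp], [0.01], [beta_out], [se_out])
        wr = wald_ratio(next(hset.pairs.itertuples(index=False)))
        assert wr.ratio == pytest.approx(ratio)
        assert wr.se == pytest.approx(se)

    def test_zero_exposure_beta_is_degenerate(self):
        hset = make_hset([0.0], [0.01], [0.05], [0.01])
        with pytest.raises(EstimationError, match="beta_exp = 0"):
            wald_ratio(next(hset.pairs.itertuples(index=False)))


class TestIVW:
    def test_single_instrument_equals_wald_ratio(self):
        hset = make_hset([0.2], [0.01], [0.06], [0.03])
        est = ivw(hset)  # multiplicative_random falls back to fixed at k=1
        assert est.method == "ivw_fixed"
        assert est.beta == pytest.approx(0.3)
        assert est.se == pytest.approx(0.03 / 0.2)

    def test_homogeneous_ratios_fixed_equals_random(self, rng):
        bx = rng.uniform(0.1, 0.5, 5)
        hset = make_hset(bx, 0.01, 0.25 * bx, rng.uniform(0.01, 0.05, 5))
        fixed = ivw(hset, "fixed")
        random = ivw(hset, "multiplicative_random")
        assert fixed.beta == pytest.approx(0.25, abs=1e-12)
        assert fixed.se == pytest.approx(random.se)  # Q = 0 -> floor at 1

    def test_matches_wls_through_origin_oracle(self, small_hset):
        est = ivw(small_hset, "fixed")
        bx, _, by, so = small_hset.arrays()
        oracle = sm.WLS(by, bx, weights=so**-2).fit()
        assert est.beta == pytest.approx(oracle.params[0], abs=1e-10)
        # fixed-effect SE: hand-summed closed form
        se_hand = math.fsum((b / s) ** 2 for b, s in zip(bx, so)) ** -0.5
        assert est.se == pytest.approx(se_hand, abs=1e-12)

    def test_random_se_inflation_floor(self, small_hset):
        fixed = ivw(small_hset, "fixed")
        random = ivw(small_hset, "multiplicative_random")
        assert random.se >= fixed.se

    @given(st.integers(0, 5))
    def test_sign_flip_of_any_instrument_is_invariant(self, idx):
        rng = np.random.default_rng(42)
        bx = rng.uniform(0.1, 0.5, 6)
        so = rng.uniform(0.01, 0.05, 6)
        by = 0.3 * bx + rng.normal(0, so)
        flipped_bx, flipped_by = bx.copy(), by.copy()
        flipped_bx[idx] *= -1
        flipped_by[idx] *= -1
        a = ivw(make_hset(bx, 0.01, by, so))
        b = ivw(make_hset(flipped_bx, 0.01, flipped_by, so))
        assert a.beta == pytest.approx(b.beta, abs=1e-12)
        assert a.se == pytest.approx(b.se, abs=1e-12)

    def test_empty_set_impossible(self):
        hset = make_hset([0.2], [0.01], [0.06], [0.03])
        hset.pairs = hset.pairs.iloc[:0]
        with pytest.raises(EstimationError):
            ivw(hset)


class TestEgger:
    def test_exact_proportional_data(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        hset = make_hset(bx, 0.01, 0.1 * bx, 0.02)
        res = mr_egger(hset)
        assert res.slope.beta == pytest.approx(0.1, abs=1e-12)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)

    def test_exact_affine_data(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        hset = make_hset(bx, 0.01, 0.02 + 0.1 * bx, 0.02)
        res = mr_egger(hset)
        assert res.slope.beta == pytest.approx(0.1, abs=1e-12)
        assert res.intercept == pytest.approx(0.02, abs=1e-12)

    def test_matches_statsmodels_wls_oracle(self):
        # deterministic residual pattern guarantees Q/(k-2) > 1
        bx = np.array([0.15, 0.22, 0.28, 0.33, 0.40, 0.47])
        so = np.array([0.020, 0.025, 0.030, 0.028, 0.035, 0.040])
        by = 0.03 + 0.2 * bx + np.array([1, -1, 1, -1, 1, -1]) * 3 * so
        hset = make_hset(bx, 0.01, by, so)
        res = mr_egger(hset)
        oracle = sm.WLS(by, sm.add_constant(bx), weights=so**-2).fit()
        assert res.slope.beta == pytest.approx(oracle.params[1], abs=1e-10)
        assert res.intercept == pytest.approx(oracle.params[0], abs=1e-10)
        # with Q/(k-2) > 1 the multiplicative scaling equals the WLS
        # residual-variance estimate, so SEs and t p-values match exactly
        assert np.sum(so**-2.0 * oracle.resid**2) > len(bx) - 2
        assert res.slope.se == pytest.approx(oracle.bse[1], abs=1e-10)
        assert res.intercept_se == pytest.approx(oracle.bse[0], abs=1e-10)
        assert res.intercept_pvalue == pytest.approx(oracle.pvalues[0], abs=1e-10)

    def test_orientation_flips_negative_exposure_betas(self, small_hset):
        flipped = small_hset
        flipped.pairs.loc[0, ["beta_exp", "beta_out"]] *= -1
        res_orig = mr_egger(small_hset)
        assert mr_egger(flipped).slope.beta == pytest.approx(res_orig.slope.beta)

    def test_slope_equals_ivw_when_intercept_zero(self):
        # exactly proportional data: intercept fits to 0, slope = IVW
        bx = np.array([0.1, 0.25, 0.4])
        hset = make_hset(bx, 0.01, 0.2 * bx, 0.03)
        assert mr_egger(hset).slope.beta == pytest.approx(
            ivw(hset, "fixed").beta, abs=1e-12
        )

    def test_needs_three_instruments(self):
        with pytest.raises(EstimationError, match="at least 3"):
            mr_egger(make_hset([0.1, 0.2], 0.01, [0.02, 0.04], 0.02))


def grid_scan_weighted_median(ratios, weights, rounds=6, points=10_001):
    """Brute-force oracle: scan the piecewise-linear cumulative weight
    function on a successively refined grid."""
    order = np.argsort(ratios)
    r = np.asarray(ratios, float)[order]
    p = np.asarray(weights, float)[order] / np.sum(weights)
    s = np.cumsum(p) - p / 2.0
    lo, hi = r[0], r[-1]
    for _ in range(rounds):
        grid = np.linspace(lo, hi, points)
        cum = np.interp(grid, r, s)
        i = int(np.argmin(np.abs(cum - 0.5)))
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, points - 1)]
    return (lo + hi) / 2.0


class TestWeightedMedian:
    def test_equal_weights_odd_k_is_sample_median(self):
        hset = make_hset([1.0] * 5, 0.01, [1.0, 2.0, 3.0, 4.0, 5.0], 0.1)
        est = weighted_median(hset, n_boot=50, seed=1)
        assert est.beta == pytest.approx(3.0)

    def test_dominant_weight_pulls_estimate(self):
        # > 0.5 of the weight on ratio 0 (weight = beta_exp^2 / se_out^2)
        hset = make_hset([1.0, 0.5, 0.5], 0.01, [0.0, 0.5, 1.0], 0.1)
        est = weighted_median(hset, n_boot=50, seed=1)
        assert est.beta < 0.5

    def test_matches_grid_scan_oracle(self, rng):
        for _ in range(10):
            k = 4
            bx = rng.uniform(0.1, 0.5, k)
            so = rng.uniform(0.02, 0.08, k)
            by = rng.normal(0.1 * bx, so)
            point = _weighted_median_point(by / bx, bx**2 / so**2)
            oracle = grid_scan_weighted_median(by / bx, bx**2 / so**2)
            assert point == pytest.approx(oracle, abs=1e-10)

    def test_weight_concentration_converges_to_that_ratio(self):
        ratios = np.array([0.1, 0.5, 0.9])
        weights = np.array([1.0, 1e6, 1.0])
        assert _weighted_median_point(ratios, weights) == pytest.approx(0.5, abs=1e-4)

    def test_bootstrap_reproducible_and_seed_required(self):
        hset = make_hset([0.2, 0.3, 0.4], 0.01, [0.05, 0.08, 0.11], 0.02)
        a = weighted_median(hset, n_boot=200, seed=7)
        b = weighted_median(hset, n_boot=200, seed=7)
        assert a == b
        from medimr.sumstats import InputError

        with pytest.raises(InputError, match="seed"):
            weighted_median(hset, n_boot=200)


class TestEstimateToOr:
    def test_reference_beta_rounds_to_printed_or(self):
        # log-odds -0.4352 -> protective OR 0.65; 0.2032 -> risk OR 1.23
        or1, _, _ = estimate_to_or(-0.4352, 0.2)
        or2, _, _ = estimate_to_or(0.2032, 0.1)
        assert round(or1, 2) == 0.65
        assert round(or2, 2) == 1.23

    def test_null_effect_symmetric_ci(self):
        or_, lo, hi = estimate_to_or(0.0, 0.3)
        assert or_ == 1.0
        assert lo * hi == pytest.approx(1.0)

    def test_roundtrip_and_ci_ordering(self, rng):
        for _ in range(20):
            beta, se = rng.normal(0, 1), rng.uniform(0.01, 1)
            or_, lo, hi = estimate_to_or(beta, se)
            assert np.log(or_) == pytest.approx(beta)
            assert lo < or_ < hi
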