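"""Causal estimators: Wald ratio, IVW, MR-Egger, weighted median."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

from mrmediate import (
    DegenerateInstrumentError,
    InsufficientInstrumentsError,
    ivw,
    mr_egger,
    wald_ratio,
    weighted_median,
)
from mrmediate.estimators import _weighted_median_point

from conftest import build_hset


class TestWaldRatio:
    def test_first_order_arithmetic(self):
        est = wald_ratio(0.1, 0.01, 0.05, 0.02)
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.2)

    def test_sign_carried_through_negative_exposure(self):
        assert wald_ratio(-0.1, 0.01, 0.05, 0.02).beta == pytest.approx(-0.5)

    def test_second_order_delta_method(self):
        est = wald_ratio(0.1, 0.05, 0.05, 0.02, second_order=True)
        expected = np.sqrt(0.02**2 / 0.1**2 + 0.05**2 * 0.05**2 / 0.1**4)
        assert est.se == pytest.approx(expected)
        assert est.se == pytest.approx(0.3202, abs=1e-4)

    def test_zero_exposure_effect_is_degenerate(self):
        with pytest.raises(DegenerateInstrumentError):
            wald_ratio(0.0, 0.01, 0.05, 0.02)


class TestIVW:
    def test_exactly_consistent_ratios_give_zero_q(self):
        h = build_hset([0.1, 0.2, 0.15], [0.05, 0.10, 0.075], 0.02)
        est = ivw(h, mode="auto")
        assert est.beta == pytest.approx(0.5)
        assert est.extras["q"] == pytest.approx(0.0, abs=1e-12)
        assert est.method == "ivw_fixed"  # no heterogeneity -> fixed

    def test_worked_fixture_point_and_se(self, worked_hset):
        est = ivw(worked_hset, mode="fixed")
        assert est.beta == pytest.approx(92.5 / 181.25, rel=1e-12)
        assert est.se == pytest.approx(np.sqrt(1 / 181.25), rel=1e-12)

    def test_matches_wls_through_origin_oracle(self, worked_hset):
        """IVW equals weighted least squares of beta_out on beta_exp with no
        intercept and weights 1/se_out^2."""
        res = sm.WLS(worked_hset.beta_out, worked_hset.beta_exp,
                     weights=1.0 / worked_hset.se_out**2).fit()
        est = ivw(worked_hset, mode="fixed")
        assert est.beta == pytest.approx(res.params[0], rel=1e-10)

    def test_random_effects_inflates_se_when_heterogeneous(self, worked_hset):
        fixed = ivw(worked_hset, mode="fixed")
        random = ivw(worked_hset, mode="random")
        assert random.beta == fixed.beta
        assert random.se >= fixed.se

    def test_single_pair_degenerates_to_wald(self):
        h = build_hset([0.1], [0.05], 0.02)
        est = ivw(h)
        assert est.beta == pytest.approx(0.5)
        assert est.extras.get("degenerate_single_snp")

    def test_recovers_truth_in_large_simulation(self):
        rng = np.random.default_rng(21)
        theta, J = 0.2, 5000
        bx = rng.normal(0.15, 0.03, J)
        sy = np.full(J, 0.02)
        by = theta * bx + rng.normal(0, sy)
        est = ivw(build_hset(bx, by, sy), mode="fixed")
        assert abs(est.beta - theta) < 3 * est.se

    def test_ivw_is_inverse_variance_meta_of_wald_ratios(self):
        """Algebraic identity: theta = sum(w_j r_j)/sum(w_j), w_j = bx^2/sy^2."""
        rng = np.random.default_rng(4)
        bx = rng.uniform(0.05, 0.3, 12) * rng.choice([-1, 1], 12)
        by = rng.normal(0, 0.05, 12)
        sy = rng.uniform(0.01, 0.05, 12)
        h = build_hset(bx, by, sy)
        r, w = by / bx, bx**2 / sy**2
        assert ivw(h, "fixed").beta == pytest.approx(np.sum(w * r) / np.sum(w), rel=1e-12)


class TestMREgger:
    def test_worked_equal_weight_fixture(self):
        h = build_hset([0.1, 0.2, 0.15], [0.04, 0.12, 0.06], 1.0)  # equal weights
        est = mr_egger(h)
        assert est.beta == pytest.approx(0.8, rel=1e-10)
        assert est.extras["intercept"] == pytest.approx(-0.0466667, abs=1e-6)

    def test_matches_statsmodels_wls_oracle(self, worked_hset):
        X = sm.add_constant(worked_hset.beta_exp)
        res = sm.WLS(worked_hset.beta_out, X, weights=1.0 / worked_hset.se_out**2).fit()
        est = mr_egger(worked_hset)
        assert est.beta == pytest.approx(res.params[1], rel=1e-10)
        assert est.extras["intercept"] == pytest.approx(res.params[0], rel=1e-10)

    def test_noise_free_proportional_data_gives_zero_intercept(self, proportional_hset):
        est = mr_egger(proportional_hset)
        assert est.extras["intercept"] == pytest.approx(0.0, abs=1e-12)
        assert est.beta == pytest.approx(0.5, rel=1e-10)

    def test_orients_exposure_effects_nonnegative(self):
        """Negating any pair leaves the Egger fit unchanged."""
        rng = np.random.default_rng(8)
        bx = rng.uniform(0.05, 0.3, 10)
        by = 0.3 * bx + rng.normal(0, 0.02, 10)
        h1 = build_hset(bx, by, 0.02)
        flip = rng.random(10) < 0.5
        sgn = np.where(flip, -1.0, 1.0)
        h2 = build_hset(bx * sgn, by * sgn, 0.02)
        assert mr_egger(h1).beta == pytest.approx(mr_egger(h2).beta, rel=1e-12)

    def test_too_few_pairs_raises(self):
        with pytest.raises(InsufficientInstrumentsError):
            mr_egger(build_hset([0.1, 0.2], [0.05, 0.1], 0.02))


class TestWeightedMedian:
    def test_interpolation_oracle(self):
        """Ratios (0.4, 0.4, 0.6) with weights (25, 56.25, 100): percentiles
        (6.90, 29.31, 72.41); interpolated 50th percentile = 0.496."""
        ratios = np.array([0.4, 0.4, 0.6])
        weights = np.array([25.0, 56.25, 100.0])
        assert _weighted_median_point(ratios, weights) == pytest.approx(0.496, abs=1e-4)

    def test_worked_fixture_estimate(self, worked_hset):
        est = weighted_median(worked_hset, n_boot=200, seed=0)
        assert est.beta == pytest.approx(0.496, abs=1e-4)

    def test_constant_ratios_give_exactly_that_constant(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            w = rng.uniform(1, 100, 7)
            assert _weighted_median_point(np.full(7, 0.37), w) == pytest.approx(0.37)

    def test_robust_to_minority_invalid_instruments(self):
        """60% valid instruments at theta=0.2, 40% with large directional
        pleiotropy: the weighted median stays near truth while IVW is pulled
        away (classic breakdown-below-50% behaviour, single analysis)."""
        rng = np.random.default_rng(42)
        J, theta = 50, 0.2
        bx = rng.normal(0.15, 0.02, J)
        sy = np.full(J, 0.006)
        alpha = np.zeros(J)
        invalid = np.arange(J) < 20
        alpha[invalid] = 0.06  # ~10 ratio-SE units of one-sided pleiotropy
        by = theta * bx + alpha + rng.normal(0, sy)
        h = build_hset(bx, by, sy)
        wm = weighted_median(h, n_boot=500, seed=1)
        est_ivw = ivw(h, mode="fixed")
        assert abs(wm.beta - theta) < 3 * wm.se
        assert abs(est_ivw.beta - theta) > 3 * est_ivw.se

    def test_seeded_bootstrap_reproducible(self, worked_hset):
        a = weighted_median(worked_hset, n_boot=100, seed=7)
        b = weighted_median(worked_hset, n_boot=100, seed=7)
        assert a.se == b.se


class TestSharedInvariants:
    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_joint_negation_invariance(self, seed):
        """Jointly negating (beta_exp, beta_out) of any variant leaves every
        estimator unchanged."""
        rng = np.random.default_rng(seed)
        J = 8
        bx = rng.uniform(0.05, 0.3, J)
        by = 0.25 * bx + rng.normal(0, 0.02, J)
        sy = rng.uniform(0.01, 0.04, J)
        sgn = rng.choice([-1.0, 1.0], J)
        h1, h2 = build_hset(bx, by, sy), build_hset(bx * sgn, by * sgn, sy)
        assert ivw(h1, "fixed").beta == pytest.approx(ivw(h2, "fixed").beta, rel=1e-12)
        assert mr_egger(h1).beta == pytest.approx(mr_egger(h2).beta, rel=1e-12)
        assert weighted_median(h1, 50, 0).beta == pytest.approx(
            weighted_median(h2, 50, 0).beta, rel=1e-12)

    def test_or_ci_is_monotone_exp_of_beta_ci(self, worked_hset):
        for est in (ivw(worked_hset), mr_egger(worked_hset),
                    weighted_median(worked_hset, 100, 0)):
            assert est.or_ == pytest.approx(np.exp(est.beta))
            assert est.or_low == pytest.approx(np.exp(est.ci_low))
            assert est.or_high == pytest.approx(np.exp(est.ci_high))
            assert est.ci_low <= est.beta <= est.ci_high
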