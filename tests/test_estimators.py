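"""Univariable estimators against independent oracles and printed arithmetic."""

import math

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

from tsmr.estimators import (InsufficientInstrumentsError, beta_to_or, bh_fdr,
                             egger_estimate, ivw_estimate,
                             risk_reduction_percent, wald_ratio,
                             weighted_median, weighted_median_estimate)
from tsmr.synthetic import simulate_harmonized_panel

from conftest import make_hset


class TestWaldRatio:
    def test_first_order_arithmetic(self):
        est = wald_ratio(0.1, 0.01, 0.05, 0.02)
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.2)

    def test_zero_outcome_effect(self):
        assert wald_ratio(0.1, 0.01, 0.0, 0.02).beta == 0.0

    def test_zero_exposure_effect_raises(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio(0.0, 0.01, 0.05, 0.02)

    def test_delta_orders_agree_for_strong_instruments(self, rng):
        """For a strong instrument (se_x/|β_x| < 0.1) and a Wald ratio of
        ordinary magnitude, the second-order se correction is < 5%."""
        for _ in range(50):
            bx = rng.uniform(0.05, 0.5) * rng.choice([-1, 1])
            sx = abs(bx) * rng.uniform(0.01, 0.1)
            by = 0.3 * bx
            sy = abs(bx) * rng.uniform(0.1, 0.2)
            first = wald_ratio(bx, sx, by, sy)
            second = wald_ratio(bx, sx, by, sy, second_order=True)
            assert second.se == pytest.approx(first.se, rel=0.05)
            assert second.se >= first.se


class TestIVW:
    def test_consensus_when_all_ratios_equal(self):
        bx = np.array([0.1, 0.2, 0.4])
        h = make_hset(bx, 0.01 * bx, 0.5 * bx, [0.01, 0.03, 0.02])
        assert ivw_estimate(h).beta == pytest.approx(0.5, rel=1e-12)

    def test_single_snp_degenerates_to_wald(self):
        h = make_hset([0.1], [0.01], [0.05], [0.02])
        est = ivw_estimate(h)
        wald = wald_ratio(0.1, 0.01, 0.05, 0.02)
        assert est.beta == pytest.approx(wald.beta)
        assert est.se == pytest.approx(wald.se)

    def test_matches_wls_oracle(self, rng):
        """Zero-intercept WLS via statsmodels is the independent oracle."""
        bx = rng.normal(0, 0.1, 20)
        by = 0.3 * bx + rng.normal(0, 0.01, 20)
        sy = rng.uniform(0.005, 0.02, 20)
        h = make_hset(bx, np.full(20, 0.01), by, sy)
        est = ivw_estimate(h)
        fit = sm.WLS(by, bx[:, None], weights=1.0 / sy ** 2).fit()
        assert est.beta == pytest.approx(fit.params[0], abs=1e-10)
        # multiplicative random effects: statsmodels' scale IS Q/(k-1)
        expected_se = fit.bse[0] / math.sqrt(fit.scale) * max(1.0, math.sqrt(fit.scale))
        assert est.se == pytest.approx(expected_se, abs=1e-10)

    def test_random_effects_inflation_floored_at_one(self):
        # homogeneous data -> Q/(k-1) < 1 -> fixed-effect se retained
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        h = make_hset(bx, 0.01 * bx, 0.25 * bx, np.full(4, 0.02))
        est = ivw_estimate(h)
        w = 1.0 / 0.02 ** 2
        assert est.se == pytest.approx(1.0 / math.sqrt(w * (bx ** 2).sum()), rel=1e-10)


class TestEgger:
    def test_noiseless_line_recovered_exactly(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        a, b = 0.02, -0.4
        h = make_hset(bx, 0.01 * bx, a + b * bx, np.full(4, 0.01))
        est = egger_estimate(h)
        assert est.beta == pytest.approx(b, abs=1e-12)
        assert est.egger_intercept == pytest.approx(a, abs=1e-12)

    def test_matches_free_intercept_wls_oracle(self, rng):
        bx = np.abs(rng.normal(0, 0.1, 20))
        by = 0.01 - 0.3 * bx + rng.normal(0, 0.02, 20)
        sy = rng.uniform(0.005, 0.02, 20)
        h = make_hset(bx, np.full(20, 0.01), by, sy)
        est = egger_estimate(h)
        X = sm.add_constant(bx)
        fit = sm.WLS(by, X, weights=1.0 / sy ** 2).fit()
        assert est.beta == pytest.approx(fit.params[1], abs=1e-10)
        assert est.egger_intercept == pytest.approx(fit.params[0], abs=1e-10)
        infl = max(1.0, math.sqrt(fit.scale)) / math.sqrt(fit.scale)
        assert est.se == pytest.approx(fit.bse[1] * infl, abs=1e-10)

    def test_orientation_invariant_to_exposure_coding(self, rng):
        bx = rng.normal(0, 0.1, 10)
        by = 0.01 - 0.3 * bx + rng.normal(0, 0.01, 10)
        h1 = make_hset(bx, np.full(10, 0.01), by, np.full(10, 0.01))
        h2 = make_hset(-bx, np.full(10, 0.01), -by, np.full(10, 0.01))
        e1, e2 = egger_estimate(h1), egger_estimate(h2)
        assert e1.beta == pytest.approx(e2.beta, rel=1e-12)
        assert e1.egger_intercept == pytest.approx(e2.egger_intercept, rel=1e-12)

    def test_too_few_instruments_raises(self):
        h = make_hset([0.1, 0.2], [0.01, 0.01], [0.05, 0.1], [0.01, 0.01])
        with pytest.raises(InsufficientInstrumentsError):
            egger_estimate(h)


class TestWeightedMedian:
    def test_odd_count_equal_weights(self):
        h = make_hset([1.0, 1.0, 1.0], [0.01] * 3, [0.1, 0.2, 0.9], [0.05] * 3)
        est = weighted_median_estimate(h, n_boot=100, seed=0)
        assert est.beta == pytest.approx(0.2)

    def test_interpolation_matches_brute_force_cdf_scan(self, rng):
        """Oracle: dense scan of the weighted empirical CDF."""
        values = rng.normal(0, 1, 15)
        weights = rng.uniform(0.1, 2.0, 15)
        result = weighted_median(values, weights)
        order = np.argsort(values)
        v, w = values[order], weights[order]
        cum = (np.cumsum(w) - 0.5 * w) / w.sum()
        grid = np.linspace(v[0], v[-1], 200_001)
        cdf_on_grid = np.interp(grid, v, cum)
        oracle = grid[np.argmin(np.abs(cdf_on_grid - 0.5))]
        assert result == pytest.approx(oracle, abs=1e-4)

    def test_robust_to_single_wild_outlier(self):
        h, _ = simulate_harmonized_panel(10, theta=0.3, seed=5)
        concordant = weighted_median_estimate(h, n_boot=200, seed=0)
        h.df.loc[3, "beta_y"] += 50 * h.df.loc[3, "se_y"]
        est = weighted_median_estimate(h, n_boot=200, seed=0)
        assert abs(est.beta - concordant.beta) <= 2 * est.se

    def test_bootstrap_se_reproducible_under_seed(self):
        h, _ = simulate_harmonized_panel(10, theta=0.3, seed=5)
        a = weighted_median_estimate(h, n_boot=300, seed=9)
        b = weighted_median_estimate(h, n_boot=300, seed=9)
        assert a.se == b.se


class TestTransforms:
    @pytest.mark.parametrize("beta,expected_or", [
        (-0.582, 0.559),   # direct effect adjusted for TG
        (-0.887, 0.412),   # adjusted for HDL-C
        (-0.598, 0.550),   # adjusted for LDL-C
        (0.0, 1.0),
    ])
    def test_log_odds_to_odds_ratio(self, beta, expected_or):
        or_, _ = beta_to_or(beta)
        assert round(or_, 3) == expected_or

    def test_or_ci_uses_normal_bounds(self):
        or_, (lo, hi) = beta_to_or(-0.5, 0.1)
        assert lo == pytest.approx(math.exp(-0.5 - 1.96 * 0.1))
        assert hi == pytest.approx(math.exp(-0.5 + 1.96 * 0.1))

    @pytest.mark.parametrize("or_,expected", [
        (0.614, 38.6),
        (1.0, 0.0),
        (0.5, 50.0),
    ])
    def test_risk_reduction_percent(self, or_, expected):
        assert round(risk_reduction_percent(or_), 1) == expected


class TestFdr:
    def test_rank_one_of_three_scales_by_family_size(self):
        adj = bh_fdr([1.24e-6, 0.692, 0.9])
        assert adj[0] == pytest.approx(3.72e-6)

    def test_equal_pvalues_share_adjusted_value(self):
        adj = bh_fdr([0.02, 0.02, 0.02])
        assert np.allclose(adj, adj[0])

    def test_matches_reference_step_up_on_random_vectors(self, rng):
        for _ in range(100):
            p = rng.uniform(1e-8, 1.0, size=rng.integers(1, 40))
            _, ref, _, _ = multipletests(p, method="fdr_bh")
            assert np.allclose(bh_fdr(p), ref, atol=1e-12)

    def test_out_of_domain_pvalues_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 0.0])


class TestEstimatorProperties:
    def test_sign_equivariance_under_exposure_recoding(self):
        """Recoding the exposure's sign flips every estimator's beta exactly."""
        h, _ = simulate_harmonized_panel(30, theta=-0.4, seed=17)
        flipped = make_hset(-h.df["beta_x"].to_numpy(), h.df["se_x"].to_numpy(),
                            h.df["beta_y"].to_numpy(), h.df["se_y"].to_numpy())
        assert ivw_estimate(flipped).beta == pytest.approx(-ivw_estimate(h).beta,
                                                           rel=1e-12)
        assert egger_estimate(flipped).beta == pytest.approx(
            -egger_estimate(h).beta, rel=1e-12)
        wm_f = weighted_median_estimate(flipped, n_boot=100, seed=0)
        wm = weighted_median_estimate(h, n_boot=100, seed=0)
        assert wm_f.beta == pytest.approx(-wm.beta, rel=1e-12)

    def test_estimators_agree_without_pleiotropy(self):
        h, truth = simulate_harmonized_panel(100, theta=-0.488, seed=23)
        ivw = ivw_estimate(h)
        egger = egger_estimate(h)
        wm = weighted_median_estimate(h, n_boot=300, seed=0)
        for est in (ivw, egger, wm):
            assert abs(est.beta - truth.theta) <= 3 * est.se

    @given(st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None)
    def test_ci_and_or_invariants(self, seed):
        h, _ = simulate_harmonized_panel(10, theta=0.1, seed=seed)
        est = ivw_estimate(h)
        assert est.ci_low == pytest.approx(est.beta - 1.96 * est.se, abs=1e-10)
        assert est.ci_high == pytest.approx(est.beta + 1.96 * est.se, abs=1e-10)
        assert est.or_ == pytest.approx(math.exp(est.beta))
        assert est.or_ci[0] < est.or_ < est.or_ci[1]
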