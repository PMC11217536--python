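import math

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from mrscreen import (egger, ivw, max_likelihood, to_odds_ratio, wald_ratio,
                      weighted_median)
from mrscreen.errors import (DegenerateInstrumentError,
                             InsufficientInstrumentsError)
from helpers import make_hset, sim_hset


class TestWaldRatio:
    def test_hand_arithmetic(self):
        est = wald_ratio(bx=0.2, sx=0.02, by=0.05, sy=0.02)
        assert est.beta == pytest.approx(0.25)
        assert est.se == pytest.approx(0.1)

    def test_sign_propagation(self):
        est = wald_ratio(bx=-0.2, sx=0.02, by=0.05, sy=0.02)
        assert est.beta == pytest.approx(-0.25)
        assert est.se == pytest.approx(0.1)

    def test_null_outcome_effect(self):
        est = wald_ratio(bx=0.2, sx=0.02, by=0.0, sy=0.02)
        assert est.beta == 0.0
        assert est.or_value == 1.0

    def test_zero_exposure_effect_rejected(self):
        with pytest.raises(DegenerateInstrumentError):
            wald_ratio(bx=0.0, sx=0.02, by=0.05, sy=0.02)


class TestOddsRatioConversion:
    def test_null_beta_symmetric_log_bounds(self):
        or_value, lo, hi = to_odds_ratio(0.0, 0.1)
        assert or_value == 1.0
        assert lo < 1.0 < hi
        assert lo * hi == pytest.approx(1.0)

    def test_vanishing_uncertainty_collapses_to_point(self):
        or_value, lo, hi = to_odds_ratio(math.log(2), 1e-12)
        assert or_value == pytest.approx(2.0)
        assert lo == pytest.approx(2.0)
        assert hi == pytest.approx(2.0)

    def test_hand_arithmetic_95(self):
        or_value, lo, hi = to_odds_ratio(0.4574, 0.1938, level=0.95)
        z = 1.959964
        assert or_value == pytest.approx(math.exp(0.4574), rel=1e-12)
        assert lo == pytest.approx(math.exp(0.4574 - z * 0.1938), rel=1e-6)
        assert hi == pytest.approx(math.exp(0.4574 + z * 0.1938), rel=1e-6)


def random_hset(rng, J):
    bx = rng.uniform(0.05, 0.3, J) * rng.choice([-1, 1], J)
    return make_hset(bx, rng.uniform(0.005, 0.03, J),
                     0.3 * bx + rng.normal(0, 0.02, J), rng.uniform(0.01, 0.06, J))


class TestIVW:
    def test_single_instrument_reduces_to_wald(self):
        h = make_hset([0.2], [0.02], [0.05], [0.03])
        with pytest.warns(UserWarning):
            est = ivw(h)
        wald = wald_ratio(0.2, 0.02, 0.05, 0.03)
        assert est.beta == wald.beta
        assert est.se == wald.se

    def test_equals_wls_through_origin(self):
        rng = np.random.default_rng(11)
        h = random_hset(rng, 3)
        est = ivw(h, model="fixed")
        wls = sm.WLS(h.beta_outcome, h.beta_exposure, weights=1 / h.se_outcome ** 2).fit()
        assert est.beta == pytest.approx(wls.params[0], abs=1e-10)

    def test_auto_switches_to_random_on_heterogeneity(self):
        # wildly inconsistent ratios -> Q significant -> random effects, larger SE
        h = make_hset([0.2, 0.2, 0.2, 0.2], [0.01] * 4,
                      [0.0, 0.1, -0.1, 0.3], [0.01] * 4)
        est_auto = ivw(h, model="auto")
        est_fixed = ivw(h, model="fixed")
        assert est_auto.method == "ivw_random"
        assert est_auto.model_selected == "random"
        assert est_auto.se > est_fixed.se
        assert est_auto.beta == est_fixed.beta

    def test_auto_stays_fixed_under_homogeneity(self):
        h, _ = sim_hset(n_snps=20, theta=0.3, seed=21)
        assert ivw(h, model="auto").model_selected == "fixed"

    def test_empty_set_rejected(self):
        with pytest.raises(InsufficientInstrumentsError):
            ivw(make_hset([], [], [], []))


class TestEgger:
    def test_insufficient_instruments(self):
        h = make_hset([0.1, 0.2], [0.01] * 2, [0.05, 0.1], [0.02] * 2)
        with pytest.raises(InsufficientInstrumentsError):
            egger(h)

    def test_collinear_data_recovered_exactly(self):
        bx = np.array([0.1, 0.2, 0.3, 0.15])
        h = make_hset(bx, [0.01] * 4, 0.5 * bx, [0.02] * 4)
        slope, intercept = egger(h)
        assert slope.beta == pytest.approx(0.5, abs=1e-12)
        assert intercept.beta == pytest.approx(0.0, abs=1e-12)

    def test_equals_wls_with_intercept_after_orientation(self):
        rng = np.random.default_rng(13)
        h = random_hset(rng, 12)
        slope, intercept = egger(h)
        sign = np.where(h.beta_exposure < 0, -1.0, 1.0)
        bx, by = sign * h.beta_exposure, sign * h.beta_outcome
        X = sm.add_constant(bx)
        wls = sm.WLS(by, X, weights=1 / h.se_outcome ** 2).fit()
        assert intercept.beta == pytest.approx(wls.params[0], abs=1e-10)
        assert slope.beta == pytest.approx(wls.params[1], abs=1e-10)

    def test_directional_pleiotropy_intercept_recovery(self):
        # every instrument pleiotropic, InSIDE holding, no causal effect:
        # the intercept is a consistent estimate of the mean direct effect
        # (at theta != 0 a residual slope-attenuation bias ~ theta*(1-lambda)*
        # mean(beta_X) from exposure-side measurement error would leak in)
        intercepts = []
        for rep in range(500):
            h, _ = sim_hset(n_snps=50, theta=0.0, prop_invalid=1.0,
                            alpha_mean=0.02, alpha_sd=0.005, seed=10_000 + rep)
            intercepts.append(egger(h)[1].beta)
        assert np.mean(intercepts) == pytest.approx(0.02, abs=0.002)


class TestWeightedMedian:
    def test_equal_weights_interpolates_middle_ratio(self):
        h = make_hset([1.0, 1.0, 1.0], [0.01] * 3, [0.1, 0.2, 0.3], [0.02] * 3)
        est = weighted_median(h, n_boot=100, seed=0)
        assert est.beta == pytest.approx(0.2)

    def test_degenerate_spread_returns_common_ratio(self):
        bx = np.array([0.1, 0.2, 0.3])
        h = make_hset(bx, [1e-6] * 3, 0.7 * bx, [1e-6] * 3)
        est = weighted_median(h, n_boot=200, seed=0)
        assert est.beta == pytest.approx(0.7)
        assert est.se < 1e-4

    def test_insufficient_instruments(self):
        h = make_hset([0.1], [0.01], [0.05], [0.02])
        with pytest.raises(InsufficientInstrumentsError):
            weighted_median(h, n_boot=10, seed=0)

    def test_single_instrument_reduction_with_gate_lifted(self):
        h = make_hset([0.2], [0.02], [0.05], [0.03])
        est = weighted_median(h, n_boot=50, seed=0, _min_snp=1)
        assert est.beta == pytest.approx(wald_ratio(0.2, 0.02, 0.05, 0.03).beta)

    def test_bootstrap_se_is_seed_deterministic(self):
        h, _ = sim_hset(n_snps=15, theta=0.2, seed=33)
        a = weighted_median(h, n_boot=300, seed=7)
        b = weighted_median(h, n_boot=300, seed=7)
        assert a.se == b.se


class TestMaxLikelihood:
    def test_single_instrument_matches_wald(self):
        h = make_hset([0.2], [0.02], [0.05], [0.03])
        est = max_likelihood(h)
        assert est.beta == pytest.approx(0.25, abs=1e-6)

    def test_no_measurement_error_limit_matches_ivw(self):
        h, _ = sim_hset(n_snps=20, theta=0.4, seed=17)
        h.se_exposure = h.se_outcome * 1e-8
        est = max_likelihood(h)
        fixed = ivw(h, model="fixed")
        assert est.beta == pytest.approx(fixed.beta, abs=1e-4)
        assert est.se == pytest.approx(fixed.se, rel=1e-3)


class TestSharedProperties:
    @pytest.mark.parametrize("c", [0.5, 2.0, 10.0])
    def test_outcome_scale_equivariance(self, c):
        h, _ = sim_hset(n_snps=12, theta=0.3, seed=19)
        scaled = make_hset(h.beta_exposure, h.se_exposure,
                           c * h.beta_outcome, c * h.se_outcome)
        for fn in (lambda s: ivw(s, model="fixed"),
                   lambda s: egger(s)[0],
                   lambda s: weighted_median(s, n_boot=100, seed=3),
                   max_likelihood):
            base, scl = fn(h), fn(scaled)
            assert scl.beta == pytest.approx(c * base.beta, rel=1e-6)
            assert scl.se == pytest.approx(c * base.se, rel=1e-2)

    def test_orientation_invariance_under_joint_sign_flip(self):
        h, _ = sim_hset(n_snps=12, theta=0.3, seed=23)
        sign = np.where(np.arange(12) % 3 == 0, -1.0, 1.0)
        flipped = make_hset(sign * h.beta_exposure, h.se_exposure,
                            sign * h.beta_outcome, h.se_outcome)
        for fn in (lambda s: ivw(s, model="fixed"),
                   lambda s: egger(s)[0],
                   lambda s: weighted_median(s, n_boot=100, seed=3),
                   max_likelihood):
            assert fn(flipped).beta == pytest.approx(fn(h).beta, rel=1e-8)

    def test_ci_brackets_or_and_or_is_exp_beta(self):
        h, _ = sim_hset(n_snps=10, theta=0.2, seed=29)
        for est in (ivw(h), egger(h)[0], weighted_median(h, n_boot=100, seed=1),
                    max_likelihood(h)):
            assert est.ci_low < est.or_value < est.ci_high
            assert est.or_value == pytest.approx(math.exp(est.beta), rel=1e-12)
            assert 0 < est.pvalue <= 1

    def test_ivw_coverage_under_valid_instruments(self):
        # 95% CI coverage of the true effect under the valid-instrument model
        z = stats.norm.ppf(0.975)
        covered = 0
        reps = 1000
        for rep in range(reps):
            h, truth = sim_hset(n_snps=30, theta=0.3, seed=50_000 + rep)
            est = ivw(h, model="auto")
            if abs(est.beta - truth.theta) <= z * est.se:
                covered += 1
        assert 0.93 <= covered / reps <= 0.97
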