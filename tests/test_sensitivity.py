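import numpy as np
import pytest

from mrscreen import (cochran_q, egger, ivw, leave_one_out, mr_presso,
                      plot_data, wald_ratio)
from mrscreen.errors import InsufficientInstrumentsError
from mrscreen.sensitivity import observed_rss, render_plots
from helpers import make_hset, sim_hset


class TestCochranQ:
    def test_homogeneous_ratios_give_zero_q(self):
        bx = np.array([0.1, 0.2, 0.4])
        h = make_hset(bx, [0.01] * 3, 0.5 * bx, [0.02] * 3)
        res = cochran_q(h)
        assert res.q_statistic == pytest.approx(0.0, abs=1e-12)
        assert res.pvalue == pytest.approx(1.0)
        assert res.model_selected == "fixed"

    def test_two_snp_hand_arithmetic(self):
        # unit weights (bx=1, sy=1), ratios 0 and 1 -> pooled 0.5, Q = 0.5
        h = make_hset([1.0, 1.0], [0.01] * 2, [0.0, 1.0], [1.0, 1.0])
        res = cochran_q(h)
        assert res.q_statistic == pytest.approx(0.5)
        assert res.df == 1

    def test_single_instrument_rejected(self):
        h = make_hset([0.1], [0.01], [0.05], [0.02])
        with pytest.raises(InsufficientInstrumentsError):
            cochran_q(h)

    def test_decomposition_identity(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            J = rng.integers(2, 15)
            h = make_hset(rng.uniform(0.05, 0.3, J), rng.uniform(0.005, 0.02, J),
                          rng.normal(0, 0.05, J), rng.uniform(0.01, 0.05, J))
            ratios = h.beta_outcome / h.beta_exposure
            w = h.beta_exposure ** 2 / h.se_outcome ** 2
            direct = cochran_q(h).q_statistic
            expanded = np.sum(w * ratios ** 2) - np.sum(w * ratios) ** 2 / np.sum(w)
            assert direct == pytest.approx(expanded, abs=1e-10 * max(1, direct))

    def test_null_distribution_matches_chi_square_moment(self):
        # under valid instruments Q ~ chi2(J-1); its mean should sit at J-1
        qs = [cochran_q(sim_hset(n_snps=10, theta=0.2, seed=70_000 + rep)[0]).q_statistic
              for rep in range(2000)]
        assert np.mean(qs) == pytest.approx(9.0, rel=0.05)

    def test_random_model_selected_under_heterogeneity(self):
        h = make_hset([0.2] * 4, [0.01] * 4, [0.0, 0.1, -0.1, 0.3], [0.01] * 4)
        assert cochran_q(h).model_selected == "random"


class TestMRPresso:
    def _outlier_hset(self, seed=1, theta=0.3, J=20):
        h, truth = sim_hset(n_snps=J, theta=theta, seed=seed)
        j = 7
        h.beta_outcome[j] += 10.0 * h.se_outcome[j]
        return h, truth, j

    def test_requires_four_instruments_and_enough_simulations(self):
        h, _ = sim_hset(n_snps=3, seed=0)
        with pytest.raises(InsufficientInstrumentsError):
            mr_presso(h, n_simulations=100, seed=0)
        h4, _ = sim_hset(n_snps=4, seed=0)
        with pytest.raises(ValueError):
            mr_presso(h4, n_simulations=10, seed=0)

    def test_identical_seed_gives_identical_result(self):
        h, _, _ = self._outlier_hset()
        a = mr_presso(h, n_simulations=300, seed=11)
        b = mr_presso(h, n_simulations=300, seed=11)
        assert a.global_pvalue == b.global_pvalue
        assert a.outlier_indices == b.outlier_indices
        np.testing.assert_array_equal(a.outlier_pvalues, b.outlier_pvalues)
        assert a.distortion_pvalue == b.distortion_pvalue
        assert a.estimate_corrected.beta == b.estimate_corrected.beta

    def test_planted_gross_outlier_flagged_and_correction_helps(self):
        h, truth, j = self._outlier_hset(seed=2)
        res = mr_presso(h, n_simulations=1000, seed=3)
        assert j in res.outlier_indices
        assert res.global_pvalue < 0.05
        assert res.distortion_pvalue is not None
        assert (abs(res.estimate_corrected.beta - truth.theta)
                < abs(res.estimate_raw.beta - truth.theta))
        assert res.estimate_corrected.n_snp == 20 - len(res.outlier_indices)

    def test_clean_data_rarely_rejects_and_keeps_raw_estimate(self):
        h, _ = sim_hset(n_snps=20, theta=0.0, seed=8)
        res = mr_presso(h, n_simulations=1000, seed=9)
        assert res.outlier_indices == set()
        assert res.distortion_pvalue is None
        assert res.estimate_corrected.beta == res.estimate_raw.beta

    def test_global_pvalue_bounded_below_by_monte_carlo_floor(self):
        h, _, _ = self._outlier_hset(seed=4)
        res = mr_presso(h, n_simulations=200, seed=5)
        assert res.global_pvalue >= 1 / 201

    def test_null_global_rejection_rate_calibrated(self):
        # empirical size of the global RSS test under no pleiotropy
        rejections = 0
        reps = 500
        for rep in range(reps):
            h, _ = sim_hset(n_snps=20, theta=0.0, seed=90_000 + rep)
            res = mr_presso(h, n_simulations=1000, seed=rep)
            rejections += res.global_pvalue < 0.05
        assert 0.02 <= rejections / reps <= 0.08

    def test_removing_flagged_outlier_reduces_observed_rss(self):
        for seed in range(5):
            h, _, _ = self._outlier_hset(seed=100 + seed)
            res = mr_presso(h, n_simulations=300, seed=seed)
            if not res.outlier_indices:
                continue
            keep = sorted(set(range(h.n_snp)) - res.outlier_indices)
            assert observed_rss(h.subset(keep)) < observed_rss(h)


class TestPlotData:
    def test_empty_set_gives_empty_tables(self):
        h = make_hset([], [], [], [])
        data = plot_data(h, [])
        assert len(data.scatter) == 0
        assert len(data.funnel) == 0
        assert data.pooled is None

    def test_origin_line_for_ivw(self):
        h, _ = sim_hset(n_snps=5, theta=0.5, seed=41)
        est = ivw(h, model="fixed")
        data = plot_data(h, [est])
        line = data.lines.iloc[0]
        assert line["slope"] == est.beta
        assert line["intercept"] == 0.0
        assert data.pooled == est.beta

    def test_egger_line_uses_its_intercept(self):
        h, _ = sim_hset(n_snps=8, theta=0.5, seed=43)
        slope, intercept = egger(h)
        data = plot_data(h, [slope, intercept])
        line = data.lines[data.lines["method"] == "egger_slope"].iloc[0]
        assert line["intercept"] == intercept.beta
        assert "egger_intercept" not in set(data.lines["method"])

    def test_funnel_ratios_equal_wald_betas_elementwise(self):
        h, _ = sim_hset(n_snps=6, theta=0.2, seed=47)
        data = plot_data(h, [ivw(h)])
        expected = [wald_ratio(bx, sx, by, sy).beta
                    for bx, sx, by, sy in zip(h.beta_exposure, h.se_exposure,
                                              h.beta_outcome, h.se_outcome)]
        np.testing.assert_allclose(data.funnel["ratio"], expected)

    def test_render_plots_writes_files(self, tmp_path):
        h, _ = sim_hset(n_snps=6, theta=0.2, seed=47)
        data = plot_data(h, [ivw(h)])
        paths = render_plots(data, str(tmp_path / "demo"))
        assert all(p.endswith(".png") for p in paths)
        import os
        assert all(os.path.getsize(p) > 0 for p in paths)


class TestLeaveOneOut:
    def test_one_row_per_excluded_instrument(self):
        h, _ = sim_hset(n_snps=6, theta=0.3, seed=53)
        loo = leave_one_out(h)
        assert len(loo) == 6
        assert set(loo["excluded"]) == set(h.variant_ids)
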