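"""Critical-ratio extraction, threshold curve fits and the recommendation rule."""

import numpy as np
import pytest

from richsplit import (
    AbundanceSample,
    ThresholdModel,
    critical_ratio,
    estimate_cv_from_sample,
    fit_poly_N,
    fit_power_law,
    recommend,
)


def _model(pair, a, b):
    return ThresholdModel(pair, "mid", (1e3, 1e5), a, b, fit_points=((0.5, a * 0.5**b),))


class TestCriticalRatio:
    def test_constructed_crossing_point(self, rng):
        # differences are negative exactly above n/s = 30
        ratios = rng.uniform(5, 60, size=400)
        diffs = np.where(ratios > 30, -1.0, 1.0)
        cr = critical_ratio(ratios, diffs, "mid", n_bins=10)
        assert cr.crossed
        assert cr.value == pytest.approx(30, abs=60 / 10)  # within one bin width

    def test_all_negative_gives_lowest_bin(self, rng):
        ratios = rng.uniform(5, 60, size=200)
        cr = critical_ratio(ratios, -np.ones(200), "mid")
        assert cr.crossed
        assert cr.value <= np.quantile(ratios, 0.1)

    def test_all_positive_no_crossing(self, rng):
        ratios = rng.uniform(5, 60, size=200)
        cr = critical_ratio(ratios, np.ones(200), "mid")
        assert not cr.crossed
        assert np.isnan(cr.value)

    def test_edge_criterion_stricter_than_mid(self, rng):
        ratios = rng.uniform(0, 100, size=2000)
        # fraction of negatives grows smoothly with the ratio
        p_neg = np.clip(ratios / 100, 0, 1)
        diffs = np.where(rng.random(2000) < p_neg, -1.0, 1.0)
        mid = critical_ratio(ratios, diffs, "mid")
        edge = critical_ratio(ratios, diffs, "edge")
        if mid.crossed and edge.crossed:
            assert edge.value >= mid.value

    def test_minimum_points_enforced(self):
        with pytest.raises(ValueError):
            critical_ratio([1.0] * 10, [1.0] * 10)


class TestPowerLawFit:
    def test_noiseless_recovery_is_exact(self):
        cvs = np.array([0.25, 0.35, 0.45, 0.55, 0.65, 0.75, 0.85, 0.95, 1.05, 1.15])
        ratios = 80.10 * cvs**2.05
        a, b, resid = fit_power_law(cvs, ratios)
        assert a == pytest.approx(80.10, abs=1e-6)
        assert b == pytest.approx(2.05, abs=1e-6)
        assert resid < 1e-6

    def test_flat_points_give_zero_exponent(self):
        cvs = np.array([0.3, 0.5, 0.7, 0.9])
        a, b, _ = fit_power_law(cvs, np.full(4, 12.0))
        assert a == pytest.approx(12.0, abs=1e-8)
        assert b == pytest.approx(0.0, abs=1e-8)

    def test_matches_grid_search_oracle(self):
        cvs = np.array([0.3, 0.5, 0.8, 1.1])
        ratios = 29.22 * cvs**3.16
        a_grid = np.linspace(20, 40, 201)
        b_grid = np.linspace(2, 4, 201)
        sse = np.array(
            [
                [np.sum((ratios - a * cvs**b) ** 2) for b in b_grid]
                for a in a_grid
            ]
        )
        ia, ib = np.unravel_index(np.argmin(sse), sse.shape)
        a, b, _ = fit_power_law(cvs, ratios)
        assert a == pytest.approx(a_grid[ia], abs=0.1)
        assert b == pytest.approx(b_grid[ib], abs=0.01)

    def test_noisy_recovery_within_stochastic_band(self):
        """+/-10% multiplicative noise: a within 15%, b within 0.3.

        The bands are ~3 sigma for this noise level, so they are asserted on
        the 95th percentile over 100 seeded trials rather than the worst case.
        """
        rng = np.random.default_rng(5)
        cvs = np.array([0.25, 0.35, 0.45, 0.55, 0.65, 0.75, 0.85, 0.95, 1.05, 1.15])
        err_a, err_b = [], []
        for _ in range(100):
            noisy = 80.10 * cvs**2.05 * rng.uniform(0.9, 1.1, size=cvs.size)
            a, b, _ = fit_power_law(cvs, noisy)
            err_a.append(abs(a - 80.10) / 80.10)
            err_b.append(abs(b - 2.05))
        assert np.quantile(err_a, 0.95) < 0.15
        assert np.quantile(err_b, 0.95) < 0.3

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_power_law([0.5, 1.0], [10.0, 20.0])


class TestPolyFit:
    def test_exact_cubic_interpolation(self):
        coef_true = np.array([2e-12, -3e-8, 4e-4, 7.0])
        Ns = np.array([1e3, 1e4, 5e4, 1e5])
        ratios = np.polyval(coef_true, Ns)
        np.testing.assert_allclose(fit_poly_N(Ns, ratios), coef_true, rtol=1e-6)

    def test_constant_points(self):
        Ns = np.array([1e3, 2e3, 5e3, 1e4, 2e4])
        coef = fit_poly_N(Ns, np.full(5, 9.0))
        assert coef[3] == pytest.approx(9.0, abs=1e-6)
        np.testing.assert_allclose(coef[:3], 0.0, atol=1e-9)

    def test_matches_normal_equations(self, rng):
        # moderate-scale N keeps the raw normal equations well conditioned,
        # so the direct linear-algebra solution is a trustworthy oracle
        Ns = rng.uniform(1.0, 10.0, size=30)
        ratios = rng.uniform(10, 80, size=30)
        vander = np.vander(Ns, 4)
        beta = np.linalg.solve(vander.T @ vander, vander.T @ ratios)
        np.testing.assert_allclose(fit_poly_N(Ns, ratios), beta, rtol=1e-9)

    def test_rank_deficiency(self):
        with pytest.raises(np.linalg.LinAlgError):
            fit_poly_N([1e3, 1e3, 1e3, 1e3], [1.0, 2.0, 3.0, 4.0])


class TestRecommendationRule:
    chao = _model("chao2_vs_chao1", 80.10, 2.05)
    jk = _model("jk_i_vs_jk1a", 29.22, 3.16)

    def test_high_cv_above_threshold_splits_with_jackknife(self):
        rec = recommend(n=5000, s_obs=20, N_hat=5e4, cv_hat=0.95,
                        chao_model=self.chao, jk_model=self.jk)
        assert rec.estimator_id == "jk1i"
        assert rec.use_splitting and rec.k == 2
        assert rec.branch == "jackknife"

    def test_low_cv_above_threshold_splits_with_chao2(self):
        rec = recommend(n=5000, s_obs=20, N_hat=5e4, cv_hat=0.35,
                        chao_model=self.chao, jk_model=self.jk)
        assert rec.estimator_id == "chao2_bc"
        assert rec.use_splitting

    def test_below_threshold_stays_with_abundance_estimator(self):
        rec = recommend(n=300, s_obs=100, N_hat=5e4, cv_hat=0.95,
                        chao_model=self.chao, jk_model=self.jk)
        assert rec.estimator_id == "jk1a"
        assert not rec.use_splitting
        rec_lo = recommend(n=300, s_obs=100, N_hat=5e4, cv_hat=0.35,
                           chao_model=self.chao, jk_model=self.jk)
        assert rec_lo.estimator_id == "chao1_bc"

    def test_boundary_cv_ties_to_chao_branch(self):
        with pytest.warns(RuntimeWarning, match="boundary"):
            rec = recommend(n=5000, s_obs=20, N_hat=5e4, cv_hat=0.65,
                            chao_model=self.chao, jk_model=self.jk)
        assert rec.branch == "chao"
        assert rec.note

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            recommend(0, 10, 1e4, 0.5, self.chao, self.jk)


class TestCVEstimation:
    def test_even_counts_give_zero(self):
        assert estimate_cv_from_sample(AbundanceSample({"a": 4, "b": 4, "c": 4})) == 0.0

    def test_hand_arithmetic(self):
        # counts {1, 3}: mean 2, population sd 1
        assert estimate_cv_from_sample(AbundanceSample({"a": 1, "b": 3})) == pytest.approx(0.5)

    def test_requires_two_species(self):
        with pytest.raises(ValueError):
            estimate_cv_from_sample(AbundanceSample({"a": 5}))

    def test_tracks_true_cv_over_grid(self):
        """cv_hat rank-correlates with the generating cv on large samples."""
        from scipy.stats import spearmanr

        from richsplit import SADParams, catch_probabilities, draw_sample

        rng = np.random.default_rng(3)
        true_cvs = np.repeat([0.15, 0.35, 0.55, 0.75, 0.95, 1.15], 5)
        hats = []
        for cv in true_cvs:
            asm = catch_probabilities(SADParams.create("lognormal", 30, 500.0, cv))
            hats.append(estimate_cv_from_sample(draw_sample(asm, 3000, rng)))
        rho, _ = spearmanr(true_cvs, hats)
        assert rho > 0.8


class TestThresholdModelIO:
    def test_text_round_trip(self, tmp_path):
        model = ThresholdModel(
            "jk_i_vs_jk1a", "mid", (1e3, 1e5), 29.22, 3.16,
            fit_points=((0.75, 29.22 * 0.75**3.16), (0.95, 29.22 * 0.95**3.16)),
            poly_N=(1e-12, -2e-8, 3e-4, 5.0),
        )
        path = tmp_path / "model.txt"
        model.to_text(path)
        back = ThresholdModel.from_text(path)
        assert back == model

    def test_prediction_monotone_in_cv(self):
        model = _model("jk_i_vs_jk1a", 29.22, 3.16)
        cvs = np.linspace(0.2, 1.2, 20)
        preds = [model.predict(c) for c in cvs]
        assert np.all(np.diff(preds) > 0)

    def test_invalid_model_rejected(self):
        with pytest.raises(ValueError):
            ThresholdModel("nope", "mid", (1, 2), 1.0, 1.0, ((0.5, 1.0),))
        with pytest.raises(ValueError):
            ThresholdModel("jk_i_vs_jk1a", "mid", (1, 2), -1.0, 1.0, ((0.5, 1.0),))
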