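"""Stage linearization and the CDD ~ stage model family."""

import numpy as np
import pandas as pd
import pytest

from vinedev.inference_core import MCMCConfig
from vinedev.phenology import (
    BEGIN_FLOWERING_LINEAR,
    STAGE_LINEARIZATION,
    UnmappedStageError,
    attach_cdd,
    fit_phenology_bayes,
    fit_phenology_reml,
    linearize_stage,
    predict_stage_calendar,
    predict_stage_cdd,
)
from vinedev.thermal_time import DevelopmentCalendar


class TestLinearization:
    def test_reference_stages(self):
        assert linearize_stage(4) == 4.00
        assert linearize_stage(7) == 6.5
        assert linearize_stage(5) == 5.00
        assert linearize_stage(18) == 19.5
        assert BEGIN_FLOWERING_LINEAR == 21.5

    def test_strictly_increasing_in_stage_order(self):
        stages = sorted(STAGE_LINEARIZATION)
        values = [STAGE_LINEARIZATION[s] for s in stages]
        assert all(a < b for a, b in zip(values, values[1:]))

    @pytest.mark.parametrize("stage", [6, 8, 10, 0, 19])
    def test_unmapped_stage_is_domain_error(self, stage):
        with pytest.raises(UnmappedStageError):
            linearize_stage(stage)


def _degenerate_posterior(intercept, slope, sigma=1e-9, likelihood="gaussian",
                          beta_exg=None):
    """Posterior with all draws at fixed values, for closed-form checks."""
    from vinedev.inference_core import PosteriorSamples
    from vinedev.phenology import PhenologyPosterior

    n = 200
    params = {"intercept": np.full((1, n), float(intercept)),
              "el_linear": np.full((1, n), float(slope)),
              "sigma": np.full((1, n), float(sigma))}
    if beta_exg is not None:
        params["beta_exg"] = np.full((1, n), float(beta_exg))
    return PhenologyPosterior(
        variant="final" if beta_exg is None else "final-exgaussian",
        likelihood=likelihood, trt_levels=("aCO2", "eCO2"),
        year_levels=(2018, 2019),
        draws=PosteriorSamples(params, 1, n))


class TestPredictStageCdd:
    def test_budburst_threshold_from_reported_coefficients(self):
        # intercept 2.7789 + 4 x 1.2577 = 7.8097 ~ 7.8 CDD for budburst
        post = _degenerate_posterior(2.7789, 1.2577)
        draws = predict_stage_cdd(post, 4.0, n_draws=50, include_noise=False)
        assert np.all(draws == pytest.approx(7.8097, abs=1e-9))
        assert round(float(draws.mean()), 1) == 7.8

    def test_stage_zero_returns_intercept(self):
        post = _degenerate_posterior(2.5, 1.3)
        draws = predict_stage_cdd(post, 0.0, n_draws=20, include_noise=False)
        assert np.all(draws == pytest.approx(2.5))

    def test_exgaussian_mean_is_location_plus_beta(self):
        post = _degenerate_posterior(2.0, 1.25, sigma=0.5, likelihood="exgaussian",
                                     beta_exg=1.5)
        draws = predict_stage_cdd(post, 4.0, n_draws=40_000, seed=3)
        assert draws.mean() == pytest.approx(2.0 + 5.0 + 1.5, abs=0.05)
        # positive skew from the exponential component
        assert float(pd.Series(draws).skew()) > 0.2

    def test_affine_equivariance_in_intercept(self):
        a = predict_stage_cdd(_degenerate_posterior(2.0, 1.25), 4.0, 50,
                              include_noise=False)
        b = predict_stage_cdd(_degenerate_posterior(5.0, 1.25), 4.0, 50,
                              include_noise=False)
        assert np.allclose(b - a, 3.0)


class TestPredictStageCalendar:
    @staticmethod
    def _calendar(dd):
        return DevelopmentCalendar(year=2018, doy0=1,
                                   doy=np.arange(1, len(dd) + 1), dd=dd)

    def test_point_posterior_single_day(self):
        cal = self._calendar(np.full(120, 0.1))
        post = _degenerate_posterior(2.7789, 1.2577)
        pred = predict_stage_calendar(post, 4.0, cal, n_draws=200, seed=0)
        assert len(pred.pmf) == 1
        assert pred.median_doy == 79  # first day with cdd >= 7.8097

    def test_cold_spell_creates_hdi_gap(self):
        # development halts on days 60-80: thresholds on either side of the
        # stall map to days separated by a gap the HDI must preserve
        dd = np.full(150, 0.1)
        dd[60:80] = 0.0
        cal = self._calendar(dd)
        from vinedev.inference_core import PosteriorSamples
        from vinedev.phenology import PhenologyPosterior

        n = 400
        rng = np.random.default_rng(5)
        thresholds = np.where(rng.uniform(size=n) < 0.5, 5.5, 7.0)
        post = PhenologyPosterior(
            variant="final", likelihood="gaussian", trt_levels=("a",),
            year_levels=(2018,),
            draws=PosteriorSamples({"intercept": thresholds[None, :],
                                    "el_linear": np.zeros((1, n)),
                                    "sigma": np.full((1, n), 1e-9)}, 1, n))
        pred = predict_stage_calendar(post, 4.0, cal, n_draws=400, seed=1)
        assert len(pred.hdi95) >= 2  # union with a gap across the stall
        covered = {d for lo, hi in pred.hdi95 for d in range(lo, hi + 1)}
        assert not ({d for d in range(62, 80)} & covered)

    def test_warm_year_earlier_than_cold_year(self):
        post = _degenerate_posterior(2.7789, 1.2577, sigma=0.5)
        warm = self._calendar(np.full(200, 0.15))
        cold = self._calendar(np.full(200, 0.06))
        p_warm = predict_stage_calendar(post, 4.0, warm, 500, seed=2)
        p_cold = predict_stage_calendar(post, 4.0, cold, 500, seed=2)
        assert p_warm.median_doy < p_cold.median_doy

    def test_stage_monotonicity_of_median_day(self):
        post = _degenerate_posterior(2.7789, 1.2577, sigma=0.5)
        cal = self._calendar(np.full(250, 0.12))
        medians = [predict_stage_calendar(post, el, cal, 300, seed=4).median_doy
                   for el in (4.0, 6.5, 9.5, 19.5)]
        assert medians == sorted(medians)

    def test_unattained_draws_warn(self):
        cal = self._calendar(np.full(30, 0.1))  # tops out at CDD 3
        post = _degenerate_posterior(2.7789, 1.2577, sigma=2.0)
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError):
                predict_stage_calendar(post, 19.5, cal, 200, seed=5)


class TestRemlFit:
    def test_zero_noise_slope_exact(self):
        rng = np.random.default_rng(0)
        rows = []
        for ring in range(4):
            for plant in range(3):
                for el in (4.0, 6.5, 8.5, 10.5, 12.5):
                    rows.append({"year": 2018, "trt": "aCO2" if ring < 2 else "eCO2",
                                 "ring": f"r{ring}", "plant": f"p{plant}",
                                 "shoot": "s1", "doy": 100, "el_linear": el,
                                 "cdd": 2.5 + 1.25 * el})
        df = pd.DataFrame(rows)
        fit = fit_phenology_reml(df)
        for slope in fit.slope_by_trt.values():
            assert slope == pytest.approx(1.25, abs=1e-6)
        assert fit.intercept == pytest.approx(2.5, abs=1e-6)

    def test_recovers_generator_slope(self, small_bundle):
        obs = attach_cdd(small_bundle.ratings, small_bundle.calendars)
        fit = fit_phenology_reml(obs)
        truth = small_bundle.truth.phen_slope
        for slope in fit.slope_by_trt.values():
            assert slope == pytest.approx(truth, rel=0.08)

    def test_train_test_nrmse_gap_small(self, small_bundle):
        from vinedev.inference_core import error_metrics
        from vinedev.pipeline import phenology_split

        obs = attach_cdd(small_bundle.ratings, small_bundle.calendars)
        train, test, _ = phenology_split(obs, 0.8, seed=3)
        fit = fit_phenology_reml(train)
        gap = abs(error_metrics(train["cdd"], fit.predict(train), "nrmse")
                  - error_metrics(test["cdd"], fit.predict(test), "nrmse"))
        assert gap < 0.05


class TestBayesVariants:
    def test_final_variant_recovers_generator_slope(self, small_bundle, fast_mcmc):
        obs = attach_cdd(small_bundle.ratings, small_bundle.calendars)
        post = fit_phenology_bayes(obs, "final", fast_mcmc)
        slope = post.slope
        truth = small_bundle.truth.phen_slope
        assert abs(slope.mean() - truth) < 3 * slope.std()
        from vinedev.inference_core import probability_of_direction

        assert probability_of_direction(slope) == 100.0

    def test_exgaussian_predictive_right_skew(self, small_bundle, fast_mcmc):
        obs = attach_cdd(small_bundle.ratings, small_bundle.calendars)
        post = fit_phenology_bayes(obs, "final-exgaussian", fast_mcmc)
        draws = predict_stage_cdd(post, 4.0, n_draws=4000, seed=1)
        assert float(pd.Series(draws).skew()) > 0.0

    def test_gaussian_posterior_agrees_with_reml(self, small_bundle, fast_mcmc):
        obs = attach_cdd(small_bundle.ratings, small_bundle.calendars)
        post = fit_phenology_bayes(obs, "final", fast_mcmc)
        reml = fit_phenology_reml(obs)
        slope_draws = post.slope
        reml_slope = np.mean(list(reml.slope_by_trt.values()))
        assert abs(slope_draws.mean() - reml_slope) < 2 * slope_draws.std() + 0.02

    def test_unknown_variant_rejected(self, small_bundle):
        obs = attach_cdd(small_bundle.ratings, small_bundle.calendars)
        with pytest.raises(ValueError):
            fit_phenology_bayes(obs, "no-such-ladder-step")
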