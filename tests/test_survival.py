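import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from nsclc_cea.survival import (
    ExponentialParams,
    LogLogisticParams,
    SurvivalCurve,
    apply_hazard_ratio,
    fit_exponential_mle,
    fit_loglogistic_mle,
    fit_weibull_mle,
    interval_event_prob,
    loglogistic_hazard,
    loglogistic_survival,
    select_model_aic,
)
from nsclc_cea.synthetic import SimulationTruth, simulate_ipd

OS_PARAMS = LogLogisticParams(scale=0.07476837, shape=1.52037)


class TestLogLogisticSurvival:
    def test_starts_at_one(self):
        assert loglogistic_survival(OS_PARAMS, 0.0) == 1.0

    def test_median_is_inverse_scale(self):
        # analytic median of S(t)=1/(1+(lt)^g) is 1/l; confirm against an
        # independent numeric root-finder on the survival function itself
        median = 1.0 / OS_PARAMS.scale
        assert loglogistic_survival(OS_PARAMS, median) == pytest.approx(0.5, abs=1e-12)
        root = brentq(lambda t: loglogistic_survival(OS_PARAMS, t) - 0.5, 1e-6, 1e3)
        assert root == pytest.approx(median, rel=1e-9)

    def test_vanishes_at_large_times(self):
        assert loglogistic_survival(OS_PARAMS, 1e6) < 1e-6

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            loglogistic_survival(OS_PARAMS, -1.0)

    @settings(deadline=None, max_examples=50)
    @given(
        scale=st.floats(1e-3, 10.0),
        shape=st.floats(0.1, 8.0),
    )
    def test_monotone_and_bounded(self, scale, shape):
        p = LogLogisticParams(scale, shape)
        t = np.linspace(0.0, 200.0, 301)
        s = p.survival(t)
        assert np.all(s <= 1.0 + 1e-12) and np.all(s >= 0.0)
        assert np.all(np.diff(s) <= 1e-12)


class TestLogLogisticHazard:
    def test_matches_numeric_derivative_of_log_survival(self):
        for t in (0.5, 3.0, 12.0, 40.0):
            eps = 1e-5
            numeric = -(
                np.log(loglogistic_survival(OS_PARAMS, t + eps))
                - np.log(loglogistic_survival(OS_PARAMS, t - eps))
            ) / (2 * eps)
            assert loglogistic_hazard(OS_PARAMS, t) == pytest.approx(numeric, abs=1e-6)

    def test_shape_one_gives_decreasing_closed_form(self):
        p = LogLogisticParams(scale=0.2, shape=1.0)
        ts = np.array([0.5, 1.0, 5.0, 20.0])
        expected = p.scale / (1.0 + p.scale * ts)
        np.testing.assert_allclose(loglogistic_hazard(p, ts), expected, rtol=1e-12)
        assert np.all(np.diff(loglogistic_hazard(p, ts)) < 0)

    def test_hazard_times_survival_equals_density(self):
        for t in (1.0, 10.0, 30.0):
            eps = 1e-5
            dS = (
                loglogistic_survival(OS_PARAMS, t + eps)
                - loglogistic_survival(OS_PARAMS, t - eps)
            ) / (2 * eps)
            f = loglogistic_hazard(OS_PARAMS, t) * loglogistic_survival(OS_PARAMS, t)
            assert f == pytest.approx(-dS, abs=1e-6)

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError):
            loglogistic_hazard(OS_PARAMS, 0.0)


class TestHazardRatio:
    def test_unit_ratio_is_identity(self):
        base = SurvivalCurve(OS_PARAMS)
        same = apply_hazard_ratio(base, 1.0)
        t = np.linspace(0, 100, 50)
        np.testing.assert_allclose(same.survival(t), base.survival(t))

    def test_proportional_hazards_power_rule(self):
        curve = apply_hazard_ratio(SurvivalCurve(OS_PARAMS), 0.73)
        t_half = 1.0 / OS_PARAMS.scale  # baseline survival is 0.5 here
        assert float(curve.survival(t_half)) == pytest.approx(0.5**0.73, rel=1e-12)
        assert 0.5**0.73 == pytest.approx(0.6029, abs=5e-4)

    def test_vanishing_ratio_approaches_full_survival(self):
        curve = apply_hazard_ratio(SurvivalCurve(OS_PARAMS), 1e-9)
        assert float(curve.survival(500.0)) > 0.999

    def test_protective_ratio_dominates_baseline(self):
        base = SurvivalCurve(OS_PARAMS)
        better = apply_hazard_ratio(base, 0.73)
        t = np.linspace(0.1, 300, 100)
        assert np.all(better.survival(t) > base.survival(t))

    def test_aft_mode_rescales_time(self):
        curve = SurvivalCurve(OS_PARAMS, hr=0.5, hr_mode="aft")
        t = np.array([4.0, 20.0, 80.0])
        np.testing.assert_allclose(curve.survival(t), OS_PARAMS.survival(0.5 * t))

    def test_invalid_ratio_rejected(self):
        with pytest.raises(ValueError):
            apply_hazard_ratio(SurvivalCurve(OS_PARAMS), 0.0)


class TestIntervalEventProb:
    def test_flat_survival_gives_zero(self):
        # an exponential over a zero-length hazard region is approximated by
        # a tiny interval where survival barely moves
        curve = SurvivalCurve(ExponentialParams(1e-12))
        assert interval_event_prob(curve, 0.0, 10.0) == pytest.approx(0.0, abs=1e-9)

    def test_ratio_arithmetic(self):
        # choose times where the log-logistic takes survival 0.8 and 0.6
        p = LogLogisticParams(scale=0.1, shape=1.5)
        t80 = ((1 / 0.8 - 1) ** (1 / p.shape)) / p.scale
        t60 = ((1 / 0.6 - 1) ** (1 / p.shape)) / p.scale
        prob = interval_event_prob(SurvivalCurve(p), t80, t60)
        assert prob == pytest.approx(1 - 0.6 / 0.8, rel=1e-9)  # = 0.25

    def test_chaining_adjacent_intervals(self):
        curve = SurvivalCurve(OS_PARAMS, hr=0.73)
        p1 = interval_event_prob(curve, 0.0, 6.0)
        p2 = interval_event_prob(curve, 6.0, 14.0)
        combined = interval_event_prob(curve, 0.0, 14.0)
        assert 1 - (1 - p1) * (1 - p2) == pytest.approx(combined, rel=1e-12)

    def test_bad_interval_rejected(self):
        with pytest.raises(ValueError):
            interval_event_prob(SurvivalCurve(OS_PARAMS), 5.0, 5.0)


class TestMaximumLikelihood:
    def test_recovers_truth_uncensored(self):
        truth = SimulationTruth(OS_PARAMS, n=5000, seed=11)
        ipd = simulate_ipd(truth)
        est, _ = fit_loglogistic_mle(ipd.times, ipd.events)
        assert est.scale == pytest.approx(OS_PARAMS.scale, rel=0.05)
        assert est.shape == pytest.approx(OS_PARAMS.shape, rel=0.05)

    def test_recovers_truth_with_censoring(self):
        truth = SimulationTruth(OS_PARAMS, n=5000, censoring_rate=0.30, seed=12)
        ipd = simulate_ipd(truth)
        est, _ = fit_loglogistic_mle(ipd.times, ipd.events)
        assert est.scale == pytest.approx(OS_PARAMS.scale, rel=0.10)
        assert est.shape == pytest.approx(OS_PARAMS.shape, rel=0.10)

    def test_optimum_beats_generating_parameters(self):
        truth = SimulationTruth(OS_PARAMS, n=800, censoring_rate=0.2, seed=13)
        ipd = simulate_ipd(truth)
        est, ll_hat = fit_loglogistic_mle(ipd.times, ipd.events)
        ll_truth = float(
            np.sum(
                np.where(
                    ipd.events == 1,
                    OS_PARAMS.log_pdf(ipd.times),
                    OS_PARAMS.log_survival(ipd.times),
                )
            )
        )
        assert ll_hat >= ll_truth - 1e-6

    def test_fitted_median_matches_sample_median(self):
        truth = SimulationTruth(OS_PARAMS, n=4000, seed=14)
        ipd = simulate_ipd(truth)
        est, _ = fit_loglogistic_mle(ipd.times, ipd.events)
        sample_median = float(np.median(ipd.times))
        assert 1.0 / est.scale == pytest.approx(sample_median, rel=0.05)

    def test_all_censored_rejected(self):
        with pytest.raises(ValueError):
            fit_loglogistic_mle([1.0, 2.0, 3.0], [0, 0, 0])

    def test_matches_lifelines_oracle(self):
        lifelines = pytest.importorskip("lifelines")
        truth = SimulationTruth(OS_PARAMS, n=1500, censoring_rate=0.25, seed=15)
        ipd = simulate_ipd(truth)
        est, ll_hat = fit_loglogistic_mle(ipd.times, ipd.events)
        llf = lifelines.LogLogisticFitter().fit(ipd.times, ipd.events)
        # lifelines parameterises S(t) = 1/(1+(t/alpha)^beta)
        assert est.scale == pytest.approx(1.0 / llf.alpha_, rel=1e-3)
        assert est.shape == pytest.approx(llf.beta_, rel=1e-3)
        assert ll_hat == pytest.approx(llf.log_likelihood_, abs=1e-2)


class TestModelSelection:
    def test_fewer_parameters_break_ties(self):
        ranked = select_model_aic([("A", 2, -100.0), ("B", 3, -100.0)])
        assert [r[0] for r in ranked] == ["A", "B"]

    def test_better_loglik_wins(self):
        ranked = select_model_aic([("A", 2, -100.0), ("B", 2, -90.0)])
        assert ranked[0][0] == "B"

    def test_aic_arithmetic(self):
        (_, _, _, aic), = select_model_aic([("A", 2, -100.0)])
        assert aic == 204.0

    def test_loglogistic_data_prefers_loglogistic(self):
        truth = SimulationTruth(LogLogisticParams(0.1, 3.0), n=3000, seed=16)
        ipd = simulate_ipd(truth)
        fits = []
        for name, fitter, k in [
            ("loglogistic", fit_loglogistic_mle, 2),
            ("weibull", fit_weibull_mle, 2),
            ("exponential", fit_exponential_mle, 1),
        ]:
            _, ll = fitter(ipd.times, ipd.events)
            fits.append((name, k, ll))
        ranked = select_model_aic(fits)
        assert ranked[0][0] == "loglogistic"
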