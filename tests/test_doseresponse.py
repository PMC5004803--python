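"""Dose-response model evaluation, fitting, acceptance rules and ECx."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from osdtox.doseresponse import (
    E_EXCEEDS_MAX_DOSE,
    FIT_FAILED,
    R2_BELOW_THRESHOLD,
    SLOPE_NONPOSITIVE,
    DoseResponseFit,
    DoseSeries,
    EcxNotAttainedError,
    HormesisParams,
    LogLogisticParams,
    apply_acceptance_criteria,
    compute_ecx,
    ecx_confidence_interval,
    eval_hormesis,
    eval_loglogistic,
    fit_dose_response,
    select_model,
)
from osdtox.doseresponse import test_hormesis_significance as hormesis_f_test


def bisect_response_level(evalf, params, target, lo=1e-12, hi=1e9, iters=200):
    """Independent oracle: bisection for the dose where the declining curve
    crosses a target response."""
    for _ in range(iters):
        mid = math.sqrt(lo * hi)
        if evalf(params, mid) > target:
            lo = mid
        else:
            hi = mid
    return math.sqrt(lo * hi)


class TestEvaluation:
    @pytest.mark.parametrize(
        "params,dose,expected",
        [
            (LogLogisticParams(2, 0, 100, 10), 0.0, 100.0),
            (LogLogisticParams(2, 0, 100, 10), 10.0, 50.0),
            (LogLogisticParams(1, 20, 100, 5), 15.0, 40.0),
        ],
    )
    def test_loglogistic_examples(self, params, dose, expected):
        assert eval_loglogistic(params, dose) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize(
        "params,dose,expected",
        [
            (HormesisParams(2, 0, 100, 10, 0), 10.0, 50.0),
            (HormesisParams(2, 0, 100, 10, 5), 0.0, 100.0),
            (HormesisParams(1.3, 7, 90, 3, 2), 0.0, 90.0),
            (HormesisParams(2, 0, 100, 10, 5), 10.0, 75.0),
        ],
    )
    def test_hormesis_examples(self, params, dose, expected):
        assert eval_hormesis(params, dose) == pytest.approx(expected, rel=1e-12)

    def test_loglogistic_limits(self):
        p = LogLogisticParams(2, 5, 100, 10)
        assert eval_loglogistic(p, 1e12) == pytest.approx(p.c, abs=1e-6)
        assert eval_loglogistic(p, 0.0) == p.d

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            eval_loglogistic(LogLogisticParams(2, 0, 100, 10), -1.0)

    def test_nonfinite_params_rejected(self):
        with pytest.raises(ValueError):
            LogLogisticParams(math.nan, 0, 100, 10)
        with pytest.raises(ValueError):
            LogLogisticParams(1, 0, 100, -3)
        with pytest.raises(ValueError):
            HormesisParams(1, 0, 100, 10, math.inf)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        b=st.floats(-3, 5).filter(lambda v: abs(v) > 1e-3),
        c=st.floats(-50, 50),
        d=st.floats(-50, 200),
        e=st.floats(0.01, 1e4),
        dose=st.floats(0, 1e5),
    )
    def test_hormesis_with_zero_f_equals_loglogistic(self, b, c, d, e, dose):
        ll = eval_loglogistic(LogLogisticParams(b, c, d, e), dose)
        h = eval_hormesis(HormesisParams(b, c, d, e, 0.0), dose)
        assert h == pytest.approx(ll, rel=1e-12, abs=1e-12)


class TestFitting:
    def test_noise_free_recovery(self, clean_loglogistic_series):
        series, truth = clean_loglogistic_series
        fit = fit_dose_response(series, "loglogistic4")
        assert fit.accepted and not fit.rejection_reasons
        got = fit.params.as_array()
        want = truth.as_array()
        assert np.all(np.abs(got - want) / np.abs(want) < 1e-4)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)
        assert fit.covariance is not None and fit.covariance.shape == (4, 4)

    def test_noise_free_hormesis_recovery(self, dose_grid_14):
        truth = HormesisParams(2.0, 0.0, 100.0, 10.0, 5.0)
        y = eval_hormesis(truth, dose_grid_14)
        fit = fit_dose_response(DoseSeries(doses=dose_grid_14, responses=y), "hormesis5")
        got = fit.params.as_array()
        assert np.allclose(got, truth.as_array(), rtol=1e-4, atol=1e-6)

    def test_flat_responses_fail(self, dose_grid_14):
        series = DoseSeries(doses=dose_grid_14, responses=np.full(14, 7.0))
        fit = fit_dose_response(series, "loglogistic4")
        assert not fit.accepted
        assert FIT_FAILED in fit.rejection_reasons

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            DoseSeries(doses=[1, 2, 3, 4, 5], responses=[5, 4, 3, 2, 1])

    def test_hormetic_f_recovered_with_noise(self, dose_grid_14):
        # 2% noise; median relative f error over replicates stays below 25%
        truth = HormesisParams(1.5, 0.0, 100.0, 20.0, 12.0)
        y0 = eval_hormesis(truth, dose_grid_14)
        rng = np.random.default_rng(0)
        errs = []
        for _ in range(60):
            y = y0 + rng.normal(0, 2.0, size=y0.size)
            fit = fit_dose_response(DoseSeries(doses=dose_grid_14, responses=y), "hormesis5")
            if not fit.failed:
                errs.append(abs(fit.params.f - truth.f) / truth.f)
        assert np.median(errs) < 0.25


class TestAcceptance:
    def _fit(self, b=1.5, e=10.0, r2=0.9, model="loglogistic4"):
        params = (
            LogLogisticParams(b, 0, 100, e)
            if model == "loglogistic4"
            else HormesisParams(b, 0, 100, e, 1.0)
        )
        return DoseResponseFit(
            model=model, params=params, covariance=np.eye(len(params.as_array())),
            r_squared=r2, residual_df=9, accepted=True, rejection_reasons=[],
            max_dose=404.0, n_obs=14,
        )

    @pytest.mark.parametrize(
        "kwargs,reason",
        [
            ({"b": -2.0}, SLOPE_NONPOSITIVE),
            ({"e": 700.0}, E_EXCEEDS_MAX_DOSE),
            ({"r2": 0.5}, R2_BELOW_THRESHOLD),
        ],
    )
    def test_single_criterion_rejections(self, kwargs, reason):
        out = apply_acceptance_criteria(self._fit(**kwargs), max_dose=404.0)
        assert not out.accepted
        assert out.rejection_reasons == [reason]

    def test_r2_threshold_is_strict(self):
        out = apply_acceptance_criteria(self._fit(r2=0.65), max_dose=404.0)
        assert R2_BELOW_THRESHOLD in out.rejection_reasons
        ok = apply_acceptance_criteria(self._fit(r2=0.651), max_dose=404.0)
        assert ok.accepted

    def test_good_fit_accepted(self):
        out = apply_acceptance_criteria(self._fit(), max_dose=404.0)
        assert out.accepted and out.rejection_reasons == []

    def test_hormesis_significance_wald(self):
        fit = self._fit(model="hormesis5")
        cov = np.zeros((5, 5))
        cov[4, 4] = 4.0  # SE(f) = 2
        fit.covariance = cov
        fit.params = HormesisParams(1.5, 0, 100, 10, 10.0)
        assert hormesis_f_test(fit) is True  # CI (5.48, 14.52)
        fit.params = HormesisParams(1.5, 0, 100, 10, 1.0)
        assert hormesis_f_test(fit) is False
        fit.params = HormesisParams(1.5, 0, 100, 10, 0.0)
        assert hormesis_f_test(fit) is False

    def test_hormesis_significance_without_covariance(self):
        fit = self._fit(model="hormesis5")
        fit.covariance = None
        assert hormesis_f_test(fit) is False

    def test_select_model_prefers_hormesis(self):
        ll = self._fit()
        h = self._fit(model="hormesis5")
        assert select_model(ll, h).model == "hormesis5"
        h_rej = apply_acceptance_criteria(self._fit(model="hormesis5", r2=0.2), 404.0)
        assert select_model(ll, h_rej).model == "loglogistic4"
        ll_rej = apply_acceptance_criteria(self._fit(r2=0.2), 404.0)
        assert select_model(ll_rej, h_rej) is None


class TestEcx:
    def _accepted_fit(self, params, model="loglogistic4", max_dose=5590.0, cov=None):
        return DoseResponseFit(
            model=model, params=params, covariance=cov, r_squared=0.99,
            residual_df=9, accepted=True, rejection_reasons=[],
            max_dose=max_dose, control_dose=0.1, n_obs=14,
        )

    def test_ec50_modes_agree_when_c_zero(self):
        fit = self._accepted_fit(LogLogisticParams(1, 0, 100, 10))
        assert compute_ecx(fit, 50, "span").value == pytest.approx(10.0, rel=1e-12)
        assert compute_ecx(fit, 50, "upper_asymptote").value == pytest.approx(10.0, rel=1e-12)

    def test_ec20_closed_form(self):
        fit = self._accepted_fit(LogLogisticParams(1, 0, 100, 10))
        assert compute_ecx(fit, 20, "span").value == pytest.approx(2.5, rel=1e-12)

    def test_upper_asymptote_vs_span_with_nonzero_c(self):
        # with c > 0, a 20% drop from d is a larger absolute drop than 20%
        # of the d..c span, so the upper-asymptote EC20 sits at a higher dose
        fit = self._accepted_fit(LogLogisticParams(2, 30, 100, 10))
        ua = compute_ecx(fit, 20, "upper_asymptote").value
        sp = compute_ecx(fit, 20, "span").value
        assert ua > sp
        target = 0.8 * 100
        oracle = bisect_response_level(eval_loglogistic, fit.params, target)
        assert ua == pytest.approx(oracle, rel=1e-8)

    def test_no_crossing_when_target_below_lower_asymptote(self):
        fit = self._accepted_fit(LogLogisticParams(2, 90, 100, 10))
        with pytest.raises(EcxNotAttainedError):
            compute_ecx(fit, 20, "upper_asymptote")  # 0.8*d = 80 < c = 90

    def test_hormesis_ecx_matches_grid_scan(self):
        params = HormesisParams(2, 0, 100, 10, 5)
        fit = self._accepted_fit(params, model="hormesis5", max_dose=5590.0)
        got = compute_ecx(fit, 20, "upper_asymptote").value
        grid = np.geomspace(1e-3, 5590.0 * 10, 10**6)
        y = eval_hormesis(params, grid)
        peak = int(np.argmax(y))
        target = 0.8 * params.d
        desc = y[peak:]
        j = int(np.argmax(desc <= target))
        oracle = grid[peak + j]
        assert got == pytest.approx(oracle, rel=1e-4)

    def test_ecx_monotone_in_p(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            params = LogLogisticParams(
                rng.uniform(0.5, 4), 0.0, rng.uniform(50, 200), rng.uniform(1, 100)
            )
            fit = self._accepted_fit(params)
            ps = np.linspace(5, 95, 10)
            vals = [compute_ecx(fit, p, "span").value for p in ps]
            assert np.all(np.diff(vals) >= 0)

    def test_below_background_flagged(self):
        fit = self._accepted_fit(LogLogisticParams(1, 0, 100, 0.2))
        est = compute_ecx(fit, 20, "span")  # 0.2 * 0.25 = 0.05 < 0.1
        assert est.below_background is True

    def test_ci_zero_covariance_collapses(self):
        fit = self._accepted_fit(LogLogisticParams(1, 0, 100, 10), cov=np.zeros((4, 4)))
        est = ecx_confidence_interval(fit, 20, "span")
        assert est.ci_low == pytest.approx(est.value)
        assert est.ci_high == pytest.approx(est.value)

    def test_ci_analytic_width_for_var_e_only(self):
        # only e uncertain: CI width = 2 * 1.96 * sigma * (p/(100-p))^(1/b)
        sigma = 1.5
        cov = np.zeros((4, 4))
        cov[3, 3] = sigma**2
        b = 1.8
        fit = self._accepted_fit(LogLogisticParams(b, 0, 100, 10), cov=cov)
        est = ecx_confidence_interval(fit, 20, "span")
        want = 2 * 1.96 * sigma * (20 / 80) ** (1 / b)
        assert est.ci_high - est.ci_low == pytest.approx(want, rel=1e-3)

    def test_ci_without_covariance_returns_point(self):
        fit = self._accepted_fit(LogLogisticParams(1, 0, 100, 10), cov=None)
        est = ecx_confidence_interval(fit, 20, "span")
        assert est.ci_low is None and est.ci_high is None

    def test_rejected_fit_refuses_ecx(self):
        fit = self._accepted_fit(LogLogisticParams(1, 0, 100, 10))
        fit = apply_acceptance_criteria(fit, max_dose=5.0)  # e > max dose
        with pytest.raises(ValueError):
            compute_ecx(fit, 20)

    def test_delta_ci_covers_truth_in_simulation(self, dose_grid_14):
        truth = LogLogisticParams(1.5, 0.0, 100.0, 20.0)
        y0 = eval_loglogistic(truth, dose_grid_14)
        true_ec20 = 20.0 * (20 / 80) ** (1 / 1.5)
        rng = np.random.default_rng(2)
        n_cover = 0
        n = 120
        for _ in range(n):
            y = y0 + rng.normal(0, 2.0, size=y0.size)
            fit = fit_dose_response(DoseSeries(doses=dose_grid_14, responses=y))
            est = ecx_confidence_interval(fit, 20, "span")
            if est.ci_low is not None and est.ci_low <= true_ec20 <= est.ci_high:
                n_cover += 1
        assert 0.85 <= n_cover / n <= 1.0
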