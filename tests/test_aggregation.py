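"""Torque-curve feature extraction and the Chesler--Cram peak fit."""

import numpy as np
import pytest

from vitalgluten.aggregation import (AggregationCurve, CCEParams,
                                     DataQualityWarning, cce_eval,
                                     compute_peak_areas, extract_bem_pmt,
                                     fit_cce)
from vitalgluten.synthetic import generate_aggregation_curve

PARAMS = CCEParams(y0=2.0, xc1=300.0, A=25.0, w=1500.0, k2=0.04, xc2=100.0,
                   B=0.3, k3=0.015, xc3=480.0)


def _curve(torque, time=None):
    torque = np.asarray(torque, float)
    if time is None:
        time = np.arange(torque.size, dtype=float)
    return AggregationCurve(time=np.asarray(time, float), torque=torque)


class TestCCEEval:
    def test_gaussian_apex_without_tail(self):
        p = CCEParams(y0=5.0, xc1=250.0, A=25.0, w=900.0, k2=0.05,
                      xc2=100.0, B=0.0, k3=0.02, xc3=400.0)
        assert cce_eval(p, 250.0) == pytest.approx(30.0, abs=1e-12)

    def test_left_limit_is_offset(self):
        # far left of every centre both bracketed terms vanish
        y = cce_eval(PARAMS, -1e5)
        assert y == pytest.approx(PARAMS.y0, abs=1e-9)

    def test_matches_independent_transcription(self):
        # independently coded form of the same equation
        def oracle(p, x):
            gauss = np.exp(-((x - p.xc1) ** 2) / (2 * p.w))
            sigm = 1 - 0.5 * (1 - np.tanh(p.k2 * (x - p.xc2)))
            expo = np.exp(-0.5 * p.k3 * (abs(x - p.xc3) + (x - p.xc3)))
            return p.y0 + p.A * (gauss + p.B * sigm * expo)

        xs = np.linspace(0, 600, 173)
        ours = cce_eval(PARAMS, xs)
        theirs = np.array([oracle(PARAMS, float(x)) for x in xs])
        np.testing.assert_allclose(ours, theirs, atol=1e-12, rtol=0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            CCEParams(y0=1, xc1=1, A=-2, w=1, k2=1, xc2=1, B=1, k3=1, xc3=1)
        with pytest.raises(ValueError):
            CCEParams(y0=1, xc1=1, A=2, w=0, k2=1, xc2=1, B=1, k3=1, xc3=1)
        with pytest.raises(ValueError):
            CCEParams(y0=np.nan, xc1=1, A=2, w=1, k2=1, xc2=1, B=1, k3=1,
                      xc3=1)


class TestBemPmt:
    def test_argmax_with_times(self):
        curve = _curve([0, 5, 30, 10] + [1] * 6,
                       [0, 100, 250, 400, 410, 420, 430, 440, 450, 460])
        assert extract_bem_pmt(curve) == (30.0, 250.0)

    def test_tie_broken_by_earliest_time(self):
        curve = _curve([0, 7, 7, 3, 2, 1, 1, 1, 1, 1])
        assert extract_bem_pmt(curve) == (7.0, 1.0)

    def test_constant_curve_warns(self):
        curve = _curve([4.0] * 12)
        with pytest.warns(DataQualityWarning):
            bem, pmt = extract_bem_pmt(curve)
        assert (bem, pmt) == (4.0, 0.0)

    def test_invariant_to_appending_smaller_values(self):
        base = generate_aggregation_curve(PARAMS, noise_sd=0.0)
        bem, pmt = extract_bem_pmt(base)
        extended = AggregationCurve(
            time=np.concatenate([base.time, base.time[-1] + [1, 2, 3]]),
            torque=np.concatenate([base.torque, [0.1, 0.2, 0.0]]))
        assert extract_bem_pmt(extended) == (bem, pmt)

    def test_closed_form_argmax_recovered(self):
        # without the tail term the maximum sits exactly at xc1
        p = CCEParams(y0=5.0, xc1=300.0, A=25.0, w=1200.0, k2=0.05,
                      xc2=100.0, B=0.0, k3=0.02, xc3=400.0)
        curve = generate_aggregation_curve(p, noise_sd=0.0, interval=1.0)
        grid = np.linspace(0, 600, 60001)
        oracle_pmt = grid[np.argmax(cce_eval(p, grid))]
        _, pmt = extract_bem_pmt(curve)
        assert abs(pmt - oracle_pmt) <= 1.0


class TestPeakAreas:
    def test_constant_torque_rectangles(self):
        t = np.arange(0, 601, 1.0)
        curve = _curve(np.full_like(t, 3.0), t)
        peak30, peak180, ratio = compute_peak_areas(curve, pmt=300.0)
        assert peak30 == pytest.approx(30 * 3.0)
        assert peak180 == pytest.approx(135 * 3.0)
        assert ratio == pytest.approx(2 / 9)

    def test_windows_coincide_at_pmt_195(self):
        t = np.arange(0, 601, 1.0)
        curve = _curve(np.full_like(t, 2.0), t)
        peak30, peak180, ratio = compute_peak_areas(curve, pmt=195.0)
        assert peak30 == pytest.approx(peak180)
        assert ratio == pytest.approx(1.0)

    def test_early_pmt_flagged(self):
        t = np.arange(0, 601, 1.0)
        curve = _curve(np.full_like(t, 2.0), t)
        with pytest.warns(DataQualityWarning):
            compute_peak_areas(curve, pmt=150.0)

    def test_interpolated_endpoints_match_fine_riemann_sum(self):
        curve = generate_aggregation_curve(PARAMS, noise_sd=0.0, interval=1.0)
        peak30, peak180, _ = compute_peak_areas(curve, pmt=300.0)
        fine = np.linspace(285, 315, 300001)
        oracle30 = np.trapezoid(cce_eval(PARAMS, fine), fine)
        fine = np.linspace(180, 315, 300001)
        oracle180 = np.trapezoid(cce_eval(PARAMS, fine), fine)
        assert peak30 == pytest.approx(oracle30, rel=1e-3)
        assert peak180 == pytest.approx(oracle180, rel=1e-3)

    def test_curve_too_short_for_window(self):
        curve = _curve(np.linspace(0, 5, 20), np.linspace(0, 400, 20))
        with pytest.raises(ValueError):
            compute_peak_areas(curve, pmt=395.0)


class TestCCEFit:
    def test_noise_free_parameter_recovery(self):
        curve = generate_aggregation_curve(PARAMS, noise_sd=0.0)
        fit = fit_cce(curve)
        true = PARAMS.as_array()
        rel = np.abs(fit.params.as_array() - true) / np.abs(true)
        assert rel.max() < 1e-3
        assert fit.r_squared > 1 - 1e-9

    def test_unpacks_as_params_and_r2(self):
        curve = generate_aggregation_curve(PARAMS, noise_sd=0.0)
        params, r2 = fit_cce(curve)
        assert isinstance(params, CCEParams)
        assert 0 <= r2 <= 1

    def test_residual_not_worse_than_initialisation(self):
        from vitalgluten.aggregation import _initial_guess
        curve = generate_aggregation_curve(PARAMS, noise_sd=1.0, seed=3)
        fit = fit_cce(curve)
        x0 = _initial_guess(curve)
        sse_fit = np.sum((cce_eval(fit.params, curve.time) - curve.torque) ** 2)
        sse_init = np.sum(
            (cce_eval(CCEParams.from_array(x0), curve.time) - curve.torque) ** 2)
        assert sse_fit <= sse_init + 1e-9

    def test_scale_consistency(self):
        # scaling torque by c scales y0 and A; centres stay put
        curve = generate_aggregation_curve(PARAMS, noise_sd=0.0)
        scaled = AggregationCurve(time=curve.time, torque=3.0 * curve.torque)
        f1 = fit_cce(curve)
        f2 = fit_cce(scaled)
        assert f2.params.y0 == pytest.approx(3 * f1.params.y0, rel=1e-3)
        assert f2.params.A == pytest.approx(3 * f1.params.A, rel=1e-3)
        assert f2.params.xc1 == pytest.approx(f1.params.xc1, rel=1e-4)
        assert f2.params.xc3 == pytest.approx(f1.params.xc3, rel=1e-3)

    def test_deterministic(self):
        curve = generate_aggregation_curve(PARAMS, noise_sd=1.5, seed=11)
        a = fit_cce(curve)
        b = fit_cce(curve)
        np.testing.assert_array_equal(a.params.as_array(), b.params.as_array())


class TestCurveValidation:
    def test_rejects_nan_and_unsorted_time(self):
        with pytest.raises(ValueError):
            _curve([1, 2, np.nan] + [1] * 7)
        with pytest.raises(ValueError):
            AggregationCurve(time=np.array([0, 2, 1] + list(range(3, 10)), float),
                             torque=np.ones(10))

    def test_rejects_short_curves(self):
        with pytest.raises(ValueError):
            _curve([1.0] * 5)
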