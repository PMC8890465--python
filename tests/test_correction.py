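"""Correction equations, their reduction identities, and the OLS calibration."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nirtcal.correction import (
    CameraCalibration,
    CorrectionInputs,
    IDENTITY_CALIBRATION,
    conventional_correction,
    fit_linear_coefficients,
    full_reference_correction,
    linear_correction,
    reference_correction,
)

radiance = st.floats(min_value=400.0, max_value=600.0)
emissivity = st.floats(min_value=0.5, max_value=1.0)
trans = st.floats(min_value=0.9, max_value=1.0)


def make_inputs(w1=500.0, w2=460.0, w_amb=450.0, w_tmt=462.0, **kw):
    return CorrectionInputs(w_det1=w1, w_det2=w2, w_amb=w_amb, w_tmt_rs=w_tmt, **kw)


class TestConventional:
    def test_hand_arithmetic(self):
        inp = make_inputs(w1=500.0, w_amb=450.0, eps_obj=0.97, tau_atm=0.994)
        expected = 450.0 + 50.0 / (0.97 * 0.994)
        assert conventional_correction(inp).radiance == pytest.approx(expected, rel=1e-12)

    def test_object_reading_ambient_returns_ambient(self):
        inp = make_inputs(w1=450.0, w_amb=450.0)
        assert conventional_correction(inp).radiance == pytest.approx(450.0)

    def test_identity_chain(self):
        inp = make_inputs(w1=512.3, eps_obj=1.0, tau_atm=1.0)
        assert conventional_correction(inp).radiance == 512.3

    def test_temperature_consistent_with_radiance(self):
        from nirtcal.radiometry import radiance_to_celsius

        res = conventional_correction(make_inputs())
        assert res.temperature_c == pytest.approx(radiance_to_celsius(res.radiance))


class TestReference:
    def test_hand_arithmetic(self):
        inp = make_inputs(w1=510.0, w2=460.0, w_tmt=462.0, eps_obj=0.97, tau_atm=0.994)
        expected = 462.0 + 50.0 / (0.97 * 0.994)
        assert reference_correction(inp).radiance == pytest.approx(expected, rel=1e-12)

    def test_object_at_reference_equilibrium(self):
        inp = make_inputs(w1=460.0, w2=460.0, w_tmt=462.0)
        assert reference_correction(inp).radiance == pytest.approx(462.0)

    def test_collapses_to_identity(self):
        inp = make_inputs(w1=510.0, w2=460.0, w_tmt=460.0, eps_obj=1.0, tau_atm=1.0)
        assert reference_correction(inp).radiance == pytest.approx(510.0)


class TestReductionIdentities:
    @given(radiance, radiance, radiance, emissivity, emissivity, trans)
    def test_full_form_reduces_in_steady_state(self, w1, w2, w_tmt, eo, er, tau):
        """With W_amb = W_det2 the reference's own correction term vanishes."""
        inp = CorrectionInputs(
            w_det1=w1, w_det2=w2, w_amb=w2, w_tmt_rs=w_tmt,
            eps_obj=eo, eps_rs=er, tau_atm=tau,
        )
        assert full_reference_correction(inp).radiance == pytest.approx(
            reference_correction(inp).radiance, rel=1e-12
        )

    @given(radiance, radiance, radiance, radiance, emissivity, trans)
    def test_identity_calibration_equals_reference(self, w1, w2, wa, w_tmt, eo, tau):
        inp = CorrectionInputs(
            w_det1=w1, w_det2=w2, w_amb=wa, w_tmt_rs=w_tmt, eps_obj=eo, tau_atm=tau
        )
        assert linear_correction(inp, IDENTITY_CALIBRATION).radiance == pytest.approx(
            reference_correction(inp).radiance, rel=1e-14
        )

    def test_both_quotients_vanish(self):
        inp = make_inputs(w1=450.0, w2=450.0, w_amb=450.0, w_tmt=465.0)
        assert full_reference_correction(inp).radiance == pytest.approx(465.0)

    def test_equal_emissivities_cancel_ambient(self):
        for w_amb in (430.0, 450.0, 470.0):
            inp = CorrectionInputs(
                w_det1=480.0, w_det2=480.0, w_amb=w_amb, w_tmt_rs=455.0,
                eps_obj=0.95, eps_rs=0.95, tau_atm=0.99,
            )
            assert full_reference_correction(inp).radiance == pytest.approx(455.0)


class TestLinear:
    def test_zero_predictor_gives_thermistor_plus_intercept(self):
        cal = CameraCalibration("c", a=0.9, b=1.5, r_squared=1.0, n_conditions=24)
        inp = make_inputs(w1=460.0, w2=460.0, w_tmt=462.0)
        assert linear_correction(inp, cal).radiance == pytest.approx(462.0 + 1.5)

    def test_affine_slopes_by_finite_differences(self):
        """All corrections are affine in W_det1 with the slopes implied by
        their equations: 1/(eps*tau) for the physical forms, a/(eps*tau)
        for the calibrated form."""
        eps, tau, h = 0.97, 0.994, 1.0
        cal = CameraCalibration("c", a=0.9, b=0.1, r_squared=1.0, n_conditions=24)
        lo, hi = make_inputs(w1=500.0, eps_obj=eps, tau_atm=tau), make_inputs(
            w1=500.0 + h, eps_obj=eps, tau_atm=tau
        )
        for fn, slope in [
            (conventional_correction, 1 / (eps * tau)),
            (reference_correction, 1 / (eps * tau)),
            (full_reference_correction, 1 / (eps * tau)),
        ]:
            assert (fn(hi).radiance - fn(lo).radiance) / h == pytest.approx(
                slope, rel=1e-9
            )
        d = linear_correction(hi, cal).radiance - linear_correction(lo, cal).radiance
        assert d / h == pytest.approx(cal.a / (eps * tau), rel=1e-9)


class TestInputValidation:
    @pytest.mark.parametrize(
        "kw", [{"eps_obj": 0.0}, {"eps_obj": 1.2}, {"eps_rs": -0.1}, {"tau_atm": 0.0}, {"tau_atm": 1.1}]
    )
    def test_out_of_range_parameters_rejected(self, kw):
        with pytest.raises(ValueError):
            make_inputs(**kw)


class TestFit:
    def test_two_points_interpolated_exactly(self):
        x = np.array([10.0, 60.0])
        y = 0.95 * x + 0.05
        cal = fit_linear_coefficients(x, np.zeros(2), y)
        assert cal.a == pytest.approx(0.95, rel=1e-12)
        assert cal.b == pytest.approx(0.05, rel=1e-9)
        assert cal.r_squared == pytest.approx(1.0)
        assert cal.n_conditions == 2

    def test_response_is_true_minus_thermistor(self):
        x = np.array([0.0, 10.0, 20.0, 30.0])
        w_tmt = np.full(4, 450.0)
        w_true = 450.0 + 0.9 * x + 0.2
        cal = fit_linear_coefficients(x, w_tmt, w_true)
        assert cal.a == pytest.approx(0.9, rel=1e-12)
        assert cal.b == pytest.approx(0.2, abs=1e-9)

    def test_noisy_recovery(self):
        rng = np.random.default_rng(7)
        x = np.linspace(-30.0, 60.0, 24)
        y = 0.926 * x + 0.07 + rng.normal(0, 0.01, 24)
        cal = fit_linear_coefficients(x, np.zeros(24), y)
        assert cal.a == pytest.approx(0.926, abs=5e-3)
        assert cal.r_squared > 0.999

    def test_rank_deficient_design_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            fit_linear_coefficients([5.0, 5.0, 5.0], [0.0] * 3, [1.0, 2.0, 3.0])

    def test_single_condition_rejected(self):
        with pytest.raises(ValueError):
            fit_linear_coefficients([5.0], [0.0], [1.0])


class TestCalibrationObject:
    def test_json_roundtrip(self, tmp_path):
        cal = CameraCalibration(
            "IRT-1", a=0.924892, b=0.0704166, r_squared=0.999931,
            n_conditions=24, fit_timestamp="2026-01-01T00:00:00",
        )
        path = tmp_path / "cal.json"
        cal.to_json(path)
        assert CameraCalibration.from_json(path) == cal

    def test_printed_coefficient_sets_serialize(self, tmp_path):
        # coefficient sets of the three reference cameras, as a format check
        printed = [
            ("IRT-1", 0.924892, 0.0704166, 0.999931),
            ("IRT-2", 0.9805749, 0.0821071, 0.99997),
            ("IRT-3", 1.1669497, -0.075513, 0.998043),
        ]
        for cam, a, b, r2 in printed:
            cal = CameraCalibration(cam, a=a, b=b, r_squared=r2, n_conditions=24)
            p = tmp_path / f"{cam}.json"
            cal.to_json(p)
            loaded = CameraCalibration.from_json(p)
            assert (loaded.a, loaded.b, loaded.r_squared) == (a, b, r2)

    @pytest.mark.parametrize(
        "kw",
        [
            {"a": 0.0},
            {"a": -0.5},
            {"r_squared": 1.5},
            {"n_conditions": 1},
            {"b": float("nan")},
        ],
    )
    def test_invalid_calibration_rejected(self, kw):
        base = dict(camera_id="c", a=1.0, b=0.0, r_squared=1.0, n_conditions=24)
        base.update(kw)
        with pytest.raises(ValueError):
            CameraCalibration(**base)
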