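import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fdkin import (
    FitFailureError,
    TimeCourse,
    fit_dose_response,
    fit_double_exponential,
    fit_isotherm,
    fit_reverse_fd,
    fit_single_exponential,
    kapp_conformational_selection,
    kapp_hyperbolic,
    kapp_linear,
    select_rate_law,
    subtract_sigmoid_drift,
)
from fdkin.fitting import sigmoid_drift
from fdkin.synth import (
    NOISELESS,
    ExperimentDesign,
    NoiseModel,
    gen_competition_courses,
    gen_decay_trace,
    gen_fp_titration,
)


def decay(t, k, s0=0.1, s1=1.0):
    return s0 + s1 * np.exp(-k * t)


class TestSingleExponential:
    def test_noiseless_recovery_is_exact(self):
        k = 1e-3
        t = np.linspace(0, 5 * np.log(2) / k, 200)
        res = fit_single_exponential(TimeCourse(t, decay(t, k)))
        assert res.reported_rate == pytest.approx(k, rel=1e-6)
        assert res.s0 == pytest.approx(0.1, abs=1e-8)
        assert res.amplitudes[0] == pytest.approx(1.0, rel=1e-6)

    def test_rise_direction_recovers_rate_and_amplitudes(self):
        k, s0, s1 = 2e-2, 5.0, 3.0
        t = np.linspace(0, 300, 200)
        y = s0 + s1 * (1 - np.exp(-k * t))
        res = fit_single_exponential(TimeCourse(t, y), direction="rise")
        assert res.reported_rate == pytest.approx(k, rel=1e-6)
        assert res.s0 == pytest.approx(s0, rel=1e-6)
        assert res.amplitudes[0] == pytest.approx(s1, rel=1e-6)

    def test_constant_signal_fails(self):
        t = np.linspace(0, 100, 50)
        with pytest.raises(FitFailureError):
            fit_single_exponential(TimeCourse(t, np.ones_like(t)))

    def test_one_percent_noise_recovers_within_two_percent(self):
        k = 1e-3
        t = np.linspace(0, 5 * np.log(2) / k, 200)
        y = decay(t, k, s0=0.0) + np.random.default_rng(7).normal(0, 0.01, t.size)
        res = fit_single_exponential(TimeCourse(t, y))
        assert res.reported_rate == pytest.approx(k, rel=0.02)

    def test_recovery_bias_under_repeated_noise(self):
        """Mean of 500 replicate estimates at 1 % noise stays within 0.5 %
        of the true rate (no systematic bias from the estimator)."""
        k = 1e-2
        t = np.linspace(0, 5 * np.log(2) / k, 200)
        clean = decay(t, k, s0=0.0)
        rng = np.random.default_rng(1234)
        est = [
            fit_single_exponential(TimeCourse(t, clean + rng.normal(0, 0.01, t.size))).reported_rate
            for _ in range(500)
        ]
        assert abs(np.mean(est) - k) / k < 0.005

    @given(scale=st.floats(min_value=0.01, max_value=100),
           offset=st.floats(min_value=-5, max_value=5))
    @settings(max_examples=20, derandomize=True, deadline=None)
    def test_affine_signal_invariance(self, scale, offset):
        """Rescaling the signal axis leaves the rate untouched and scales
        the amplitude."""
        k = 5e-3
        t = np.linspace(0, 2000, 120)
        y = decay(t, k)
        base = fit_single_exponential(TimeCourse(t, y))
        moved = fit_single_exponential(TimeCourse(t, scale * y + offset))
        assert moved.reported_rate == pytest.approx(base.reported_rate, rel=1e-6)
        assert moved.amplitudes[0] == pytest.approx(scale * base.amplitudes[0], rel=1e-5)


class TestDoubleExponential:
    def test_reports_faster_component_when_amplitude_sufficient(self):
        t = np.arange(0, 3000, 5.0)
        y = 0.1 + 0.7 * np.exp(-1e-2 * t) + 0.3 * np.exp(-1e-4 * t)
        res = fit_double_exponential(TimeCourse(t, y))
        assert res.reported_rate == pytest.approx(1e-2, rel=0.01)
        assert "faster" in res.selection_rule

    def test_amplitude_rule_overrides_for_minor_fast_component(self):
        t = np.arange(0, 30000, 30.0)
        y = 0.1 + 0.05 * np.exp(-1e-2 * t) + 0.95 * np.exp(-1e-4 * t)
        res = fit_double_exponential(TimeCourse(t, y))
        assert res.reported_rate == pytest.approx(1e-4, rel=0.01)
        assert "larger amplitude" in res.selection_rule

    def test_equal_rates_degrade_to_single(self):
        t = np.arange(0, 3000, 5.0)
        y = 0.1 + 1.0 * np.exp(-1e-3 * t)
        res = fit_double_exponential(TimeCourse(t, y))
        assert res.n_components == 1
        assert any("degraded_to_single" in w for w in res.warnings)
        assert res.reported_rate == pytest.approx(1e-3, rel=1e-4)


class TestDoseResponse:
    conc = 2e-6 / 2 ** np.arange(12)

    def test_linear_law_exact_recovery(self):
        k = kapp_linear(self.conc, 1e5, 1e-3)
        res = fit_dose_response(self.conc, k, "linear")
        assert res.params["k_on"] == pytest.approx(1e5, rel=1e-8)
        assert res.params["k_off"] == pytest.approx(1e-3, rel=1e-8)

    def test_hyperbolic_law_exact_recovery(self):
        k = kapp_hyperbolic(self.conc, 1e-2, 1e-7, 1e-5)
        res = fit_dose_response(self.conc, k, "hyperbolic")
        assert res.params["k_max"] == pytest.approx(1e-2, rel=1e-6)
        assert res.params["K_half"] == pytest.approx(1e-7, rel=1e-6)
        assert res.params["k_base"] == pytest.approx(1e-5, rel=1e-6)

    def test_conformational_selection_recovers_switch_rate(self):
        """Series produced by the 3-state eigenvalue law over a 12-point
        twofold dilution pins k_switch to within 5 %."""
        truth = dict(k_switch=5e-3, k_unswitch=5e-2, k_on=1e6, k_off=1e-5)
        k = kapp_conformational_selection(self.conc, **truth)
        res = fit_dose_response(self.conc, k, "conformational_selection")
        assert res.params["k_switch"] == pytest.approx(truth["k_switch"], rel=0.05)

    def test_constrained_hyperbolic_fits_only_K_half(self):
        k = kapp_hyperbolic(self.conc, 1e-2, 1e-7, 1e-5)
        res = fit_dose_response(self.conc, k, "hyperbolic",
                                fixed={"k_max": 1e-2, "k_base": 1e-5})
        assert res.params["k_max"] == 1e-2
        assert res.params["K_half"] == pytest.approx(1e-7, rel=1e-6)

    def test_unsaturated_series_warns_not_fails(self):
        conc = self.conc
        k = kapp_hyperbolic(conc, 1e-2, 1e-3, 1e-5)  # K_half far above top conc
        res = fit_dose_response(conc, k, "hyperbolic")
        assert any("wide_ci" in w for w in res.warnings)

    def test_duplicate_concentrations_rejected(self):
        with pytest.raises(ValueError):
            fit_dose_response([1e-6, 1e-6, 1e-7, 1e-8], [1, 1, 1, 1], "linear")


class TestSelectRateLaw:
    def test_discriminates_mechanisms_on_noisy_series(self):
        conc = 2e-6 / 2 ** np.arange(12)
        rng = np.random.default_rng(5)
        k_cs = kapp_conformational_selection(conc, 5e-3, 5e-2, 1e6, 1e-5)
        k_if = kapp_linear(conc, 1e5, 1e-3)
        for _ in range(5):
            noisy_cs = k_cs * (1 + 0.01 * rng.normal(size=conc.size))
            noisy_if = k_if * (1 + 0.01 * rng.normal(size=conc.size))
            assert select_rate_law(conc, noisy_cs)[0] == "hyperbolic"
            assert select_rate_law(conc, noisy_if)[0] == "linear"


class TestIsotherm:
    design = ExperimentDesign(top_conc=1e-6, n_points=24, include_zero=True)

    def test_round_trip_recovery_within_one_percent(self):
        df = gen_fp_titration(1e-8, 5e-10, 40.0, 160.0, self.design,
                              NoiseModel(sigma_frac=0.002, seed=3))
        res = fit_isotherm(df["conc_M"], df["polarization_mP"], 5e-10)
        assert res.K_d == pytest.approx(1e-8, rel=0.01)
        assert not res.tight_binding

    def test_tight_binding_reports_upper_bound_only(self):
        df = gen_fp_titration(1e-11, 1e-9, 40.0, 160.0, self.design, NOISELESS)
        res = fit_isotherm(df["conc_M"], df["polarization_mP"], 1e-9)
        assert res.tight_binding
        assert res.reported_affinity == "K_d < 1e-09 M"

    def test_flat_titration_fails(self):
        H = self.design.concentrations()
        with pytest.raises(FitFailureError):
            fit_isotherm(H, np.full_like(H, 55.0), 1e-9)


class TestReverseFD:
    design = ExperimentDesign(top_conc=16e-6, dilution_fold=2.0, n_points=10,
                              include_zero=True, duration_s=2000.0,
                              slow_duration_s=3.5e5, sampling_interval_s=4.0)
    truth = {"k_off_TH_E": 1e-2, "K_half": 1e-6, "k_off_H_E": 1e-5,
             "S0": 40.0, "S1": 120.0}

    def _courses(self, noise):
        cs = gen_competition_courses("reverse", dict(self.truth), self.design, noise)
        return [(tc.metadata["conc_M"], tc) for tc in cs]

    def test_exact_generator_round_trip(self):
        res = fit_reverse_fd(self._courses(NOISELESS))
        assert res.params["k_off_TH_E"] == pytest.approx(1e-2, rel=0.02)
        assert res.params["K_half"] == pytest.approx(1e-6, rel=0.02)
        assert res.params["k_off_H_E"] == pytest.approx(1e-5, rel=0.02)

    def test_zero_and_midpoint_courses_obey_hyperbola(self):
        pairs = self._courses(NOISELESS)
        by_conc = dict(pairs)
        k_zero = fit_single_exponential(by_conc[0.0]).reported_rate
        assert k_zero == pytest.approx(self.truth["k_off_H_E"], rel=1e-3)
        k_mid = kapp_hyperbolic(self.truth["K_half"], self.truth["k_off_TH_E"],
                                self.truth["K_half"], self.truth["k_off_H_E"])
        assert k_mid == pytest.approx(self.truth["k_off_H_E"] + self.truth["k_off_TH_E"] / 2)

    def test_missing_zero_course_rejected(self):
        pairs = [(c, tc) for c, tc in self._courses(NOISELESS) if c > 0]
        with pytest.raises(FitFailureError, match="zero-target"):
            fit_reverse_fd(pairs)


class TestSigmoidDrift:
    t = np.arange(0, 3600, 4.0)
    drift_truth = {"S0": 1.0, "S1": 0.5, "k": 0.003, "t_half": 1200.0}

    def test_drift_plus_exponential_round_trip(self):
        d = sigmoid_drift(self.t, **self.drift_truth)
        target = 0.8 * np.exp(-2e-3 * self.t)
        out = subtract_sigmoid_drift(
            TimeCourse(self.t, d + target), TimeCourse(self.t, d))
        assert np.max(np.abs(out.signal - target)) < 1e-6
        fitted = out.metadata["drift_params"]
        mid = sigmoid_drift(fitted["t_half"], **fitted)
        assert mid == pytest.approx(fitted["S0"] + fitted["S1"] / 2, rel=1e-9)

    def test_constant_reference_subtracts_constant(self):
        ref = TimeCourse(self.t, np.full_like(self.t, 2.5))
        tc = TimeCourse(self.t, np.sin(self.t / 500) + 2.5)
        out = subtract_sigmoid_drift(tc, ref)
        assert np.allclose(out.signal, np.sin(self.t / 500))
        assert "drift_warning" in out.metadata
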