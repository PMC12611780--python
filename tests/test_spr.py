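import copy
import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

from fdkin import (
    ChipParams,
    NoiseModel,
    chip_ode_rhs,
    chip_trajectory,
    compute_keff,
    gen_cycleset,
    global_fit,
    kapp_hyperbolic,
    propagate_cycles,
    response_model,
    summarize_fd,
)
from fdkin.spr import Cycle, CycleSet, _two_state_matrix
from fdkin.synth import NOISELESS, spr_design_for


class TestChipODE:
    params = ChipParams(k_off_T_H=1e-5, k_off_T_HE=0.057, k_on_TH_E=1e6,
                        k_off_TH_E=1e-3, k_off_T_Hn=2e-5)

    def test_zero_effector_reduces_to_base_decay(self):
        d = chip_ode_rhs([0.0, 0.8, 0.0], 0.0, self.params)
        assert d[0] == 0.0
        assert d[1] == pytest.approx(-self.params.k_off_T_H * 0.8)

    def test_bound_host_only_decreases(self):
        state = [0.3, 0.5, 0.1]
        d = chip_ode_rhs(state, 1e-6, self.params)
        p = self.params
        expected = -(p.k_off_T_HE * 0.3 + p.k_off_T_H * 0.5 + p.k_off_T_Hn * 0.1)
        assert np.sum(d) == pytest.approx(expected)
        assert np.sum(d) <= 0

    def test_quasi_equilibrium_partitioning(self):
        """With effector binding much faster than target release, THE/TH
        settles at the binding quasi-equilibrium k_on[E] / k_off_TH_E
        (the slow eigenvector of the two-state block)."""
        p = ChipParams(k_off_T_H=1e-5, k_off_T_HE=1e-3, k_on_TH_E=1e6,
                       k_off_TH_E=1e-3, k_off_T_Hn=1e-5)
        E = 1e-6  # k_on[E] = 1 s^-1 >> off-rates
        t_eq = 20.0  # many fast relaxation times, decays still negligible
        traj = chip_trajectory([0.0, 1.0, 0.0], E, p, np.array([t_eq, 2 * t_eq]))
        ratio = traj[0, -1] / traj[1, -1]
        expected = p.k_on_TH_E * E / p.k_off_TH_E
        assert ratio == pytest.approx(expected, rel=0.01)

    def test_exact_propagator_matches_ode_solver(self):
        """Dual route: the eigen-decomposition propagator vs scipy solve_ivp."""
        t = np.linspace(0, 600, 301)
        x0 = [0.0, 0.9, 0.1]
        exact = chip_trajectory(x0, 2e-7, self.params, t)
        sol = solve_ivp(lambda tt, y: chip_ode_rhs(y, 2e-7, self.params),
                        (0, 600), x0, t_eval=t, rtol=1e-10, atol=1e-14)
        assert np.max(np.abs(exact - sol.y)) < 1e-8


class TestPropagateCycles:
    def _cycles(self, concs, duration=600.0):
        t = np.arange(0.0, duration + 1, 10.0)
        return CycleSet([Cycle(c, t, np.zeros_like(t)) for c in concs])

    def test_fully_responsive_host_never_accumulates(self, chip_truth):
        p = ChipParams(**{**chip_truth.to_dict(), "f_responsive": 1.0})
        initials, finals = propagate_cycles(self._cycles([0.0, 1e-6, 1e-6]), p)
        assert all(x0[2] == 0.0 for x0 in initials)

    def test_unresponsive_host_is_never_replenished_responsively(self, chip_truth):
        p = ChipParams(**{**chip_truth.to_dict(), "f_responsive": 0.0})
        initials, finals = propagate_cycles(self._cycles([1e-6, 1e-6]), p)
        assert initials[1][1] == pytest.approx(finals[0][1])

    def test_hand_recursion_after_full_dissociation(self):
        """f_responsive = 0.9, cycle 1 dissociates completely: the second
        cycle starts with exactly 10 % unresponsive complex."""
        p = ChipParams(k_off_T_H=1e-2, k_off_T_HE=1e-1, k_on_TH_E=1e6,
                       k_off_TH_E=1e-3, k_off_T_Hn=1e-2, f_responsive=0.9)
        cs = self._cycles([0.0, 0.0], duration=20000.0)  # >> all half-lives
        initials, _ = propagate_cycles(cs, p)
        assert initials[0][1] == pytest.approx(0.9)
        assert initials[0][2] == pytest.approx(0.1)
        assert initials[1][2] == pytest.approx(0.1, rel=1e-6)

    def test_unresponsive_fraction_monotone_across_cycles(self, rng):
        # accumulation is monotone when the unresponsive complex is stable
        # on the cycle timescale (the regime the chip model describes)
        for _ in range(50):
            p = ChipParams(
                k_off_T_H=10 ** rng.uniform(-5, -3),
                k_off_T_HE=10 ** rng.uniform(-3, -1),
                k_on_TH_E=10 ** rng.uniform(5, 7),
                k_off_TH_E=10 ** rng.uniform(-4, -2),
                k_off_T_Hn=10 ** rng.uniform(-6, math.log10(3e-5)),
                f_responsive=rng.uniform(0.5, 0.98),
            )
            concs = list(2e-6 / 2 ** np.arange(6))
            initials, _ = propagate_cycles(self._cycles(concs), p)
            thn = [x0[2] for x0 in initials]
            assert np.all(np.diff(thn) >= -1e-12)


class TestResponseModel:
    def test_equal_amplitudes_reduce_to_total_bound(self):
        traj = np.array([[0.1, 0.2], [0.5, 0.4], [0.2, 0.2]])
        p = ChipParams(1e-5, 1e-3, 1e6, 1e-3, 1e-5, a_TH=2.0, a_THE=2.0, a_THn=2.0)
        s = response_model(traj, p, f_n=1.0)
        assert np.allclose(s, 2.0 * traj.sum(axis=0))

    def test_cycle_factor_scales_linearly(self):
        traj = np.array([[0.1], [0.5], [0.2]])
        p = ChipParams(1e-5, 1e-3, 1e6, 1e-3, 1e-5, a_TH=1.0, a_THE=1.2, a_THn=0.9)
        assert response_model(traj, p, 2.0) == pytest.approx(2 * response_model(traj, p, 1.0))


class TestGlobalFit:
    def test_noiseless_recovery_is_essentially_exact(self, chip_truth, coarse_design):
        cs = gen_cycleset(chip_truth, coarse_design, NOISELESS)
        fit = global_fit(cs)
        for name in ("k_off_T_H", "k_off_T_HE", "f_responsive"):
            assert getattr(fit.params, name) == pytest.approx(
                getattr(chip_truth, name), rel=1e-3), name

    def test_noisy_recovery_within_five_percent(self, chip_truth, coarse_design,
                                                noise_half_pct):
        cs = gen_cycleset(chip_truth, coarse_design, noise_half_pct)
        fit = global_fit(cs)
        for name in ("k_off_T_H", "k_off_T_HE", "f_responsive"):
            assert getattr(fit.params, name) == pytest.approx(
                getattr(chip_truth, name), rel=0.05), name
        assert any("weak_identifiability" in w for w in fit.warnings)

    def test_effector_binding_covariance_leaves_off_rates_unchanged(self, chip_truth,
                                                                    coarse_design):
        """Scaling (k_on_TH_E, k_off_TH_E) jointly by 3 (ratio preserved,
        both fast) must not move the fitted target off-rates by more than
        2 % -- the documented covariance of the effector-binding pair."""
        scaled = ChipParams(**{**chip_truth.to_dict(),
                               "k_on_TH_E": chip_truth.k_on_TH_E * 3,
                               "k_off_TH_E": chip_truth.k_off_TH_E * 3})
        fits = []
        for p in (chip_truth, scaled):
            cs = gen_cycleset(p, copy.deepcopy(coarse_design),
                              NoiseModel(sigma_frac=0.005, seed=99))
            fits.append(global_fit(cs))
        for name in ("k_off_T_H", "k_off_T_HE"):
            a, b = (getattr(f.params, name) for f in fits)
            assert a == pytest.approx(b, rel=0.02), name

    def test_single_cycle_fully_responsive_equals_direct_two_state_fit(self):
        """With f_responsive = 1 and one cycle the global model is exactly
        the two-state chip model, so an independent direct fit of that cycle
        must land on the same optimum."""
        truth = ChipParams(k_off_T_H=1e-4, k_off_T_HE=1e-2, k_on_TH_E=1e6,
                           k_off_TH_E=1e-3, k_off_T_Hn=1e-4, f_responsive=1.0,
                           a_TH=1.0, a_THE=1.15, a_THn=1.0)
        E = 3e-9  # partial saturation: both decay branches visible
        t = np.arange(0.0, 6000.0, 5.0)
        traj = chip_trajectory([0.0, 1.0, 0.0], E, truth, t)
        signal = response_model(traj, truth, 1.0)
        cs = CycleSet([Cycle(E, t, signal)])
        # the weakly-identified effector pair is pinned in both routes, and
        # both start near the same branch: a single-cycle bi-exponential has
        # an exact discrete swap symmetry in (k_off_T_H, k_off_T_HE)
        common = {"f_responsive": 1.0, "k_off_T_Hn": 1e-4, "a_THn": 1.0,
                  "k_on_TH_E": 1e6, "k_off_TH_E": 1e-3}
        fit = global_fit(cs, fixed=common,
                         init={"k_off_T_H": 3e-4, "k_off_T_HE": 5e-3})

        def direct_resid(x):
            p = ChipParams(k_off_T_H=10 ** x[0], k_off_T_HE=10 ** x[1],
                           k_on_TH_E=1e6, k_off_TH_E=1e-3,
                           k_off_T_Hn=1e-4, f_responsive=1.0,
                           a_TH=x[2], a_THE=x[3], a_THn=1.0)
            tr = chip_trajectory([0.0, 1.0, 0.0], E, p, t)
            return response_model(tr, p, 1.0) - signal

        sol = least_squares(direct_resid, [-4.3, -2.3, 0.9, 1.0],
                            bounds=([-7, -7, 0.01, 0.01], [0, 0, 10, 10]),
                            xtol=1e-14, ftol=1e-14, gtol=1e-14)
        assert fit.params.k_off_T_H == pytest.approx(10 ** sol.x[0], rel=1e-3)
        assert fit.params.k_off_T_HE == pytest.approx(10 ** sol.x[1], rel=1e-3)
        assert fit.params.k_off_T_H == pytest.approx(truth.k_off_T_H, rel=1e-3)


class TestComputeKeff:
    params = ChipParams(k_off_T_H=1e-5, k_off_T_HE=0.057, k_on_TH_E=1e6,
                        k_off_TH_E=1e-3, k_off_T_Hn=2e-5)

    def test_zero_effector_gives_base_rate(self):
        assert compute_keff(self.params, 0.0) == pytest.approx(1e-5, rel=1e-9)

    def test_saturating_effector_gives_accelerated_rate(self):
        p = ChipParams(k_off_T_H=1e-5, k_off_T_HE=1e-2, k_on_TH_E=1e6,
                       k_off_TH_E=0.0, k_off_T_Hn=1e-5)
        E = 1e3 * p.k_off_T_HE / p.k_on_TH_E
        assert compute_keff(p, E) == pytest.approx(p.k_off_T_HE, rel=0.005)

    def test_matches_dense_grid_half_time_oracle(self):
        """Independent route: 1e6-point dense integration + interpolation."""
        E = 1e-7
        keff = compute_keff(self.params, E)
        M = _two_state_matrix(self.params, E)
        t = np.linspace(0, 5 * math.log(2) / keff, 10 ** 6)
        sol = solve_ivp(lambda s, y: M @ y, (0, t[-1]), [0.0, 1.0],
                        t_eval=t, rtol=1e-10, atol=1e-14)
        bound = sol.y.sum(axis=0)
        i = int(np.argmax(bound < 0.5))
        t_half = np.interp(0.5, [bound[i], bound[i - 1]], [t[i], t[i - 1]])
        assert keff == pytest.approx(math.log(2) / t_half, rel=1e-6)

    def test_monotone_in_effector_when_accelerating(self, rng):
        for _ in range(50):
            p = ChipParams(
                k_off_T_H=10 ** rng.uniform(-6, -4),
                k_off_T_HE=10 ** rng.uniform(-3, -1),
                k_on_TH_E=10 ** rng.uniform(4, 7),
                k_off_TH_E=10 ** rng.uniform(-4, -2),
                k_off_T_Hn=1e-5,
            )
            E = np.geomspace(1e-10, 1e-5, 8)
            keff = [compute_keff(p, e) for e in E]
            assert np.all(np.diff(keff) >= -1e-12 * np.max(keff))


class TestSummarizeFD:
    # rapid-equilibrium regime (effector binding fast vs target release),
    # where k_eff is exactly hyperbolic with K_half = k_off_TH_E / k_on_TH_E
    params = ChipParams(k_off_T_H=1e-4, k_off_T_HE=1e-2, k_on_TH_E=1e7,
                        k_off_TH_E=1e-1, k_off_T_Hn=1e-4)

    def test_fold_acceleration_is_rate_ratio(self):
        _, fold = summarize_fd(self.params, np.geomspace(1e-9, 1e-5, 10))
        assert fold == pytest.approx(100.0)

    def test_constrained_hyperbola_describes_keff_curve(self):
        E = np.geomspace(1e-9, 1e-5, 12)
        series, _ = summarize_fd(self.params, E)
        assert series.params["k_max"] == self.params.k_off_T_HE - self.params.k_off_T_H
        assert series.rms < 0.01 * self.params.k_off_T_HE

    def test_K_half_matches_midpoint_of_keff(self):
        E = np.geomspace(1e-9, 1e-5, 12)
        series, _ = summarize_fd(self.params, E)
        K = series.params["K_half"]
        mid = 0.5 * (self.params.k_off_T_H + self.params.k_off_T_HE)
        assert compute_keff(self.params, K) == pytest.approx(mid, rel=0.05)
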