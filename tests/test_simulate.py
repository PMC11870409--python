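"""Integration contracts: closed-form agreement, resets, delays, linearity."""

import math

import numpy as np
import pytest

from sflt1kin.model_core import (
    ModelSpec,
    ParameterSet,
    Phase,
    SystemState,
    compound_constants,
    steady_state,
)
from sflt1kin.simulate import (
    ConvergenceError,
    ScenarioConfig,
    integrate_segment,
    normalize_trajectory,
    run_to_steady_state,
    simulate_constitutive,
    simulate_pulse_chase,
)

M1 = ModelSpec()
M2 = ModelSpec(has_delay=True)


def _m1_params(median_params):
    return median_params.restricted_to(M1)


class TestIntegrateSegment:
    def test_ode_accumulation_matches_closed_form(self, median):
        # from I = I_SS, X = 0 the extracellular pool follows
        # X(t) = X_SS * (1 - exp(-delta t))
        p = _m1_params(median[0])
        ss = steady_state(p)
        traj = integrate_segment(
            p, M1, SystemState(ss.I_SS, 0.0), None, (0.0, 24.0), Phase.CONSTITUTIVE
        )
        expected = ss.X_SS * (1 - np.exp(-p.delta * traj.times))
        assert np.allclose(traj.X[1:], expected[1:], rtol=1e-3)
        assert np.allclose(traj.I, ss.I_SS, rtol=1e-6)

    def test_null_parameters_keep_state_constant(self):
        p = ParameterSet(0, 0, 0, 0)
        traj = integrate_segment(p, M1, SystemState(3.0, 7.0), None, (0.0, 5.0), "presim")
        assert np.all(traj.I == 3.0) and np.all(traj.X == 7.0)

    def test_delayed_kernel_matches_closed_form_from_steady_history(self, median):
        # constant history at I_SS keeps I pinned and X follows the same
        # closed form as the non-delayed model
        p, spec = median
        ss = steady_state(p)
        traj = integrate_segment(
            p, spec, SystemState(ss.I_SS, 0.0), lambda t: np.full_like(t, ss.I_SS),
            (0.0, 72.0), Phase.CONSTITUTIVE,
        )
        expected = ss.X_SS * (1 - np.exp(-p.delta * traj.times))
        assert np.allclose(traj.X[1:], expected[1:], rtol=1e-3)
        assert traj.X[-1] == pytest.approx(ss.X_SS * (1 - math.exp(-p.delta * 72)), rel=1e-3)


class TestRunToSteadyState:
    def test_reference_parameters_reach_analytic_steady_state(self, median):
        p, spec = median
        state, hist = run_to_steady_state(p, spec)
        assert state.I == pytest.approx(steady_state(p).I_SS, rel=0.005)
        assert hist(state.t) == pytest.approx(state.I)
        assert hist(-1e6) == 0.0

    def test_empty_production_converges_at_zero(self):
        state, _ = run_to_steady_state(ParameterSet(0, 0.1, 0.1, 0.05), M1)
        assert state.I == 0.0

    def test_no_intracellular_degradation_limit(self, median):
        c = compound_constants(median[0])
        p = ParameterSet(c.c1 / c.c2, c.c2, 0.0, 0.057)
        state, _ = run_to_steady_state(p, M1)
        assert state.I == pytest.approx(p.alpha / p.beta, rel=0.005)

    def test_slow_kinetics_exceed_presim_cap(self):
        p = ParameterSet(1e5, 5e-5, 5e-5, 0.05)
        with pytest.raises(ConvergenceError):
            run_to_steady_state(p, M1, ScenarioConfig(presim_cap=200.0))


class TestConstitutive:
    def test_intracellular_stays_at_steady_state(self, median):
        p, spec = median
        traj = simulate_constitutive(p, spec)
        i_ss = steady_state(p).I_SS
        assert np.allclose(traj.I, i_ss, rtol=0.005)
        assert len(traj.times) == 72 * 60 + 1

    def test_reset_contract(self, median):
        p, spec = median
        traj = simulate_constitutive(p, spec)
        assert traj.X[0] == 0.0
        # I carried over the media change unchanged
        assert traj.I[0] == pytest.approx(steady_state(p).I_SS, rel=0.005)

    def test_fast_extracellular_turnover_plateaus_early(self, median):
        p = _m1_params(median[0]).scaled(delta=10.0)
        traj = simulate_constitutive(p, M1, ScenarioConfig(duration=24.0))
        ss = steady_state(p)
        half_idx = np.argmax(traj.X >= ss.X_SS / 2)
        assert traj.times[half_idx] == pytest.approx(math.log(2) / p.delta, abs=2 / 60)

    def test_no_production_is_identically_zero(self):
        p = ParameterSet(0, 0.05, 0.12, 0.06)
        traj = simulate_constitutive(p, M1)
        assert np.all(traj.I == 0) and np.all(traj.X == 0)

    def test_linearity_in_alpha(self, median):
        p, spec = median
        base = simulate_constitutive(p, spec)
        scaled = simulate_constitutive(p.scaled(alpha=3.0), spec)
        assert np.allclose(scaled.I, 3 * base.I, rtol=1e-9)
        assert np.allclose(scaled.X, 3 * base.X, rtol=1e-9)


class TestPulseChase:
    def test_no_labeled_secretion_before_maturation(self, median):
        p, spec = median
        traj = simulate_pulse_chase(p, spec, ScenarioConfig(duration=10.0))
        dead_time = p.tau - 1.0 / 3.0
        chase = traj.times >= 0
        assert np.all(traj.X[chase & (traj.times < dead_time - 1e-9)] == 0.0)
        assert traj.value_at("X", dead_time + 0.5) > 0.0

    def test_pulse_fills_intracellular_pool_linearly(self, median):
        # with tau > pulse length no labeled protein leaves during the pulse
        p, spec = median
        traj = simulate_pulse_chase(p, spec, ScenarioConfig(duration=10.0))
        assert traj.value_at("I", 0.0) == pytest.approx(p.alpha / 3.0, rel=1e-9)

    def test_delayed_decay_closed_form_at_t_tau(self, median):
        # for t in (tau - pulse, tau): I(t) = alpha/3 - c2*alpha*(t-tau+1/3)^2/2
        p, spec = median
        traj = simulate_pulse_chase(p, spec, ScenarioConfig(duration=10.0))
        c2 = p.beta + p.gamma
        expected = p.alpha / 3.0 - c2 * p.alpha * (1.0 / 3.0) ** 2 / 2.0
        assert traj.value_at("I", p.tau) == pytest.approx(expected, rel=1e-4)

    def test_ode_model_secretes_immediately(self, median):
        p = _m1_params(median[0])
        traj = simulate_pulse_chase(p, M1, ScenarioConfig(duration=10.0))
        assert traj.value_at("X", 2.0 / 60.0) > 0.0

    def test_reset_and_continuity_at_media_change(self, median):
        p, spec = median
        traj = simulate_pulse_chase(p, spec, ScenarioConfig(duration=10.0))
        i0 = np.flatnonzero(traj.times == 0.0)[0]
        assert traj.X[i0] == 0.0
        assert traj.X[i0 - 1] > 0 or traj.I[i0 - 1] > 0  # pulse actually ran
        step = traj.times[i0] - traj.times[i0 - 1]
        assert abs(traj.I[i0] - traj.I[i0 - 1]) < 2 * p.alpha * step

    def test_no_production_stays_empty(self):
        p = ParameterSet(0, 0.05, 0.12, 0.06, tau=2.0)
        traj = simulate_pulse_chase(p, M2, ScenarioConfig(duration=5.0))
        assert np.all(traj.I == 0) and np.all(traj.X == 0)


class TestDelayLimit:
    def test_vanishing_delay_reproduces_ode_model(self, median):
        p1 = _m1_params(median[0])
        p2 = ParameterSet(**{**p1.as_dict(), "tau": 1e-6})
        a = simulate_constitutive(p1, M1, ScenarioConfig(duration=24.0))
        b = simulate_constitutive(p2, M2, ScenarioConfig(duration=24.0))
        scale = a.X.max()
        assert np.allclose(b.X, a.X, atol=1e-3 * scale, rtol=1e-3)
        assert np.allclose(b.I, a.I, rtol=1e-3)

    def test_small_but_resolved_delay_stays_close_to_ode(self, median):
        # tau = 18 s exercises the delayed kernel proper (step = tau)
        p1 = _m1_params(median[0])
        p2 = ParameterSet(**{**p1.as_dict(), "tau": 5e-3})
        a = simulate_constitutive(p1, M1, ScenarioConfig(duration=24.0))
        b = simulate_constitutive(p2, M2, ScenarioConfig(duration=24.0))
        c2 = p1.beta + p1.gamma
        tol = max(5 * c2 * 5e-3, 1e-3)  # O(tau) perturbation bound
        assert np.allclose(b.X, a.X, rtol=tol, atol=tol * a.X.max())


class TestMassFlow:
    @pytest.mark.parametrize("scenario", ["constitutive", "pulse_chase"])
    def test_finite_difference_dX_matches_rate_terms(self, median, scenario):
        p, spec = median
        if scenario == "constitutive":
            traj = simulate_constitutive(p, spec, ScenarioConfig(duration=24.0))
        else:
            traj = simulate_pulse_chase(p, spec, ScenarioConfig(duration=10.0))
        t, X = traj.times, traj.X
        interior = slice(1, -1)
        dxdt = (X[2:] - X[:-2]) / (t[2:] - t[:-2])
        expected = p.beta * traj.I_delayed[interior] - p.delta * X[interior]
        # exclude the media-change discontinuity and, in pulse-chase, the
        # kink times where the delayed secretion term is non-smooth
        keep = np.abs(t[interior]) > 2.0 / 60.0
        if scenario == "pulse_chase":
            for kink in (p.tau - 1.0 / 3.0, p.tau):
                keep &= np.abs(t[interior] - kink) > 3.0 / 60.0
        scale = np.abs(expected[keep]).max()
        assert np.allclose(dxdt[keep], expected[keep], atol=2e-3 * scale)


class TestNormalization:
    def test_anchors_become_one(self, median):
        p, spec = median
        traj = simulate_constitutive(p, spec)
        norm = normalize_trajectory(traj, anchor_X=24.0, anchor_I=0.0)
        assert norm.value_at("X", 24.0) == pytest.approx(1.0)
        assert norm.value_at("I", 0.0) == pytest.approx(1.0)
        assert norm.units == "relative"
        assert norm.value_at("X", 72.0) == pytest.approx(
            traj.value_at("X", 72.0) / traj.value_at("X", 24.0)
        )

    def test_normalized_trajectory_invariant_to_alpha(self, median):
        p, spec = median
        a = normalize_trajectory(simulate_constitutive(p, spec), 24.0, 0.0)
        b = normalize_trajectory(simulate_constitutive(p.scaled(alpha=5.0), spec), 24.0, 0.0)
        assert np.allclose(a.X, b.X, rtol=1e-9)
        assert np.allclose(a.I, b.I, rtol=1e-9)

    def test_zero_anchor_rejected(self, median):
        p, spec = median
        traj = simulate_constitutive(p, spec)
        with pytest.raises(ValueError, match="anchor"):
            normalize_trajectory(traj, anchor_X=0.0, anchor_I=0.0)  # X(0) = 0


class TestTrajectoryExport:
    def test_tidy_frame_schema(self, median):
        p, spec = median
        traj = simulate_constitutive(p, spec, ScenarioConfig(duration=1.0))
        df = traj.to_frame()
        assert list(df.columns) == ["time_h", "species", "value", "phase", "units"]
        assert set(df["species"]) == {"I", "X"}
        assert len(df) == 2 * len(traj.times)
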