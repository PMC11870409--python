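"""Closed-form quantities: steady states, compound constants, bounds, rates."""

import math

import pytest
import yaml
from hypothesis import given
from hypothesis import strategies as st

from sflt1kin.model_core import (
    CompoundConstants,
    DegenerateParameterError,
    ModelSpec,
    ParameterSet,
    Phase,
    SystemState,
    all_model_specs,
    compound_constants,
    load_parameters,
    model_from_id,
    params_from_beta,
    rate_terms,
    save_parameters,
    steady_state,
    theoretical_bounds,
)

M1 = ModelSpec()
M2 = ModelSpec(has_delay=True)

rates = st.floats(min_value=1e-4, max_value=10.0, allow_nan=False)
alphas = st.floats(min_value=1e2, max_value=1e7, allow_nan=False)


class TestModelSpec:
    def test_ids_are_a_bijection_with_flags(self):
        specs = all_model_specs()
        assert len({s.model_id for s in specs}) == 8
        assert M1.model_id == "M1" and M1.n_processes == 0
        assert M2.model_id == "M2"
        assert model_from_id("m2") == M2

    def test_degrees_of_freedom_count_active_parameters(self):
        assert M1.k_dof == 5  # alpha, beta, gamma, delta + 1
        assert M2.k_dof == 6
        assert model_from_id("M8").k_dof == 8

    def test_unknown_id_rejected(self):
        with pytest.raises(ValueError, match="unknown model id"):
            model_from_id("M9")


class TestRateTerms:
    def test_empty_system_produces_at_rate_alpha(self, median):
        params, _ = median
        dI, dX = rate_terms(SystemState(0, 0), 0.0, params, M1, Phase.CONSTITUTIVE)
        assert dI == pytest.approx(1.419e5)
        assert dX == 0.0

    def test_null_system_is_stationary(self):
        zero = ParameterSet(0, 0, 0, 0)
        for spec in all_model_specs():
            assert rate_terms(SystemState(5, 5), 5.0, zero, spec, "presim") == (0, 0)

    def test_delayed_model_stationary_at_steady_state(self, median):
        # with I(t - tau) = I_SS and X = X_SS both derivatives vanish
        params, spec = median
        ss = steady_state(params)
        dI, dX = rate_terms(
            SystemState(ss.I_SS, ss.X_SS), ss.I_SS, params, spec, Phase.CONSTITUTIVE
        )
        assert abs(dI) < 1e-8 * params.alpha
        assert abs(dX) < 1e-8 * params.alpha

    def test_chase_production_switches_off_or_decays(self, median):
        params, _ = median
        dI, _ = rate_terms(SystemState(0, 0), 0.0, params, M2, Phase.CHASE, 1.0)
        assert dI == 0.0
        decay_spec = model_from_id("M6")
        decayed = ParameterSet(
            params.alpha, params.beta, params.gamma, params.delta, params.tau, 0.0, 2.0
        )
        dI, _ = rate_terms(SystemState(0, 0), 0.0, decayed, decay_spec, Phase.CHASE, 1.0)
        assert dI == pytest.approx(params.alpha * math.exp(-2.0))

    def test_internalization_moves_protein_inward(self):
        spec = model_from_id("M3")
        p = ParameterSet(0, 0, 0, 0, epsilon=0.5)
        dI, dX = rate_terms(SystemState(0, 10), 0.0, p, spec, "constitutive")
        assert dI == pytest.approx(5.0)
        assert dX == pytest.approx(-5.0)

    def test_invalid_inputs_rejected(self, median):
        params, _ = median
        with pytest.raises(ValueError):
            rate_terms(SystemState(0, 0), -1.0, params, M1, "constitutive")
        with pytest.raises(ValueError):
            rate_terms(SystemState(0, 0), 0.0, params, M2, Phase.CHASE)  # no clock
        with pytest.raises(ValueError):
            rate_terms(SystemState(0, 0), 0.0, params, M1, "warmup")


class TestSteadyState:
    def test_reference_steady_state_matches_reported_median(self, median):
        params, _ = median
        ss = steady_state(params)
        assert ss.I_SS == pytest.approx(8.2e5, rel=0.01)
        assert ss.X_SS == pytest.approx(7.33e5, rel=1e-3)
        assert ss.T50_X == pytest.approx(12.07, rel=1e-3)
        assert ss.X_SS == pytest.approx(params.beta / params.delta * ss.I_SS)

    def test_no_production_means_empty_system(self):
        ss = steady_state(ParameterSet(0, 0.1, 0.1, 0.05))
        assert ss.I_SS == 0 and ss.X_SS == 0

    def test_degenerate_denominators_raise(self):
        with pytest.raises(DegenerateParameterError):
            steady_state(ParameterSet(1e5, 0, 0, 0.05))
        with pytest.raises(DegenerateParameterError):
            steady_state(ParameterSet(1e5, 0.1, 0.1, 0))


class TestCompoundConstants:
    def test_reference_values_match_reported_medians(self, median):
        params, _ = median
        c = compound_constants(params)
        assert c.c1 == pytest.approx(7.269e3, rel=1e-3)
        assert c.c2 == pytest.approx(1.727e-1, rel=1e-3)

    def test_no_secretion_degenerates_to_gamma(self):
        c = compound_constants(ParameterSet(1e5, 0, 0.2, 0.05))
        assert c.c1 == 0 and c.c2 == pytest.approx(0.2)

    @given(alpha=alphas, beta=rates, gamma=rates, delta=rates)
    def test_steady_state_identity(self, alpha, beta, gamma, delta):
        # I_SS * c2 == alpha to 10 significant digits (algebraic identity)
        p = ParameterSet(alpha, beta, gamma, delta)
        c = compound_constants(p)
        assert steady_state(p).I_SS * c.c2 == pytest.approx(alpha, rel=1e-10)


class TestParamsFromBeta:
    def test_beta_at_ceiling_removes_intracellular_degradation(self, median):
        c = compound_constants(median[0])
        p = params_from_beta(c.c2, c, delta=0.057, tau=1.958)
        assert p.gamma == 0.0
        assert p.alpha == pytest.approx(c.c1 / c.c2)

    def test_midpoint_splits_c2_evenly(self):
        c = CompoundConstants(c1=7269.0, c2=0.1727)
        p = params_from_beta(c.c2 / 2, c, delta=0.057)
        assert p.gamma == pytest.approx(c.c2 / 2)

    def test_low_beta_arithmetic(self):
        c = CompoundConstants(c1=7269.0, c2=0.1727)
        p = params_from_beta(0.2 * c.c2, c, delta=0.057)
        assert p.alpha == pytest.approx(7269.0 / (0.2 * 0.1727))

    @pytest.mark.parametrize("beta", [0.0, -0.1, 0.2])
    def test_out_of_range_beta_rejected(self, beta):
        with pytest.raises(ValueError, match="beta"):
            params_from_beta(beta, CompoundConstants(7269.0, 0.1727), delta=0.057)

    @given(alpha=alphas, beta=rates, gamma=rates, delta=rates)
    def test_round_trip_recovers_parameters(self, alpha, beta, gamma, delta):
        p = ParameterSet(alpha, beta, gamma, delta, tau=1.0)
        c = compound_constants(p)
        q = params_from_beta(beta, c, delta, tau=1.0)
        assert q.alpha == pytest.approx(alpha, rel=1e-12)
        assert q.gamma == pytest.approx(gamma, rel=1e-9, abs=1e-12)


class TestTheoreticalBounds:
    def test_reference_bounds(self, median):
        c = compound_constants(median[0])
        b = theoretical_bounds(c)
        assert b["min_I_SS"] == pytest.approx(2.44e5, rel=2e-3)
        assert b["min_alpha"] == pytest.approx(c.c1 / c.c2)
        assert b["max_beta"] == b["max_gamma"] == c.c2

    def test_unit_constants(self):
        b = theoretical_bounds(CompoundConstants(1.0, 1.0))
        assert set(b.values()) == {1.0}

    @given(beta_frac=st.floats(min_value=0.01, max_value=1.0))
    def test_family_respects_bounds(self, beta_frac, median):
        c = compound_constants(median[0])
        b = theoretical_bounds(c)
        p = params_from_beta(beta_frac * c.c2, c, delta=0.057)
        assert steady_state(p).I_SS >= b["min_I_SS"] * (1 - 1e-12)
        assert p.alpha >= b["min_alpha"] * (1 - 1e-12)


class TestParameterSet:
    def test_negative_or_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            ParameterSet(-1, 0.1, 0.1, 0.05)
        with pytest.raises(ValueError):
            ParameterSet(float("nan"), 0.1, 0.1, 0.05)

    def test_inactive_process_parameters_must_be_zero(self, median):
        params, _ = median
        with pytest.raises(ValueError, match="tau"):
            params.validate_for(M1)
        params.restricted_to(M1).validate_for(M1)

    def test_yaml_round_trip(self, tmp_path, median):
        params, spec = median
        path = tmp_path / "params.yaml"
        save_parameters(params, spec, path)
        loaded, loaded_spec = load_parameters(path)
        assert loaded == params and loaded_spec == spec

    def test_unknown_keys_rejected(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text(yaml.safe_dump({"model_id": "M1", "alpha": 1, "beta": 1,
                                        "gamma": 1, "delta": 1, "mystery": 2}))
        with pytest.raises(ValueError, match="mystery"):
            load_parameters(path)
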