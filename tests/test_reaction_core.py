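"""Rate laws, control algebra, and right-hand-side assembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from complement_rom.reaction_core import (
    ConfigurationError,
    ControlFactor,
    ControlRule,
    InputError,
    InvalidRuleError,
    ParameterSet,
    RhsEvaluator,
    evaluate_rhs,
    hill_transfer,
    integrate_control,
    mass_action_rate,
    saturation_rate,
)

concentrations = st.floats(min_value=0.0, max_value=1e6,
                           allow_nan=False, allow_infinity=False)
positives = st.floats(min_value=1e-6, max_value=1e6,
                      allow_nan=False, allow_infinity=False)


class TestHillTransfer:
    @pytest.mark.parametrize(
        "x, K, n, direction, expected",
        [
            (4.0, 4.0, 1.7, "activating", 0.5),     # half-saturation point
            (0.0, 2.0, 1.0, "activating", 0.0),
            (0.0, 2.0, 1.0, "inhibiting", 1.0),
            (6.0, 2.0, 2.0, "activating", 0.9),     # x = 3K, n = 2
            (6.0, 2.0, 2.0, "inhibiting", 0.1),
        ],
    )
    def test_known_values(self, x, K, n, direction, expected):
        assert hill_transfer(x, K, n, direction) == pytest.approx(expected)

    @pytest.mark.parametrize("K, n", [(0.0, 1.0), (-1.0, 1.0), (1.0, 0.0)])
    def test_invalid_constants_rejected(self, K, n):
        with pytest.raises(InvalidRuleError):
            hill_transfer(1.0, K, n)

    def test_negative_actor_rejected(self):
        with pytest.raises(InvalidRuleError):
            hill_transfer(-0.5, 1.0, 1.0)

    @given(x=concentrations, K=positives, n=st.floats(0.5, 8.0))
    @settings(max_examples=200, deadline=None)
    def test_output_in_unit_interval(self, x, K, n):
        for direction in ("activating", "inhibiting"):
            assert 0.0 <= hill_transfer(x, K, n, direction) <= 1.0

    def test_large_arguments_do_not_overflow(self):
        assert hill_transfer(1e300, 1.0, 8.0) == pytest.approx(1.0)


class TestIntegrateControl:
    def _rule(self, integration):
        # actor levels chosen so transfer outputs are 0.2 and 0.7
        return ControlRule(
            target_reaction="r",
            integration=integration,
            factors=(
                ControlFactor("X", "activating", 4.0, 1.0),   # 1/(4+1) = 0.2
                ControlFactor("Y", "activating", 3.0, 1.0),   # 7/(3+7) = 0.7
            ),
        )

    def test_min_selects_strongest_inhibition(self):
        levels = {"X": 1.0, "Y": 7.0}
        assert integrate_control(self._rule("min"), levels) == pytest.approx(0.2)

    def test_max_selects_strongest_activation(self):
        levels = {"X": 1.0, "Y": 7.0}
        assert integrate_control(self._rule("max"), levels) == pytest.approx(0.7)

    def test_no_rule_means_unregulated(self):
        assert integrate_control(None, {}) == 1.0

    def test_unknown_actor_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            integrate_control(self._rule("min"), {"X": 1.0})

    def test_gain_resolved_from_parameter_set(self):
        params = ParameterSet(("Kx",), np.array([4.0]),
                              np.array([[0.1, 10.0]]))
        rule = ControlRule(
            "r", "min", (ControlFactor("X", "activating", "Kx", 1.0),)
        )
        assert integrate_control(rule, {"X": 4.0}, params) == pytest.approx(0.5)

    @given(
        levels=st.lists(concentrations, min_size=1, max_size=4),
        gains=st.lists(positives, min_size=4, max_size=4),
        integration=st.sampled_from(["min", "max"]),
    )
    @settings(max_examples=100, deadline=None)
    def test_control_output_in_unit_interval(self, levels, gains, integration):
        factors = tuple(
            ControlFactor(f"s{i}", "activating" if i % 2 else "inhibiting",
                          gains[i], 1.0 + i)
            for i in range(len(levels))
        )
        rule = ControlRule("r", integration, factors)
        state = {f"s{i}": x for i, x in enumerate(levels)}
        assert 0.0 <= integrate_control(rule, state) <= 1.0


class TestSaturationRate:
    def test_half_max(self):
        assert saturation_rate(1.0, 2.0, 3.0, 3.0, 1.0) == pytest.approx(1.0)

    def test_no_catalyst_no_rate(self):
        assert saturation_rate(5.0, 0.0, 3.0, 3.0, 1.0) == 0.0

    def test_direct_evaluation(self):
        # 2 * 1 * 81 / (9 + 81) = 1.8
        assert saturation_rate(2.0, 1.0, 9.0, 3.0, 2.0) == pytest.approx(1.8)

    def test_negative_concentration_rejected(self):
        with pytest.raises(InvalidRuleError):
            saturation_rate(1.0, 1.0, -1.0, 1.0, 1.0)

    @given(x=st.lists(concentrations, min_size=2, max_size=2).map(sorted),
           k=positives, eps=positives, K=positives, eta=st.floats(0.5, 4.0))
    @settings(max_examples=150, deadline=None)
    def test_monotone_and_bounded(self, x, k, eps, K, eta):
        lo, hi = saturation_rate(k, eps, x[0], K, eta), saturation_rate(
            k, eps, x[1], K, eta)
        assert lo <= hi + 1e-12 * max(abs(lo), 1)
        assert hi <= k * eps * (1 + 1e-12)


class TestMassActionRate:
    def test_product_law(self):
        assert mass_action_rate(2.0, [3.0, 4.0], [-1, -1]) == pytest.approx(24.0)

    def test_zero_reactant_zero_rate(self):
        assert mass_action_rate(2.0, [0.0, 4.0], [-1, -1]) == 0.0

    def test_stoichiometric_power(self):
        assert mass_action_rate(1.0, [2.0], [-2]) == pytest.approx(4.0)

    def test_empty_reactant_set_rejected(self):
        with pytest.raises(ConfigurationError):
            mass_action_rate(1.0, [], [])

    @given(
        levels=st.lists(st.floats(1e-3, 1e3), min_size=1, max_size=3),
        sigma=st.lists(st.integers(-3, -1), min_size=3, max_size=3),
        c=st.floats(0.1, 10.0),
        k=positives,
    )
    @settings(max_examples=150, deadline=None)
    def test_homogeneity_in_reactant_levels(self, levels, sigma, c, k):
        """Scaling all reactants by c scales the rate by c^(sum |sigma|)."""
        sigma = sigma[: len(levels)]
        base = mass_action_rate(k, levels, sigma)
        scaled = mass_action_rate(k, [c * x for x in levels], sigma)
        total_order = -sum(sigma)
        assert scaled == pytest.approx(base * c**total_order, rel=1e-9)


class TestEvaluateRhs:
    def test_zero_rates_zero_derivatives(self, toy_model):
        params = toy_model.parameters.with_values(np.array([1e-300, 1.0]))
        dx = evaluate_rhs(toy_model, np.array([5.0, 0.0, 0.0]), params,
                          {"signal": 1.0})
        assert np.allclose(dx, 0.0)

    def test_single_conversion_conserves_mass(self, decay_model):
        state = np.array([10.0, 0.0, 0.0])
        dx = evaluate_rhs(decay_model, state, decay_model.parameters,
                          {"zymosan": 0.0})
        k = decay_model.parameters["k_tickover"]
        assert dx[0] == pytest.approx(-k * 10.0)
        assert dx[1] == pytest.approx(k * 10.0)
        assert dx[0] + dx[1] == pytest.approx(0.0)

    def test_matches_hand_assembled_matrix_product(self, toy_model):
        """dx/dt must equal tau o (S diag(v) r) assembled by hand."""
        params = toy_model.parameters
        state = np.array([5.0, 1.0, 2.0])
        signal = 3.0
        k, K = params["k_conv"], params["K_gate"]
        v = np.array([signal / (K + signal), 1.0])
        r = np.array([k * 5.0, k * 5.0])
        S = np.array([[-1, -1], [1, 0], [0, 1]], dtype=float)
        tau = np.array([1.0, 1.0, signal / 1.0])
        expected = tau * (S @ (v * r))
        dx = evaluate_rhs(toy_model, state, params, {"signal": signal})
        assert np.allclose(dx, expected)

    def test_reference_dose_equals_unscaled_assembly(self, toy_model):
        """At z = z* the tau factor is 1, so scaled rows match plain S r."""
        state = np.array([5.0, 1.0, 2.0])
        dx = evaluate_rhs(toy_model, state, toy_model.parameters,
                          {"signal": 1.0})
        rhs = RhsEvaluator(toy_model, toy_model.parameters, {"signal": 1.0})
        plain = rhs.S @ rhs.rates(state)
        assert np.allclose(dx, plain)

    def test_missing_initiator_for_scaled_species(self, toy_model):
        with pytest.raises(InputError):
            evaluate_rhs(toy_model, np.zeros(3), toy_model.parameters, {})

    def test_negative_states_clamped_before_rates(self, decay_model):
        dx = evaluate_rhs(decay_model, np.array([-1e-9, 0.0, 0.0]),
                          decay_model.parameters, {"zymosan": 0.0})
        assert np.all(dx == 0.0)
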