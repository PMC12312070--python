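"""Standardized rate law, omega combination and the windowed integrator."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from fbrsim import (ClampSet, Edge, IntegratorOptions, NetworkSpec, NodeSpec,
                    ParameterSet, SystemState, activation_response,
                    build_default_network, detect_oscillation, run_simulation,
                    state_derivative, total_input_omega)

P = ParameterSet()


def single_node_net(drive: float) -> NetworkSpec:
    """One dynamic node X driven by a constant source at a fixed level."""
    return NetworkSpec(
        nodes=[NodeSpec("S", "constant", constant_value=drive), NodeSpec("X")],
        edges=[Edge("S", "X", "activate")])


class TestActivationResponse:
    @pytest.mark.parametrize("h", [1.0, 5.0, 25.0])
    @pytest.mark.parametrize("omega, expected", [(0.0, 0.0), (0.5, 0.5), (1.0, 1.0)])
    def test_fixed_points_for_all_gains(self, h, omega, expected):
        assert activation_response(omega, h) == pytest.approx(expected, abs=1e-12)

    @given(h=st.floats(0.1, 40.0))
    def test_strictly_increasing(self, h):
        grid = np.linspace(0.0, 1.0, 21)
        vals = activation_response(grid, h)
        assert np.all(np.diff(vals) > 0.0)
        assert np.all((vals >= -1e-12) & (vals <= 1 + 1e-12))

    def test_rejects_nonpositive_gain(self):
        with pytest.raises(ValueError):
            activation_response(0.5, 0.0)


class TestTotalInputOmega:
    def test_single_activator_saturates_to_one(self):
        net = single_node_net(1.0)
        state = SystemState({"S": 1.0, "X": 0.0})
        assert total_input_omega("X", state, net, P) == pytest.approx(1.0)

    def test_single_activator_at_half(self):
        # frozen arithmetic value of the saturating form:
        # (1.12/0.12) * (0.06/1.06) = 0.52830188...
        net = single_node_net(0.5)
        state = SystemState({"S": 0.5, "X": 0.0})
        assert total_input_omega("X", state, net, P) == pytest.approx(0.528302, abs=1e-6)

    def test_full_inhibition_wins_over_full_activation(self):
        net = NetworkSpec(
            nodes=[NodeSpec("Up", "constant", constant_value=1.0),
                   NodeSpec("Down", "constant", constant_value=1.0),
                   NodeSpec("X")],
            edges=[Edge("Up", "X", "activate"), Edge("Down", "X", "inhibit")])
        state = SystemState({"Up": 1.0, "Down": 1.0, "X": 0.5})
        assert total_input_omega("X", state, net, P) == pytest.approx(0.0)

    def test_silent_inhibitors_reproduce_activator_branch(self, net):
        """With every inhibitor at 0, the product form equals act exactly."""
        state = {n.name: 0.37 for n in net.nodes}
        for n in net.nodes:
            if n.name in ("IL10", "Ant", "MMPs", "TIMPs", "mF", "M1", "TNFa"):
                state[n.name] = 0.0
        # TGFb has activators {M2, mF, C} and inhibitors {IL10, Ant}
        omega_full = total_input_omega("TGFb", state, net, P)
        acts_only = NetworkSpec(nodes=list(net.nodes),
                                edges=[e for e in net.edges
                                       if not (e.target == "TGFb" and e.sign == "inhibit")])
        assert omega_full == pytest.approx(
            total_input_omega("TGFb", state, acts_only, P), abs=1e-14)

    def test_unregulated_node_is_an_error(self):
        net = NetworkSpec(nodes=[NodeSpec("X"), NodeSpec("Y")],
                          edges=[Edge("X", "Y", "activate")])
        with pytest.raises(ValueError, match="no regulators"):
            total_input_omega("X", SystemState({"X": 0.0, "Y": 0.0}), net, P)


class TestStateDerivative:
    def test_quiescent_state_is_a_fixed_point(self, net):
        state = {n.name: 0.0 for n in net.nodes}
        deriv = state_derivative(state, net, P, inputs=(0.0, 0.0, 0.0))
        assert all(abs(v) < 1e-12 for v in deriv.values())

    def test_production_minus_decay(self):
        net = single_node_net(1.0)
        deriv = state_derivative({"S": 1.0, "X": 0.0}, net, P)
        assert deriv["X"] == pytest.approx(1.0)  # omega=1, x=0
        deriv = state_derivative({"S": 1.0, "X": 1.0}, net, P)
        assert deriv["X"] == pytest.approx(0.0)  # fixed point at x*=1

    def test_clamped_nodes_do_not_move(self, net):
        state = {n.name: 0.5 for n in net.nodes}
        deriv = state_derivative(state, net, P, clamps=ClampSet({"TGFb": 0.0}),
                                 inputs=(1.0, 0.0, 0.0))
        assert deriv["TGFb"] == 0.0


class TestRunSimulation:
    def test_no_input_decays_to_zero(self, net, params):
        res = run_simulation(net, params, (0.0, 0.0, 0.0))
        assert res.converged
        for name, value in res.steady_state.items():
            expected = 0.3 if name == "Ant" else 0.0
            assert value == pytest.approx(expected, abs=1e-6), name

    def test_analytic_single_node_fixed_point(self):
        """x* = f(omega)/gamma for a node under constant drive."""
        for drive in (0.25, 0.5, 0.9):
            net = single_node_net(drive)
            res = run_simulation(net, P, (0.0, 0.0, 0.0))
            state = SystemState({"S": drive, "X": 0.0})
            omega = total_input_omega("X", state, net, P)
            expected = activation_response(omega, P.h) / P.gamma
            assert res.steady_state["X"] == pytest.approx(expected, abs=1e-4)

    def test_trajectory_stays_in_unit_box(self, net, params):
        rng = np.random.default_rng(42)
        for _ in range(3):
            inputs = tuple(rng.uniform(0, 1, 3))
            res = run_simulation(net, params, inputs)
            for state in res.trajectory:
                for name, v in state.values.items():
                    assert -1e-6 <= v <= 1 + 1e-6, (name, v)

    def test_clamp_held_exactly_along_trajectory(self, net, params):
        res = run_simulation(net, params, (1.0, 0.5, 0.0),
                             clamps={"IL10": 1.0, "MMPs": 0.0})
        for state in res.trajectory:
            assert state.values["IL10"] == 1.0
            assert state.values["MMPs"] == 0.0

    def test_higher_wound_input_raises_cells_and_matrix(self, net, params):
        low = run_simulation(net, params, (0.3, 0.0, 0.0)).steady_state
        high = run_simulation(net, params, (0.9, 0.0, 0.0)).steady_state
        for name in ("M1", "M2", "mF", "ECM"):
            assert high[name] > low[name]

    def test_solvers_agree_on_baseline(self, net, params):
        rk = run_simulation(net, params, (1.0, 0.0, 0.0))
        ls = run_simulation(net, params, (1.0, 0.0, 0.0),
                            opts=IntegratorOptions(method="lsoda"))
        for name in rk.steady_state:
            assert rk.steady_state[name] == pytest.approx(
                ls.steady_state[name], abs=1e-3)

    def test_initial_conditions_do_not_move_steady_state(self, net, params):
        """At h=1 the intermediate variables forget their starting values."""
        base = run_simulation(net, params, (0.7, 0.5, 0.3)).steady_state
        rng = np.random.default_rng(7)
        randomized = NetworkSpec(
            nodes=[NodeSpec(n.name, n.role,
                            float(rng.uniform()) if n.role == "dynamic" else n.initial_value,
                            n.constant_value) for n in net.nodes],
            edges=list(net.edges))
        pert = run_simulation(randomized, params, (0.7, 0.5, 0.3)).steady_state
        for name in base:
            assert base[name] == pytest.approx(pert[name], abs=1e-4), name

    def test_invalid_inputs_rejected(self, net, params):
        with pytest.raises(ValueError):
            run_simulation(net, params, (1.2, 0.0, 0.0))
        with pytest.raises(KeyError):
            run_simulation(net, params, (1.0, 0.0, 0.0), clamps={"BOGUS": 1.0})


class TestOscillationDetection:
    def test_converged_baseline_not_flagged(self, net, params):
        res = run_simulation(net, params, (1.0, 0.0, 0.0))
        assert res.converged and not res.oscillating

    def test_constant_trajectory_not_flagged(self):
        traj = [SystemState({"X": 0.4}, t) for t in range(30)]
        assert detect_oscillation(traj) is False

    def test_bounded_limit_cycle_flagged(self):
        traj = [SystemState({"X": 0.5 + 0.2 * np.sin(t)}, t) for t in range(30)]
        assert detect_oscillation(traj) is True

    def test_high_gain_destabilizes_some_cells(self, net, params):
        from dataclasses import replace
        res = run_simulation(net, replace(params, h=25.0), (1.0, 0.5, 0.5),
                             opts=IntegratorOptions(max_windows=120))
        assert not res.converged and res.oscillating
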