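"""Standardized ODE dynamics of the FBR network.

Every integrated node follows the same normalized rate law: a sigmoid
activation term driven by the node's total regulatory input ω, minus a
first-order decay,

    dx/dt = f(ω; h) − γ·x,

where f passes through (0,0), (0.5,0.5) and (1,1) for every gain h, so all
activation levels live in [0, 1].  ω combines the node's activators and
inhibitors through a saturating, weight-normalized form: with only
activators present, ω saturates to 1 when all activators are fully on; with
both kinds present, ω is the activator term times (1 − inhibitor term), so
full inhibition always wins.

The input variables A, B, C are not integrated.  The simulation runs in
windows of fixed duration: inputs are held constant within a window and,
when feedback is enabled, recomputed between windows from the auxiliary
node levels (:mod:`fbrsim.feedback`).  The run ends when both the state and
the inputs stop changing across a window, or when the window budget is
exhausted (in which case a bounded, non-decaying residual motion is flagged
as oscillation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .feedback import caux_gate, update_inputs
from .network import NetworkSpec, ParameterSet, validate_network

__all__ = [
    "SystemState",
    "ClampSet",
    "IntegratorOptions",
    "SimulationResult",
    "activation_response",
    "total_input_omega",
    "state_derivative",
    "run_simulation",
    "detect_oscillation",
]

_BOUND_TOL = 1e-6


@dataclass
class SystemState:
    """Snapshot of all node activation levels at one time point."""

    values: dict[str, float]
    time: float = 0.0


@dataclass
class ClampSet:
    """Nodes held at a fixed activation level for the whole simulation.

    Clamping to 0 mimics a knockout / depletion experiment, clamping to 1 a
    supplementation experiment.
    """

    entries: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for name, v in self.entries.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"clamp {name}={v} outside [0, 1]")

    def __bool__(self):
        return bool(self.entries)


@dataclass
class IntegratorOptions:
    """Numerical controls for the windowed steady-state integration.

    The non-stiff default is RK45 at (rtol=1e-3, atol=1e-6); windows that
    fail under RK45 are retried with LSODA at 1e-9/1e-9, which switches
    automatically between Adams and BDF schemes for stiff stretches.
    ``window_duration`` is in units of the decay time 1/γ; with γ = 1 a
    window of 1.0 resolves the natural relaxation timescale.
    """

    method: str = "rk45"
    rtol: float = 1e-3
    atol: float = 1e-6
    window_duration: float = 1.0
    max_windows: int = 500
    steady_tol: float = 1e-5

    def __post_init__(self):
        self.method = self.method.lower()
        if self.method not in ("rk45", "lsoda"):
            raise ValueError(f"unknown integrator method {self.method!r}")


@dataclass
class SimulationResult:
    """Outcome of one windowed run.

    ``trajectory`` holds the initial state plus one snapshot per completed
    window; ``input_trace`` holds the effective (A, B, C) used in each
    window.  ``steady_state`` is the end-of-run value of every node,
    including inputs and constants.
    """

    trajectory: list[SystemState]
    steady_state: dict[str, float]
    input_trace: list[tuple[float, float, float]]
    converged: bool
    oscillating: bool
    windows_used: int


# ---------------------------------------------------------------------------
# rate-law primitives
# ---------------------------------------------------------------------------

def activation_response(omega, h: float):
    """Normalized sigmoid production rate f(ω; h).

    f(0) = 0, f(0.5) = 0.5 and f(1) = 1 for every gain h > 0; larger h gives
    a steeper, more switch-like response around ω = 0.5.  Accepts scalars or
    arrays.
    """
    if h <= 0:
        raise ValueError("sigmoid gain h must be strictly positive")
    omega = np.asarray(omega, dtype=float)
    e_half = math.exp(0.5 * h)
    expo = np.exp(-h * (omega - 0.5))
    out = (-e_half + expo) / ((1.0 - e_half) * (1.0 + expo))
    return float(out) if out.ndim == 0 else out


def _combine(weights: np.ndarray, values: np.ndarray) -> float:
    """Saturating weighted-input term: ((1+Σw)/Σw) · (Σwx / (1+Σwx))."""
    s = float(weights.sum())
    sx = float(weights @ values)
    return (1.0 + s) / s * (sx / (1.0 + sx))


def total_input_omega(node: str, state: SystemState | Mapping[str, float],
                      net: NetworkSpec, params: ParameterSet) -> float:
    """Total regulatory input ω to ``node`` under the given state.

    Uses the branch appropriate to the node's regulator sets: activators
    only, inhibitors only, or the product form act·(1 − inh).  Raises for a
    node with no regulators (such a network is invalid).
    """
    values = state.values if isinstance(state, SystemState) else state
    acts = net.activators_of(node)
    inhs = net.inhibitors_of(node)
    if not acts and not inhs:
        raise ValueError(f"node {node!r} has no regulators")
    act_term = inh_term = None
    if acts:
        w = np.array([e.resolve_weight(params) for e in acts])
        x = np.array([values[e.source] for e in acts])
        act_term = _combine(w, x)
    if inhs:
        w = np.array([e.resolve_weight(params) for e in inhs])
        x = np.array([values[e.source] for e in inhs])
        inh_term = _combine(w, x)
    if act_term is not None and inh_term is not None:
        omega = act_term * (1.0 - inh_term)
    elif act_term is not None:
        omega = act_term
    else:
        omega = 1.0 - inh_term
    # round-off may push ω a hair outside [0, 1]
    if omega < 0.0 or omega > 1.0:
        excess = max(-omega, omega - 1.0)
        if excess > 1e-12:
            raise ArithmeticError(f"omega for {node!r} out of range by {excess:g}")
        omega = min(1.0, max(0.0, omega))
    return float(omega)


def state_derivative(state: SystemState | Mapping[str, float], net: NetworkSpec,
                     params: ParameterSet, clamps: ClampSet | None = None,
                     inputs: tuple[float, float, float] = (0.0, 0.0, 0.0),
                     ) -> dict[str, float]:
    """Time derivative of every node for the given instantaneous state.

    Inputs and constants contribute their current values as regulators but
    carry derivative 0, as do clamped nodes.  The Caux stiffening carrier
    gets ω = 0 while the ECM + mF gate is closed.
    """
    values = dict(state.values if isinstance(state, SystemState) else state)
    clamps = clamps or ClampSet()
    values["A"], values["B"], values["C"] = inputs
    for n in net.nodes:
        if n.role == "constant":
            values[n.name] = n.constant_value
    values.update(clamps.entries)
    gate_a, gate_b = net.caux_gate_members
    gate_open = (caux_gate(values[gate_a], values[gate_b], params.caux_threshold)
                 if gate_a in values and gate_b in values else True)
    deriv: dict[str, float] = {}
    for n in net.nodes:
        if n.role in ("constant", "input") or n.name in clamps.entries:
            deriv[n.name] = 0.0
            continue
        if n.name == "Caux" and not gate_open:
            omega = 0.0
        else:
            omega = total_input_omega(n.name, values, net, params)
        deriv[n.name] = activation_response(omega, params.h) - params.gamma * values[n.name]
    return deriv


# ---------------------------------------------------------------------------
# compiled right-hand side
# ---------------------------------------------------------------------------

class _CompiledModel:
    """Index-based form of the network for fast repeated RHS evaluation."""

    def __init__(self, net: NetworkSpec, params: ParameterSet,
                 clamps: ClampSet | None = None):
        params.validate()
        diags = validate_network(net)
        if diags:
            raise ValueError("invalid network: " + "; ".join(diags))
        self.net = net
        self.params = params
        self.clamps = clamps or ClampSet()
        for name in self.clamps.entries:
            if not net.has_node(name):
                raise KeyError(f"clamp names unknown node {name!r}")

        integ = [n.name for n in net.nodes if n.role in ("dynamic", "auxiliary")]
        consts = [n for n in net.nodes if n.role == "constant"]
        inputs = [n.name for n in net.nodes if n.role == "input"]
        self.state_names = integ
        self.all_names = integ + [n.name for n in consts] + inputs
        self.index = {name: i for i, name in enumerate(self.all_names)}
        self.n_state = len(integ)
        self.const_idx = np.array([self.index[n.name] for n in consts], dtype=int)
        self.const_val = np.array([n.constant_value for n in consts])
        self.input_idx = {name: self.index[name] for name in inputs}
        self.clamp_state = [(i, v) for i, v in
                            ((self.index.get(k), v) for k, v in self.clamps.entries.items())
                            if i is not None and i < self.n_state]
        self.y0 = np.array([net.node(n).initial_value for n in integ])
        for i, v in self.clamp_state:
            self.y0[i] = v

        # per-node regulator index/weight arrays into the full value vector
        self.regs: list[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = []
        for name in integ:
            acts = net.activators_of(name)
            inhs = net.inhibitors_of(name)
            ai = np.array([self.index[e.source] for e in acts], dtype=int)
            aw = np.array([e.resolve_weight(params) for e in acts])
            ii = np.array([self.index[e.source] for e in inhs], dtype=int)
            iw = np.array([e.resolve_weight(params) for e in inhs])
            self.regs.append((ai, aw, ii, iw))
        self.caux_i = self.index.get("Caux")
        ga, gb = net.caux_gate_members
        self.gate_idx = ((self.index[ga], self.index[gb])
                         if ga in self.index and gb in self.index else None)
        self._full = np.zeros(len(self.all_names))

    def rhs(self, t: float, y: np.ndarray,
            inputs: tuple[float, float, float]) -> np.ndarray:
        p = self.params
        full = self._full
        full[: self.n_state] = y
        for i, v in self.clamp_state:
            full[i] = v
        if self.const_idx.size:
            full[self.const_idx] = self.const_val
        for name, val in zip(("A", "B", "C"), inputs):
            idx = self.input_idx.get(name)
            if idx is not None:
                full[idx] = self.clamps.entries.get(name, val)
        gate_open = (caux_gate(full[self.gate_idx[0]], full[self.gate_idx[1]],
                               p.caux_threshold)
                     if self.gate_idx is not None else True)
        dy = np.empty(self.n_state)
        for i in range(self.n_state):
            if i == self.caux_i and not gate_open:
                omega = 0.0
            else:
                ai, aw, ii, iw = self.regs[i]
                act = _combine(aw, full[ai]) if ai.size else None
                inh = _combine(iw, full[ii]) if ii.size else None
                if act is not None and inh is not None:
                    omega = act * (1.0 - inh)
                elif act is not None:
                    omega = act
                else:
                    omega = 1.0 - inh
                omega = min(1.0, max(0.0, omega))
            dy[i] = activation_response(omega, p.h) - p.gamma * full[i]
        for i, _ in self.clamp_state:
            dy[i] = 0.0
        return dy

    def snapshot(self, y: np.ndarray, inputs: tuple[float, float, float]
                 ) -> dict[str, float]:
        vals = {name: float(y[i]) for i, name in enumerate(self.state_names)}
        for n, v in zip(self.const_idx, self.const_val):
            vals[self.all_names[n]] = float(v)
        for name, val in zip(("A", "B", "C"), inputs):
            if name in self.input_idx:
                vals[name] = float(self.clamps.entries.get(name, val))
        for k, v in self.clamps.entries.items():
            vals[k] = float(v)
        return vals


def _integrate_window(model: _CompiledModel, y: np.ndarray,
                      inputs: tuple[float, float, float],
                      opts: IntegratorOptions, window_index: int,
                      upper: float) -> np.ndarray:
    """Advance one window, falling back from RK45 to LSODA (1e-9) when the
    solver rejects the window or overshoots the invariant [0, upper] box
    (steep high-gain dynamics make the system stiff)."""
    method_order = (["RK45", "LSODA"] if opts.method == "rk45" else ["LSODA"])
    last_err = None
    for method in method_order:
        rtol, atol = ((opts.rtol, opts.atol) if method == "RK45" else (1e-9, 1e-9))
        try:
            sol = solve_ivp(model.rhs, (0.0, opts.window_duration), y,
                            method=method, rtol=rtol, atol=atol, args=(inputs,))
        except Exception as exc:  # pragma: no cover - solver internals
            last_err = exc
            continue
        if sol.success:
            y_end = sol.y[:, -1]
            excess = max(float(-(y_end.min())), float(y_end.max() - upper), 0.0)
            if excess <= _BOUND_TOL or method == method_order[-1]:
                return y_end
            last_err = f"state left [0, {upper:g}] by {excess:g}"
        else:
            last_err = sol.message
    raise RuntimeError(
        f"integration failed in window {window_index} "
        f"(methods tried: {method_order}): {last_err}")


def run_simulation(net: NetworkSpec, params: ParameterSet | None = None,
                   inputs0: tuple[float, float, float] = (0.0, 0.0, 0.0),
                   clamps: ClampSet | Mapping[str, float] | None = None,
                   feedback_enabled: bool = True,
                   opts: IntegratorOptions | None = None) -> SimulationResult:
    """Integrate the FBR network to steady state under inputs (A0, B0, C0).

    The outer loop alternates ODE integration over one window with the
    algebraic input update.  With ``feedback_enabled=False`` the inputs stay
    frozen at their prescriptions for the whole run, which disconnects the
    auxiliary nodes from the rest of the system.
    """
    params = params or ParameterSet()
    opts = opts or IntegratorOptions()
    if isinstance(clamps, Mapping):
        clamps = ClampSet(dict(clamps))
    for v in inputs0:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"initial inputs must lie in [0, 1], got {inputs0}")
    model = _CompiledModel(net, params, clamps)
    A0, B0, C0 = inputs0

    def aux(y, name):
        i = model.index.get(name)
        return float(y[i]) if i is not None and i < model.n_state else 0.0

    y = model.y0.copy()
    if feedback_enabled:
        inputs = update_inputs(A0, B0, C0, aux(y, "Aaux"), aux(y, "Baux"),
                               aux(y, "Caux"), params)
    else:
        inputs = (A0, B0, C0)

    trajectory = [SystemState(model.snapshot(y, inputs), 0.0)]
    input_trace: list[tuple[float, float, float]] = []
    converged = False
    windows = 0
    # the fixed point of dx/dt = f(omega) - gamma*x is bounded by f(1)/gamma,
    # so activation levels can exceed 1 only when gamma < 1
    upper = max(1.0, 1.0 / params.gamma)
    for w in range(opts.max_windows):
        input_trace.append(inputs)
        y_new = _integrate_window(model, y, inputs, opts, w, upper)
        excess = max(float(-(y_new.min())), float(y_new.max() - upper), 0.0)
        if excess > _BOUND_TOL:
            raise RuntimeError(
                f"state left [0, {upper:g}] by {excess:g} in window {w}; "
                "this indicates a model construction error")
        y_new = np.clip(y_new, 0.0, upper)
        windows = w + 1
        if feedback_enabled:
            new_inputs = update_inputs(A0, B0, C0, aux(y_new, "Aaux"),
                                       aux(y_new, "Baux"), aux(y_new, "Caux"),
                                       params)
        else:
            new_inputs = inputs
        trajectory.append(
            SystemState(model.snapshot(y_new, new_inputs), windows * opts.window_duration))
        state_change = float(np.max(np.abs(y_new - y)))
        input_change = max(abs(a - b) for a, b in zip(new_inputs, inputs))
        y, inputs = y_new, new_inputs
        if state_change <= opts.steady_tol and input_change <= opts.steady_tol:
            converged = True
            break

    oscillating = False
    if not converged:
        oscillating = detect_oscillation(trajectory, steady_tol=opts.steady_tol,
                                         converged=False)
    return SimulationResult(
        trajectory=trajectory,
        steady_state=model.snapshot(y, inputs),
        input_trace=input_trace,
        converged=converged,
        oscillating=oscillating,
        windows_used=windows,
    )


def detect_oscillation(trajectory: Sequence[SystemState], *,
                       steady_tol: float = 1e-5, converged: bool = False,
                       tail: int = 20) -> bool:
    """Flag sustained bounded motion in a non-converged trajectory.

    True iff the run did not converge and, over the trailing windows, at
    least one node keeps a min–max amplitude above 10× the steady-state
    tolerance while every value stays inside [0, 1] — i.e. the residual
    motion is a genuine limit cycle or instability rather than slow decay.
    """
    if converged or len(trajectory) < 5:
        return False
    names = list(trajectory[-1].values)
    block = np.array([[s.values[n] for n in names] for s in trajectory[-tail:]])
    if block.min() < -_BOUND_TOL or block.max() > 1.0 + _BOUND_TOL:
        return False
    amplitudes = block.max(axis=0) - block.min(axis=0)
    return bool(amplitudes.max() > 10.0 * steady_tol)
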