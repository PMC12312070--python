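"""One-at-a-time sensitivity analyses of the FBR model.

Three batteries:

* twofold (×0.5, ×2) variation of the network-related weight parameters
  (α, β, cx, bx), reading out the steady-state ECM level,
* ±10 % variation of the input-related parameters (fA, fB, fC and the
  C-gate threshold), reading out the relative ECM difference between the
  zero-material and maximal-material conditions (the "B/C effect"),
* a sweep of the sigmoid gain h, recording convergence, oscillation and
  how binary the steady-state ECM landscape becomes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .dynamics import IntegratorOptions, run_simulation
from .experiments import classify_outcome
from .network import NetworkSpec, ParameterSet

__all__ = [
    "SensitivityRecord",
    "network_param_sensitivity",
    "input_param_sensitivity",
    "bc_effect",
    "gain_sweep",
]

INPUT_PARAMS = ("fA", "fB", "fC", "caux_threshold")


@dataclass
class SensitivityRecord:
    """Effect of one parameter perturbation on one scalar readout."""

    parameter: str
    factor: float
    quantity: str               # 'ecm_ss' | 'bc_effect'
    baseline_value: float
    perturbed_value: float
    percent_change: float | None

    @staticmethod
    def make(parameter, factor, quantity, baseline, perturbed):
        pc = (100.0 * (perturbed - baseline) / baseline) if baseline != 0 else None
        return SensitivityRecord(parameter, factor, quantity, baseline, perturbed, pc)


def _records_frame(records: Sequence[SensitivityRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def _ecm_ss(net, params, inputs, opts):
    return run_simulation(net, params, inputs, opts=opts).steady_state["ECM"]


def _weight_groups(net: NetworkSpec) -> dict[str, list[int]]:
    """The one-at-a-time parameter groups of the twofold battery.

    Every activator weight (an individual alpha_n) and inhibitor weight (a
    beta_m) is its own parameter, except the inputs of the B- and C-feedback
    equations, which carry the named weights ``bx`` and ``cx`` and are
    varied as (single-parameter) groups.
    """
    groups: dict[str, list[int]] = {}
    for i, e in enumerate(net.edges):
        if e.target == "Caux":
            groups.setdefault("cx", []).append(i)
        elif e.target == "Baux":
            groups.setdefault("bx", []).append(i)
        else:
            kind = "alpha" if e.sign == "activate" else "beta"
            groups[f"{kind}:{e.source}->{e.target}"] = [i]
    return groups


def _rescale_edges(net: NetworkSpec, params: ParameterSet,
                   idxs: Sequence[int], factor: float) -> NetworkSpec:
    from .network import Edge
    edges = [Edge(e.source, e.target, e.sign,
                  e.resolve_weight(params) * factor if i in set(idxs) else e.weight)
             for i, e in enumerate(net.edges)]
    return NetworkSpec(nodes=list(net.nodes), edges=edges,
                       caux_gate_members=net.caux_gate_members)


def network_param_sensitivity(
        net: NetworkSpec, params: ParameterSet | None = None,
        factors: Iterable[float] = (0.5, 2.0),
        input_set: tuple[float, float, float] = (1.0, 0.0, 0.0),
        opts: IntegratorOptions | None = None) -> list[SensitivityRecord]:
    """Twofold one-at-a-time variation of the network weight parameters.

    Each relative weight of the model — every activator weight alpha_n,
    every inhibitor weight beta_m, and the named feedback weights cx (inputs
    of the C equation) and bx (input of the B equation) — is rescaled
    independently, the steady-state simulation is rerun, and the percent
    change of steady-state ECM versus baseline is recorded.  The default
    condition is the wound-only baseline (1, 0, 0), where every feedback
    loop is active.  Records are sorted by |percent change| descending, so
    the first entry names the most influential parameter.
    """
    params = params or ParameterSet()
    baseline = _ecm_ss(net, params, input_set, opts)
    records = []
    for name, idxs in _weight_groups(net).items():
        for factor in factors:
            if factor == 1.0:
                value = baseline
            else:
                value = _ecm_ss(_rescale_edges(net, params, idxs, factor),
                                params, input_set, opts)
            records.append(SensitivityRecord.make(name, factor, "ecm_ss",
                                                  baseline, value))
    records.sort(key=lambda r: -abs(r.percent_change or 0.0))
    return records


def bc_effect(net: NetworkSpec, params: ParameterSet | None = None,
              opts: IntegratorOptions | None = None) -> float:
    """Percent increase of steady-state ECM from (1,0,0) to (1,1,1).

    The readout quantifying how much the material inputs B and C add to the
    fibrotic response on top of a maximal wound input.
    """
    params = params or ParameterSet()
    low = _ecm_ss(net, params, (1.0, 0.0, 0.0), opts)
    high = _ecm_ss(net, params, (1.0, 1.0, 1.0), opts)
    return 100.0 * (high - low) / low


def input_param_sensitivity(
        net: NetworkSpec, params: ParameterSet | None = None,
        delta: float = 0.10,
        opts: IntegratorOptions | None = None) -> list[SensitivityRecord]:
    """±delta multiplicative variation of the input-related parameters.

    The readout is the B/C effect (see :func:`bc_effect`); each of fA, fB,
    fC and the C-gate threshold is scaled to (1−delta)× and (1+delta)× in
    turn.  Sorted by |percent change| of the readout, descending.
    """
    params = params or ParameterSet()
    baseline = bc_effect(net, params, opts)
    records = []
    for name in INPUT_PARAMS:
        for factor in (1.0 - delta, 1.0 + delta):
            perturbed = replace(params, **{name: getattr(params, name) * factor})
            value = baseline if factor == 1.0 else bc_effect(net, perturbed, opts)
            records.append(SensitivityRecord.make(name, factor, "bc_effect",
                                                  baseline, value))
    records.sort(key=lambda r: -abs(r.percent_change or 0.0))
    return records


def gain_sweep(net: NetworkSpec, params: ParameterSet | None = None,
               h_values: Iterable[float] = (1, 5, 10, 25, 50),
               B_grid: Iterable[float] = (0.0, 0.5, 1.0),
               C_grid: Iterable[float] = (0.0, 0.5, 1.0),
               A0: float = 1.0,
               opts: IntegratorOptions | None = None) -> pd.DataFrame:
    """Sweep the sigmoid gain h over a B0 × C0 grid at fixed A0.

    Higher gains push the response toward a binary switch; above h ≈ 10 the
    steady-state landscape loses intermediate ECM values and some (B0, C0)
    cells stop converging, oscillating instead.  Returns one row per
    (h, B0, C0) cell with convergence and outcome, plus the per-h fraction
    of intermediate steady states (ECM in (0.1, 0.9)) in the column
    ``frac_intermediate``.
    """
    params = params or ParameterSet()
    rows = []
    for h in h_values:
        p = replace(params, h=float(h))
        ecms = []
        for b in B_grid:
            for c in C_grid:
                res = run_simulation(net, p, (A0, float(b), float(c)), opts=opts)
                ecm = res.steady_state["ECM"]
                ecms.append((b, c, ecm, res.converged, res.oscillating))
        frac = float(np.mean([0.1 < e[2] < 0.9 for e in ecms]))
        for b, c, ecm, conv, osc in ecms:
            rows.append({"h": float(h), "B0": float(b), "C0": float(c),
                         "ecm": ecm, "converged": conv, "oscillating": osc,
                         "outcome": classify_outcome(ecm, params.ecm_threshold),
                         "frac_intermediate": frac})
    return pd.DataFrame(rows)
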