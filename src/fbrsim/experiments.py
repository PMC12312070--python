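"""Experiment batteries built on the FBR simulator.

* outcome classification of steady-state ECM into low / high (fibrotic),
* the in-silico perturbation battery mimicking eight published in vivo
  antifibrotic interventions (knockout = clamp to 0, supplementation =
  clamp to 1), with direction-of-effect comparison against the in vivo
  expectation,
* B×C input sweeps producing ECM heatmaps at fixed wound input A,
* the A* analysis: the minimum wound input that produces a fibrotic
  outcome for given material inputs, with and without input feedback,
* a robustness check that rescales the battery's input levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .dynamics import ClampSet, IntegratorOptions, run_simulation
from .network import NetworkSpec, ParameterSet

__all__ = [
    "PerturbationCondition",
    "PerturbationCell",
    "PerturbationReport",
    "SweepResult",
    "AStarResult",
    "classify_outcome",
    "default_conditions",
    "default_input_sets",
    "run_perturbation_battery",
    "input_sweep",
    "find_A_star",
    "input_robustness_check",
]

#: Minimum |ΔECM| required to call a perturbation effect "up" or "down".
DIRECTION_TOL = 1e-4


def classify_outcome(ecm_steady: float, threshold: float = 0.35) -> str:
    """Classify a steady-state ECM level: 'high' (fibrotic) iff strictly above
    the threshold, else 'low' (physiological deposition)."""
    return "high" if ecm_steady > threshold else "low"


@dataclass(frozen=True)
class PerturbationCondition:
    """One in-silico replicate of an in vivo antifibrotic intervention.

    ``implant_context`` records whether the source study involved an
    implanted material; studies of general (non-implant) fibrosis can only
    be compared with the model at zero material inputs.
    """

    name: str
    clamps: dict[str, float]
    expected_in_vivo_direction: str = "decrease"
    implant_context: bool = True


def default_conditions() -> list[PerturbationCondition]:
    """The eight-intervention battery.

    All eight interventions reduced fibrosis in vivo.  The inhibitory drug
    coating clamps the four pro-inflammatory cytokines at once; macrophage
    depletion clamps both polarization states.
    """
    return [
        PerturbationCondition("IL-10 supplementation", {"IL10": 1.0},
                              implant_context=False),
        PerturbationCondition("PDGF receptor blocker", {"PDGF": 0.0},
                              implant_context=False),
        PerturbationCondition("MMP inhibition", {"MMPs": 0.0},
                              implant_context=False),
        PerturbationCondition("IL-4 eluting coating", {"IL4": 1.0}),
        PerturbationCondition("TGF-b inhibitor", {"TGFb": 0.0}),
        PerturbationCondition("IFN-g gene disruption", {"IFNg": 0.0}),
        PerturbationCondition("inhibitory drug coating",
                              {"IL1b": 0.0, "IFNg": 0.0, "TNFa": 0.0, "IL6": 0.0}),
        PerturbationCondition("macrophage depletion", {"M1": 0.0, "M2": 0.0}),
    ]


def default_input_sets() -> list[tuple[float, float, float]]:
    return [(1.0, 0.0, 0.0), (1.0, 1.0, 0.0), (1.0, 1.0, 1.0)]


@dataclass
class PerturbationCell:
    """One condition × input-set comparison against baseline."""

    condition: str
    inputs: tuple[float, float, float]
    baseline_ecm: float
    perturbed_ecm: float
    direction: str          # 'up' | 'down' | 'none'
    match: str              # 'match' | 'mismatch' | 'not-comparable'


@dataclass
class PerturbationReport:
    cells: list[PerturbationCell]
    condition_match: dict[str, bool]
    total_matches: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{
                "condition": c.condition,
                "A0": c.inputs[0], "B0": c.inputs[1], "C0": c.inputs[2],
                "baseline_ecm": c.baseline_ecm,
                "perturbed_ecm": c.perturbed_ecm,
                "direction": c.direction,
                "match": c.match,
            } for c in self.cells])


def _direction(delta: float, tol: float) -> str:
    if delta > tol:
        return "up"
    if delta < -tol:
        return "down"
    return "none"


def run_perturbation_battery(
        net: NetworkSpec, params: ParameterSet | None = None,
        conditions: Sequence[PerturbationCondition] | None = None,
        input_sets: Sequence[tuple[float, float, float]] | None = None,
        direction_tol: float = DIRECTION_TOL,
        opts: IntegratorOptions | None = None) -> PerturbationReport:
    """Run every condition against its baseline over the given input sets.

    A non-implant condition is comparable only at zero material inputs
    (B0 = C0 = 0); its other cells are marked 'not-comparable'.  The in vivo
    expectation for every default condition is a *decrease* in fibrosis, so
    a cell matches iff the simulated ECM direction is 'down'.  A condition
    counts toward ``total_matches`` iff all of its comparable cells match.
    """
    params = params or ParameterSet()
    conditions = list(default_conditions() if conditions is None else conditions)
    input_sets = list(default_input_sets() if input_sets is None else input_sets)
    for cond in conditions:
        for node in cond.clamps:
            if not net.has_node(node):
                raise KeyError(f"condition {cond.name!r} clamps unknown node {node!r}")

    baselines = {
        inp: run_simulation(net, params, inp, opts=opts).steady_state["ECM"]
        for inp in input_sets}
    cells: list[PerturbationCell] = []
    condition_match: dict[str, bool] = {}
    for cond in conditions:
        ok = True
        for inp in input_sets:
            material = inp[1] != 0.0 or inp[2] != 0.0
            base = baselines[inp]
            pert = run_simulation(net, params, inp, clamps=ClampSet(dict(cond.clamps)),
                                  opts=opts).steady_state["ECM"]
            direction = _direction(pert - base, direction_tol)
            if material and not cond.implant_context:
                match = "not-comparable"
            else:
                expected = "down" if cond.expected_in_vivo_direction == "decrease" else "up"
                match = "match" if direction == expected else "mismatch"
                ok = ok and match == "match"
            cells.append(PerturbationCell(cond.name, inp, base, pert, direction, match))
        condition_match[cond.name] = ok
    return PerturbationReport(cells, condition_match,
                              total_matches=sum(condition_match.values()))


@dataclass
class SweepResult:
    """Steady-state ECM over a B0 × C0 grid at fixed A0."""

    A0: float
    B_grid: np.ndarray
    C_grid: np.ndarray
    ecm_matrix: np.ndarray          # shape (len(B_grid), len(C_grid))
    class_matrix: np.ndarray        # 'low' / 'high' strings, same shape
    converged_matrix: np.ndarray    # booleans, same shape

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, b in enumerate(self.B_grid):
            for j, c in enumerate(self.C_grid):
                rows.append({"A0": self.A0, "B0": b, "C0": c,
                             "ecm": self.ecm_matrix[i, j],
                             "outcome": self.class_matrix[i, j],
                             "converged": bool(self.converged_matrix[i, j])})
        return pd.DataFrame(rows)


def input_sweep(net: NetworkSpec, params: ParameterSet | None = None,
                A0: float = 1.0,
                B_grid: Iterable[float] = (0.0, 0.25, 0.5, 0.75, 1.0),
                C_grid: Iterable[float] = (0.0, 0.25, 0.5, 0.75, 1.0),
                feedback_enabled: bool = True,
                opts: IntegratorOptions | None = None) -> SweepResult:
    """One steady-state simulation per (B0, C0) cell at fixed A0."""
    params = params or ParameterSet()
    B = np.asarray(list(B_grid), dtype=float)
    C = np.asarray(list(C_grid), dtype=float)
    ecm = np.zeros((B.size, C.size))
    conv = np.zeros((B.size, C.size), dtype=bool)
    cls = np.empty((B.size, C.size), dtype=object)
    for i, b in enumerate(B):
        for j, c in enumerate(C):
            res = run_simulation(net, params, (A0, float(b), float(c)),
                                 feedback_enabled=feedback_enabled, opts=opts)
            ecm[i, j] = res.steady_state["ECM"]
            conv[i, j] = res.converged
            cls[i, j] = classify_outcome(ecm[i, j], params.ecm_threshold)
    return SweepResult(A0, B, C, ecm, cls, conv)


@dataclass
class AStarResult:
    """Minimum wound input A0 (on the scan grid) giving a fibrotic outcome."""

    B0: float
    C0: float
    feedback_enabled: bool
    A_star: float | None
    monotone: bool              # every scanned A0 >= A_star was also 'high'


def find_A_star(net: NetworkSpec, params: ParameterSet | None = None,
                B0: float = 0.0, C0: float = 0.0,
                feedback_enabled: bool = True, step: float = 0.01,
                opts: IntegratorOptions | None = None) -> AStarResult:
    """Scan A0 upward from 0 and return the first grid value classified high.

    The scan continues past A* to verify that the high region is an upper
    set of the grid (monotone consistency); ``A_star`` is ``None`` when no
    A0 ≤ 1 produces a fibrotic outcome.
    """
    params = params or ParameterSet()
    grid = np.round(np.arange(0.0, 1.0 + step / 2, step), 10)
    a_star = None
    monotone = True
    for a0 in grid:
        res = run_simulation(net, params, (float(a0), B0, C0),
                             feedback_enabled=feedback_enabled, opts=opts)
        high = classify_outcome(res.steady_state["ECM"], params.ecm_threshold) == "high"
        if a_star is None and high:
            a_star = float(a0)
        elif a_star is not None and not high:
            monotone = False
    return AStarResult(B0, C0, feedback_enabled, a_star, monotone)


def input_robustness_check(
        net: NetworkSpec, params: ParameterSet | None = None,
        scale: float = 0.5,
        conditions: Sequence[PerturbationCondition] | None = None,
        input_sets: Sequence[tuple[float, float, float]] | None = None,
        opts: IntegratorOptions | None = None) -> pd.DataFrame:
    """Re-run the battery with input levels scaled by (1 ± scale).

    Nonzero entries of every input set are multiplied by the scale factor
    and clipped to [0, 1]; zero entries stay zero.  Returns one row per
    condition with its match status at each scaling and a flag for whether
    the status is unchanged from the unscaled battery.
    """
    if not 0.0 < scale < 1.0:
        raise ValueError("scale must lie in (0, 1)")
    params = params or ParameterSet()
    conditions = list(default_conditions() if conditions is None else conditions)
    input_sets = list(default_input_sets() if input_sets is None else input_sets)

    def scaled(sets, factor):
        return [tuple(min(1.0, v * factor) for v in s) for s in sets]

    reports = {
        "baseline": run_perturbation_battery(net, params, conditions, input_sets,
                                             opts=opts),
        "scaled_down": run_perturbation_battery(
            net, params, conditions, scaled(input_sets, 1.0 - scale), opts=opts),
        "scaled_up": run_perturbation_battery(
            net, params, conditions, scaled(input_sets, 1.0 + scale), opts=opts),
    }
    rows = []
    for cond in conditions:
        statuses = {label: rep.condition_match[cond.name]
                    for label, rep in reports.items()}
        rows.append({"condition": cond.name, **statuses,
                     "stable": len(set(statuses.values())) == 1})
    return pd.DataFrame(rows)
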