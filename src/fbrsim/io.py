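"""Result serialization and run configuration.

Simulations export as tidy CSV (one row per time point per node) plus a
JSON summary; every output directory also receives the configuration that
produced it, so a stored run re-executes to identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .dynamics import IntegratorOptions, SimulationResult
from .network import ParameterSet

__all__ = [
    "RunConfig",
    "load_parameters",
    "save_parameters",
    "trajectory_frame",
    "input_trace_frame",
    "write_simulation_outputs",
]

_FLOAT_FMT = "%.9g"


@dataclass
class RunConfig:
    """Everything needed to reproduce one simulation run."""

    network: str = "default"
    inputs0: tuple[float, float, float] = (0.0, 0.0, 0.0)
    clamps: dict[str, float] = field(default_factory=dict)
    feedback_enabled: bool = True
    parameters: dict[str, float] = field(default_factory=dict)
    integrator: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["inputs0"] = list(self.inputs0)
        return d

    def parameter_set(self) -> ParameterSet:
        return ParameterSet(**self.parameters)

    def integrator_options(self) -> IntegratorOptions:
        return IntegratorOptions(**self.integrator)


def load_parameters(path: str | Path) -> ParameterSet:
    """Read a flat key→number mapping (YAML or JSON) into a ParameterSet."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a flat mapping of parameter names")
    valid = set(ParameterSet.__dataclass_fields__)
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"{path}: unknown parameter(s) {sorted(unknown)}")
    params = ParameterSet(**{k: float(v) for k, v in data.items()})
    params.validate()
    return params


def save_parameters(params: ParameterSet, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(params), sort_keys=False))


def trajectory_frame(result: SimulationResult) -> pd.DataFrame:
    """Long-format trajectory: columns time, node, value."""
    rows = [
        {"time": state.time, "node": node, "value": value}
        for state in result.trajectory
        for node, value in state.values.items()
    ]
    return pd.DataFrame(rows)


def input_trace_frame(result: SimulationResult) -> pd.DataFrame:
    """Per-window effective inputs together with the feedback carriers."""
    rows = []
    for w, (a, b, c) in enumerate(result.input_trace):
        state = result.trajectory[min(w + 1, len(result.trajectory) - 1)].values
        rows.append({
            "window": w, "A": a, "B": b, "C": c,
            "Aaux": state.get("Aaux"), "Baux": state.get("Baux"),
            "Caux": state.get("Caux"),
        })
    return pd.DataFrame(rows)


def write_simulation_outputs(result: SimulationResult, out_dir: str | Path,
                             config: RunConfig | None = None) -> dict[str, Path]:
    """Write trajectory CSV, input-trace CSV, steady-state JSON and config."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "trajectory": out / "trajectory.csv",
        "input_trace": out / "input_trace.csv",
        "summary": out / "summary.json",
    }
    trajectory_frame(result).to_csv(paths["trajectory"], index=False,
                                    float_format=_FLOAT_FMT)
    input_trace_frame(result).to_csv(paths["input_trace"], index=False,
                                     float_format=_FLOAT_FMT)
    summary = {
        "steady_state": result.steady_state,
        "converged": result.converged,
        "oscillating": result.oscillating,
        "windows_used": result.windows_used,
    }
    paths["summary"].write_text(json.dumps(summary, indent=2, sort_keys=True))
    if config is not None:
        paths["config"] = out / "config.json"
        paths["config"].write_text(json.dumps(config.to_dict(), indent=2,
                                              sort_keys=True))
    return paths
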