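"""Signed interaction network of the foreign body response (FBR).

The model couples innate-immune signalling to fibroblast activation and
extracellular-matrix (ECM) turnover around an implanted biomaterial.  Nodes
are normalized activation levels in [0, 1]; edges are plain activations or
inhibitions with a relative weight.  Three algebraic input variables drive
the network:

* ``A`` — wound-related inflammatory trigger (tissue damage at implantation),
* ``B`` — immunogenic properties of the material (enhances ``A``),
* ``C`` — mechanical mismatch / stiffness cue (activates myofibroblasts and
  latent TGF-β).

Feedback from the network onto the inputs is carried by three auxiliary
nodes (``Aaux``, ``Baux``, ``Caux``) that are ordinary network variables;
the algebraic update rules that couple them back to A/B/C live in
:mod:`fbrsim.feedback`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

__all__ = [
    "NodeSpec",
    "Edge",
    "NetworkSpec",
    "ParameterSet",
    "build_default_network",
    "default_parameters",
    "validate_network",
    "load_network",
    "save_network",
    "ACTIVATE",
    "INHIBIT",
]

ACTIVATE = "activate"
INHIBIT = "inhibit"

_ROLES = ("dynamic", "constant", "input", "auxiliary")


@dataclass(frozen=True)
class NodeSpec:
    """A network node: a cell population, cytokine, matrix species or input.

    Parameters
    ----------
    name:
        Identifier used in edges and result tables.
    role:
        ``dynamic`` (integrated ODE variable), ``auxiliary`` (integrated ODE
        variable carrying feedback onto an input), ``constant`` (held fixed at
        ``constant_value``) or ``input`` (algebraic, updated between
        integration windows).
    initial_value:
        Starting activation level in [0, 1]; the default model starts every
        dynamic and auxiliary node at 0.
    constant_value:
        Fixed activation level, only meaningful for ``role='constant'``.
    """

    name: str
    role: str = "dynamic"
    initial_value: float = 0.0
    constant_value: float | None = None


@dataclass(frozen=True)
class Edge:
    """A signed interaction ``source -> target``.

    ``weight`` may be left ``None``, in which case it resolves to the named
    parameter appropriate for the edge: ``cx`` for the inputs of the
    C-feedback equation (edges into ``Caux``), ``bx`` for the inputs of the
    B-feedback equation (edges into ``Baux``), and otherwise
    ``alpha_default`` / ``beta_default`` according to the sign.  ``bx`` also
    weighs the B→A coupling inside the input update
    (:func:`fbrsim.feedback.update_input_A`).
    """

    source: str
    target: str
    sign: str
    weight: float | None = None

    def resolve_weight(self, params: "ParameterSet") -> float:
        if self.weight is not None:
            return self.weight
        if self.target == "Caux":
            return params.cx
        if self.target == "Baux":
            return params.bx
        return params.alpha_default if self.sign == ACTIVATE else params.beta_default


@dataclass(frozen=True)
class ParameterSet:
    """Scalar parameters of the standardized FBR model.

    All weights share a single default (0.12) in the standardized-equation
    philosophy; ``cx`` and ``bx`` are named separately so the material inputs
    can be tuned independently.  ``gamma`` is the uniform first-order decay
    rate, ``h`` the sigmoid gain.  ``fA``/``fB``/``fC`` scale the feedback
    of the auxiliary variables onto the inputs, ``caux_threshold`` is the
    minimum ECM + mF activation that lets the stiffness input C grow, and
    ``ecm_threshold`` separates physiological from pathological (fibrotic)
    steady-state ECM.  ``ant_level`` is the constant activation of the lumped
    TGF-β antagonist node.
    """

    alpha_default: float = 0.12
    beta_default: float = 0.12
    cx: float = 0.12
    bx: float = 0.12
    gamma: float = 1.0
    h: float = 1.0
    fA: float = 1.0
    fB: float = 1.0
    fC: float = 1.0
    caux_threshold: float = 0.7
    ecm_threshold: float = 0.35
    ant_level: float = 0.3

    def validate(self) -> None:
        for name in ("alpha_default", "beta_default", "cx", "bx", "gamma", "h",
                     "fA", "fB", "fC"):
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name!r} must be strictly positive")
        for name in ("caux_threshold", "ecm_threshold", "ant_level"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"parameter {name!r} must lie in [0, 1]")

    def replace(self, **kwargs) -> "ParameterSet":
        return replace(self, **kwargs)


def default_parameters() -> ParameterSet:
    """Return the default parameter set of the FBR model."""
    return ParameterSet()


@dataclass
class NetworkSpec:
    """The full signed network: nodes, edges and the Caux gate membership."""

    nodes: list[NodeSpec] = field(default_factory=list)
    edges: list[Edge] = field(default_factory=list)
    caux_gate_members: tuple[str, str] = ("ECM", "mF")

    # -- lookups ---------------------------------------------------------
    def node(self, name: str) -> NodeSpec:
        for n in self.nodes:
            if n.name == name:
                return n
        raise KeyError(name)

    def node_names(self, role: str | None = None) -> list[str]:
        return [n.name for n in self.nodes if role is None or n.role == role]

    def has_node(self, name: str) -> bool:
        return any(n.name == name for n in self.nodes)

    def activators_of(self, name: str) -> list[Edge]:
        return [e for e in self.edges if e.target == name and e.sign == ACTIVATE]

    def inhibitors_of(self, name: str) -> list[Edge]:
        return [e for e in self.edges if e.target == name and e.sign == INHIBIT]

    def __eq__(self, other) -> bool:
        if not isinstance(other, NetworkSpec):
            return NotImplemented
        return (sorted(self.nodes, key=lambda n: n.name) == sorted(other.nodes, key=lambda n: n.name)
                and sorted(self.edges, key=lambda e: (e.source, e.target, e.sign))
                == sorted(other.edges, key=lambda e: (e.source, e.target, e.sign))
                and tuple(self.caux_gate_members) == tuple(other.caux_gate_members))


# ---------------------------------------------------------------------------
# default model
# ---------------------------------------------------------------------------

#: Dynamic variables of the default FBR network: cytokines, growth factors,
#: matrix enzymes, the two macrophage polarization states, fibroblasts (F),
#: myofibroblasts (mF) and the ECM readout.
DYNAMIC_NODES = (
    "TNFa", "IFNg", "IL4", "IL13", "IL10", "IL1b", "IL6",
    "M1", "M2", "TGFb", "PDGF", "MMPs", "TIMPs",
    "F", "mF", "ECM",
)

AUXILIARY_NODES = ("Aaux", "Baux", "Caux")
INPUT_NODES = ("A", "B", "C")

_CYTOKINES = ("TNFa", "IFNg", "IL4", "IL13", "IL10", "IL1b", "IL6")


def _default_edges() -> list[Edge]:
    e: list[Edge] = []

    def act(src, *targets):
        e.extend(Edge(src, t, ACTIVATE) for t in targets)

    def inh(src, *targets):
        e.extend(Edge(src, t, INHIBIT) for t in targets)

    # wound input A recruits the early cytokine milieu and fibroblasts
    act("A", *_CYTOKINES)
    act("A", "F")
    # mechanical input C activates myofibroblasts directly and via latent TGF-β
    act("C", "mF", "TGFb")
    # macrophage polarization
    act("IFNg", "M1")
    act("TNFa", "M1")
    act("IL4", "M2")
    act("IL13", "M2")
    # M1 pro-inflammatory secretion
    act("M1", "IL1b", "IL6", "TNFa")
    # repair-phase growth-factor secretion: M2 macrophages and
    # myofibroblasts are the two cellular TGF-β sources
    act("M2", "TGFb", "PDGF", "MMPs", "IL10")
    act("mF", "TGFb")
    # TGF-β inhibition by IL-10 and the lumped antagonist pool
    inh("IL10", "TGFb")
    inh("Ant", "TGFb")
    # IL-10's anti-inflammatory action: restrains classical macrophage
    # activation and pro-inflammatory cytokine production
    inh("IL10", "M1")
    inh("IL10", "TNFa")
    inh("IL10", "IL6")
    # fibroblast-to-myofibroblast transition (growth factors, the
    # pro-fibrotic interleukins and the mechanical input); activated
    # fibroblasts are consumed by the switch
    act("TGFb", "mF")
    act("PDGF", "mF")
    act("F", "mF")
    act("IL6", "mF")
    act("IL1b", "mF")
    inh("mF", "F")
    # matrix turnover: myofibroblasts deposit ECM; MMPs (secreted by repair
    # macrophages, myofibroblasts and the inflammatory milieu) degrade it;
    # TIMPs of M2 origin restrain the MMPs
    act("mF", "ECM")
    inh("MMPs", "ECM")
    act("mF", "MMPs")
    act("TNFa", "MMPs")
    act("IL1b", "MMPs")
    inh("TIMPs", "MMPs")
    act("M2", "TIMPs")
    # feedback carriers: Aaux dampens A (M2 and ECM resolve inflammation,
    # M1 sustains it), Baux masks B (ECM coats the implant), Caux stiffens C
    act("M2", "Aaux")
    act("ECM", "Aaux")
    inh("M1", "Aaux")
    act("ECM", "Baux")
    act("ECM", "Caux")
    act("mF", "Caux")
    return e


def build_default_network(route_b_to_macrophages: bool = False) -> NetworkSpec:
    """Construct the default literature-based FBR network.

    Parameters
    ----------
    route_b_to_macrophages:
        If True, the immunogenic input B activates M1 and M2 directly instead
        of enhancing the wound input A.  The default (False) routes B into
        the A update, which makes B inert whenever input feedback is
        disabled.
    """
    nodes = [NodeSpec(n, "dynamic") for n in DYNAMIC_NODES]
    nodes += [NodeSpec(n, "auxiliary") for n in AUXILIARY_NODES]
    nodes.append(NodeSpec("Ant", "constant", constant_value=0.3))
    nodes += [NodeSpec(n, "input") for n in INPUT_NODES]
    edges = _default_edges()
    if route_b_to_macrophages:
        edges.append(Edge("B", "M1", ACTIVATE))
        edges.append(Edge("B", "M2", ACTIVATE))
    return NetworkSpec(nodes=nodes, edges=edges)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_network(net: NetworkSpec) -> list[str]:
    """Check structural well-formedness; return one diagnostic per violation.

    A valid network has unique node names, declared edge endpoints, strictly
    positive explicit weights, initial values in [0, 1], at least one
    regulator per integrated (dynamic or auxiliary) node, and no incoming
    edges on constant nodes.
    """
    diags: list[str] = []
    seen: set[str] = set()
    for n in net.nodes:
        if n.name in seen:
            diags.append(f"duplicate node name: {n.name!r}")
        seen.add(n.name)
        if n.role not in _ROLES:
            diags.append(f"node {n.name!r}: unknown role {n.role!r}")
        if not 0.0 <= n.initial_value <= 1.0:
            diags.append(f"node {n.name!r}: initial value {n.initial_value} outside [0, 1]")
        if n.role == "constant":
            if n.constant_value is None or not 0.0 <= n.constant_value <= 1.0:
                diags.append(f"node {n.name!r}: constant value must lie in [0, 1]")
    names = seen
    regulated: set[str] = set()
    for e in net.edges:
        for endpoint in (e.source, e.target):
            if endpoint not in names:
                diags.append(
                    f"dangling endpoint: edge {e.source}->{e.target} names "
                    f"undeclared node {endpoint!r}")
        if e.sign not in (ACTIVATE, INHIBIT):
            diags.append(f"edge {e.source}->{e.target}: unknown sign {e.sign!r}")
        if e.weight is not None and e.weight <= 0:
            diags.append(f"edge {e.source}->{e.target}: nonpositive weight {e.weight}")
        regulated.add(e.target)
    for n in net.nodes:
        if n.role in ("dynamic", "auxiliary") and n.name not in regulated:
            diags.append(f"no regulators: node {n.name!r} has no incoming edges")
        if n.role == "constant" and n.name in regulated:
            diags.append(f"node {n.name!r} is constant but has incoming edges")
    return diags


# ---------------------------------------------------------------------------
# plain-text serialization (SIF-like edge list + node table)
# ---------------------------------------------------------------------------

def save_network(net: NetworkSpec, path: str | Path) -> None:
    """Write a network to the plain-text edge-list/node-table format."""
    lines = ["# fbrsim network file", "[nodes]"]
    for n in net.nodes:
        parts = [n.name, n.role, repr(float(n.initial_value))]
        if n.constant_value is not None:
            parts.append(repr(float(n.constant_value)))
        lines.append(" ".join(parts))
    lines.append("[edges]")
    for e in net.edges:
        parts = [e.source, e.sign, e.target]
        if e.weight is not None:
            parts.append(repr(float(e.weight)))
        lines.append(" ".join(parts))
    lines.append("[gate]")
    lines.append(" ".join(net.caux_gate_members))
    Path(path).write_text("\n".join(lines) + "\n")


class NetworkParseError(ValueError):
    """Raised on malformed network files; message carries the line number."""


def _parse_edge_line(tokens: list[str], lineno: int) -> Edge:
    if len(tokens) not in (3, 4):
        raise NetworkParseError(f"line {lineno}: expected 'SOURCE SIGN TARGET [WEIGHT]'")
    source, sign, target = tokens[:3]
    if sign not in (ACTIVATE, INHIBIT):
        raise NetworkParseError(
            f"line {lineno}: unknown sign token {sign!r} (expected 'activate' or 'inhibit')")
    weight = None
    if len(tokens) == 4:
        try:
            weight = float(tokens[3])
        except ValueError:
            raise NetworkParseError(f"line {lineno}: bad weight {tokens[3]!r}") from None
    return Edge(source, target, sign, weight)


def load_network(path: str | Path) -> NetworkSpec:
    """Read a network from the plain-text format written by :func:`save_network`."""
    nodes: list[NodeSpec] = []
    edges: list[Edge] = []
    gate: tuple[str, str] = ("ECM", "mF")
    section = "edges"  # headerless files are read as a bare edge list
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            section = line[1:-1].strip().lower()
            if section not in ("nodes", "edges", "gate"):
                raise NetworkParseError(f"line {lineno}: unknown section {section!r}")
            continue
        tokens = line.split()
        if section == "nodes":
            if len(tokens) < 2 or len(tokens) > 4:
                raise NetworkParseError(
                    f"line {lineno}: expected 'NAME ROLE [INITIAL [CONSTANT]]'")
            name, role = tokens[:2]
            if role not in _ROLES:
                raise NetworkParseError(f"line {lineno}: unknown role {role!r}")
            try:
                initial = float(tokens[2]) if len(tokens) > 2 else 0.0
                const = float(tokens[3]) if len(tokens) > 3 else None
            except ValueError:
                raise NetworkParseError(f"line {lineno}: bad numeric field") from None
            nodes.append(NodeSpec(name, role, initial, const))
        elif section == "edges":
            edges.append(_parse_edge_line(tokens, lineno))
        else:  # gate
            if len(tokens) != 2:
                raise NetworkParseError(f"line {lineno}: gate section needs two node names")
            gate = (tokens[0], tokens[1])
    if not nodes:
        # bare edge list: synthesize dynamic nodes from edge endpoints
        seen: dict[str, None] = {}
        for e in edges:
            seen.setdefault(e.source)
            seen.setdefault(e.target)
        nodes = [NodeSpec(n, "dynamic") for n in seen]
    return NetworkSpec(nodes=nodes, edges=edges, caux_gate_members=gate)
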