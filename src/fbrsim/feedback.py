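"""Algebraic feedback of the network onto the input variables A, B, C.

The three inputs are not integrated: at the start of each integration window
they are recomputed from their prescribed initial values (A0, B0, C0) and the
end-of-window values of the auxiliary nodes Aaux, Baux, Caux.  The auxiliary
nodes are ordinary standardized-ODE variables; these update rules are the
only place where the network state feeds back onto the inputs.

* A is *dampened*: resolving inflammation (M2, deposited ECM) raises Aaux,
  which is subtracted from A0.  The immunogenic input B *enhances* A through
  the ``bx``-weighted coupling.
* B is *masked*: ECM coating the implant raises Baux, subtracted from B0.
* C *grows*: once the combined ECM + myofibroblast activation passes the
  gate threshold, Caux rises and is added to C0 (progressive stiffening of
  the peri-implant tissue).

All results are constrained to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

from .network import ParameterSet

__all__ = [
    "InputState",
    "update_input_A",
    "update_input_B",
    "update_input_C",
    "update_inputs",
    "caux_gate",
]


@dataclass
class InputState:
    """Prescribed initial inputs and their current effective values."""

    A0: float
    B0: float
    C0: float
    A: float = 0.0
    B: float = 0.0
    C: float = 0.0

    def __post_init__(self):
        for name in ("A0", "B0", "C0"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


def _clip01(x: float) -> float:
    return 0.0 if x < 0.0 else 1.0 if x > 1.0 else x


def update_input_A(A0: float, B_current: float, Aaux_prev: float,
                   params: ParameterSet) -> float:
    """Effective wound input: A0 enhanced by B, dampened by Aaux.

    The update is clip_[0,1](A0 + bx*B - fA*Aaux) with the guard evaluated
    on the raw auxiliary level (not the fA-scaled one): once the auxiliary
    has caught up with the enhanced prescription the input is fully
    resolved (0).  The single final clip means B keeps counteracting the
    feedback even when A0 is already maximal.
    """
    if A0 + params.bx * B_current > Aaux_prev:
        return _clip01(A0 + params.bx * B_current - params.fA * Aaux_prev)
    return 0.0


def update_input_B(B0: float, Baux_prev: float, params: ParameterSet) -> float:
    """Effective immunogenic input: B0 masked by deposited ECM (via Baux)."""
    if B0 > Baux_prev:
        return _clip01(B0 - params.fB * Baux_prev)
    return 0.0


def update_input_C(C0: float, Caux_prev: float, params: ParameterSet) -> float:
    """Effective stiffness input: C0 plus the accumulated Caux feedback."""
    if C0 + Caux_prev <= 1.0:
        return _clip01(C0 + params.fC * Caux_prev)
    return 1.0


def caux_gate(ecm: float, mf: float, threshold: float) -> bool:
    """True (open) iff ECM + mF activation reaches the stiffening threshold.

    While closed, the dynamics force Caux's total input to zero so Caux
    decays toward 0; the boundary counts as open.
    """
    return ecm + mf >= threshold


def update_inputs(A0: float, B0: float, C0: float,
                  aaux: float, baux: float, caux: float,
                  params: ParameterSet) -> tuple[float, float, float]:
    """Recompute (A, B, C) from prescriptions and auxiliary levels.

    B is updated first so the B→A enhancement uses the current effective B.
    """
    b = update_input_B(B0, baux, params)
    a = update_input_A(A0, b, aaux, params)
    c = update_input_C(C0, caux, params)
    return a, b, c
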