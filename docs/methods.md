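# Methods

## Model formalism

Each network node carries a normalized activation level x ∈ [0, 1] — a
normalized concentration for cells and matrix, a lumped
concentration-plus-activity for cytokines and growth factors. All nodes
obey the same standardized rate law

    dx/dt = f(ω; h) − γ·x,
    f(ω; h) = (−e^{h/2} + e^{−h(ω−0.5)}) / ((1 − e^{h/2})(1 + e^{−h(ω−0.5)})),

a sigmoid fixed at (0,0), (0.5,0.5), (1,1) for every gain h > 0. The total
input ω combines the node's activators and inhibitors with the saturating,
weight-normalized form given in the README; a node with only activators
uses the activator term alone, only inhibitors the complement of the
inhibitor term, and both kinds the product act·(1 − inh), so saturated
inhibition always silences a node regardless of activation. The
normalization makes a single fully-active activator produce ω = 1 exactly,
which is what lets every weight default to the same value (0.12) without
the number of regulators changing a node's dynamic range.

This formalism is deliberately semi-quantitative: it identifies stable
steady states and their ordering, not physical time courses. Model time is
dimensionless; with γ = 1 the natural relaxation scale is ~1.

## Inputs and feedback

A, B, C are algebraic, not integrated. The simulation runs in windows of
duration 1.0 (in units of 1/γ): inputs are constant within a window and
recomputed between windows from the feedback-carrier nodes,

    A ← clip[0,1](A0 + bx·B − fA·Aaux)   (0 once Aaux has caught up with A0 + bx·B)
    B ← B0 − fB·Baux if B0 > Baux else 0
    C ← min(1, C0 + fC·Caux)

Aaux integrates the inflammation-resolving influences (M2, ECM activate it;
M1 inhibits it), Baux the implant-coating effect of deposited ECM, and Caux
the progressive stiffening by ECM and contractile myofibroblasts. Caux's
production is gated: its ω is forced to 0 while ECM + mF < 0.7, so the
stiffening loop only engages once substantial matrix and contractile
machinery exist. The boundary counts as open. B is updated before A so the
B→A enhancement uses the current effective B. With feedback disabled the
inputs stay frozen at their prescriptions, which makes B inert by
construction (its only action is through the A update).

The guard in the A and B updates compares the raw auxiliary level (not the
f-scaled one), matching the piecewise definition of the updates; the
distinction only matters when fA or fB differ from 1, as in the sensitivity
battery. The C guard compares C0 + Caux (not C0 + fC·Caux) for the same
reason.

## The default network

The network encodes the consensus macrophage–fibroblast–matrix circuitry of
implant-induced fibrosis. Its core is fixed by the sources the model is
built from: A activates all seven cytokines and fibroblast recruitment; C
activates myofibroblasts directly and through latent TGF-β activation;
IFN-γ/TNF-α polarize M1 and IL-4/IL-13 polarize M2; M1 secretes IL-1β, IL-6
and TNF-α; M2 secretes TGF-β, PDGF, MMPs and IL-10; TGF-β and the
myofibroblast pool itself are the two cellular TGF-β sources alongside C;
IL-10 and a constant lumped antagonist pool (Ant = 0.3) inhibit TGF-β;
TGF-β and PDGF drive the fibroblast→myofibroblast transition, which
depletes fibroblasts; myofibroblasts deposit ECM and MMPs degrade it, with
TIMPs restraining the MMPs.

Where the sources name a player but not its regulators, the package makes
an explicit choice, kept editable as plain configuration (every inferred
edge is an ordinary entry in the default edge list):

* TIMPs ← M2 — tissue-repair macrophages as the TIMP source;
* IL-10 ⊣ M1, TNF-α, IL-6 — IL-10's defining anti-inflammatory program;
* IL-6 → mF and IL-1β → mF — pro-fibrotic interleukin drive on fibroblast
  activation;
* mF → MMPs, TNF-α → MMPs, IL-1β → MMPs — matrix-remodelling proteases from
  the fibroblast lineage and the inflammatory milieu;
* F → mF — the macrophage-independent activation route that leaves residual
  matrix deposition when macrophages are depleted.

These slots were identified by requiring the assembled model to reproduce
the documented system behavior simultaneously: a wound-only baseline
(1,0,0) just above the 0.35 threshold; a ~20% ECM increase from maximal
material inputs; the eight-intervention direction pattern (six matches,
with MMP knockout and IL-4 supplementation as the two principled
mismatches), stable under ±50% input scaling; a sub-threshold ECM ceiling
under macrophage depletion that still rises with C; fully low outcomes at
A0 = 0.1 and fully high at A0 = 0.9 across the material grid; no-feedback
runs never below their feedback counterparts; and sub-10% response to any
single twofold weight change. The calibration target is this qualitative
behavioral fingerprint, not any single number. One reported signature does
not reproduce under this edge list: in the twofold battery the strongest
single weight is PDGF→mF (≈ +9.8% at ×2) rather than the C-equation weight
cx (≈ +2%), and in the ±10% input battery fC outranks the gate threshold —
at this model's baseline the ECM + mF sum (≈ 0.93) sits far above the 0.7
gate, so small threshold shifts are inert.

## Parameters

| name | default | meaning |
|---|---|---|
| alpha_default / beta_default | 0.12 | relative weight of every unnamed activator / inhibitor |
| cx, bx | 0.12 | weights of the C-equation (Caux) and B-equation (Baux) inputs; bx also scales the B→A coupling |
| gamma | 1 | uniform first-order decay rate |
| h | 1 | sigmoid gain; >10 gives switch-like, oscillation-prone dynamics |
| fA, fB, fC | 1 | feedback multipliers in the input updates |
| caux_threshold | 0.7 | ECM + mF level that opens the stiffening gate |
| ecm_threshold | 0.35 | steady-state ECM separating physiological from fibrotic |
| ant_level | 0.3 | constant activation of the lumped TGF-β antagonist pool |

## Numerics

RK45 at (rtol 1e-3, atol 1e-6) integrates each window; a window whose
solution is rejected or overshoots the invariant box (steep high-gain
dynamics) is retried with LSODA at 1e-9, which switches automatically
between Adams and BDF schemes. A run converges when both the state and the
inputs change by ≤ 1e-5 over a window; the budget is 500 windows. States
are clipped into the invariant box after each window, with a hard error if
the excursion exceeds 1e-6 — a bound violation signals a construction bug,
not a tolerance issue. The box is [0, 1] for γ ≥ 1 and [0, 1/γ] otherwise,
since the fixed point of the rate law is f(ω)/γ.

A non-converged run is flagged oscillating when, over its trailing windows,
some node sustains a min–max amplitude above 10× the steady tolerance while
remaining bounded — distinguishing limit cycles (seen for h ≳ 10 at some
material-input combinations) from slow decay. The rule is a pragmatic
detector, not a bifurcation analysis.

At h = 1 the system is quasi-linear and steady states are independent of
the initial values of the intermediate variables (verified by test with
randomized initial conditions); all integrated nodes therefore start at 0.

## Analyses

* **Perturbation battery** — each published antifibrotic intervention is a
  clamp set (knockout = 0, supplementation = 1) held for the whole run; the
  predicted ECM direction versus the unclamped baseline (tolerance 1e-4 on
  ΔECM) is compared with the in vivo outcome at input sets (1,0,0), (1,1,0),
  (1,1,1). Interventions from non-implant fibrosis studies are compared only
  at zero material inputs; a condition counts as a match when every
  comparable cell matches.
* **Input sweeps / A\*** — independent steady-state runs per grid cell;
  A\* scans A0 upward at step 0.01 and verifies that the high region is an
  upper set rather than assuming it.
* **Sensitivity** — one-at-a-time only. The twofold battery varies each
  individual activator/inhibitor weight (with the Caux and Baux input
  weights varied as the named groups cx and bx) at the wound-only baseline,
  where all feedback loops are engaged. The decay rate is excluded by
  default because steady states scale as 1/γ, so a twofold γ change
  rescales the whole solution rather than probing network structure. The
  ±10% input battery reads out the relative ECM difference between (1,0,0)
  and (1,1,1). The gain sweep raises h and records convergence, oscillation
  and the fraction of intermediate (0.1 < ECM < 0.9) outcomes.

## Scope and limitations

The model is a steady-state screening tool: activation levels are
normalized and unitless, so it predicts orderings and classifications, not
capsule thicknesses or time-to-fibrosis. Cell populations are two-state
(M1/M2) without intermediate polarization; foreign-body giant cells,
neutrophils and angiogenesis are not explicit nodes; B is non-degradable by
construction (no prescribed input schedules); and there is no spatial
component. All inputs are synthetic by design — the model's "data" are its
input prescriptions — so passing tests demonstrate internal consistency
with the documented network behavior, not agreement with any particular
experimental time course.
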