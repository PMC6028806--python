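# Methods

## Problem and approach

Wet-lab experiments on cellular signaling each touch a small, overlapping
part of a much larger reaction network. `simexpt` treats each experiment as
a structured document (metadata, biological context, stimuli, readouts, and
a model-mapping block) and runs it as a *simulated experiment* on exactly
the sub-model it addresses: the mapping block names which pathways of the
composite model participate, which entities to delete because they are
absent from the preparation, which parameters to override to match the
experimental conditions (buffers, clamped concentrations), and how
experiment-domain entity names translate to model paths. Each run produces
a non-negative mismatch score; a battery of experiments produces a weighted
global score that a local optimizer can minimize over selected parameters.

## Model representation and kinetics

A model is a tree of pathway groups addressed by rooted `/`-separated
paths. Leaves are pools (species with a concentration in mM), reversible
mass-action reactions, and Michaelis-Menten enzymes. The canonical unit
frame is millimolar / seconds / litres; readers convert on ingest.

For state vector C (non-buffered pools only vary):

- reaction flux: `J = Kf * prod([S_i]^n_i) - Kb * prod([P_j]^m_j)`,
  with Kf in 1/s * (1/mM)^(sum n - 1);
- enzyme flux: `v = kcat * [E] * [S] / (Km + [S])`, transferring substrate
  to product (the enzyme pool is a modifier, not consumed);
- buffered pools have dC/dt = 0 identically: they model species clamped by
  the preparation.

No spatial, stochastic, or rule-based kinetics: those are out of scope.

## Sub-model extraction

`extract_subset` resolves the include selectors (a group selector takes its
whole subtree), removes delete paths (a group path deletes the subtree),
and then checks for *dangling* reactions — reactions or enzymes that lost a
substrate, product, or enzyme pool. The default policy is **strict**: any
dangling reaction aborts extraction with a full report, because a silently
dropped reaction hides a modelling error. The opt-in **prune** policy
removes dangling reactions but logs and reports every one. Loss of
regulatory input (an extracted pathway whose inhibitor was left behind, so
a signal builds up without control) is *not* detected automatically; it
requires inspection of the extracted model, which is why the extracted
sub-model can be exported as SBML for examination. Condition overrides are
applied after extraction; name-map targets must resolve in the extracted
model.

## Experiment classes and their simulation semantics

- **TimeSeries** — stimuli are (time, value) assignments applied
  instantaneously (left-limit state, field set, integrator restarted).
  By default the sub-model is first relaxed to steady state before t=0
  (`settleBeforeStart`), emulating an equilibrated preparation; the flag is
  per-experiment because some protocols start from defined, non-equilibrium
  initial conditions. Output is sampled on a uniform grid (400 points per
  run) and linearly interpolated to the readout times.
- **DoseResponse** — the dose entity is *clamped* (buffered) at each dose
  and the model relaxed to steady state; each dose restarts from the
  initial conditions. Clamping, rather than a one-off bolus, matches
  bath-application protocols; this interpretation is configurable only in
  the sense that a bolus can be written as a TimeSeries experiment.
- **MultiStimulus** — each named combination buffers its listed entities at
  their values at t=0, integrates for the stated settle time, and records
  one readout bar; combinations are independent.
- **Electrical TimeSeries** — a single-compartment Hodgkin-Huxley membrane
  (classic squid-axon parameters: Cm 1 uF/cm^2, gNa 120, gK 36, gLeak
  0.3 mS/cm^2, ENa 50, EK -77, ELeak -54.387 mV; no temperature
  correction) under piecewise-constant current clamp, driven by the same
  document schema with stimulus field `current` and readout field `Vm`.
  This demonstrates that an electrical protocol needs only minor extensions
  of the time-series class, not a calibrated neuron model.

## Numerics

The chemical integrator is SciPy's LSODA (`ode_stiff`, the default —
kinase cascades are routinely stiff) or RK45 (`ode_nonstiff`), rtol 1e-6,
atol 1e-9 mM. Steady state is declared when
`max|dC/dt| / max(1, max|C|) < 1e-6 /s`, probed on doubling time windows up
to t_max 1e5 s; the criterion and horizon are configurable because "steady
state" is an operational choice, and runs that fail to settle are still
reported but flagged. Solver undershoot below zero is clipped to 0 up to
100*atol and treated as failure beyond that. Simultaneous stimulus events
on distinct entities commute (applied between the same two integration
segments). The HH integrator works internally in ms with max_step 0.25 ms
so the ~1 ms spike upstroke cannot be stepped over; gating variables are
initialized at their steady state for the starting potential and checked to
stay in [0, 1].

## Scoring

Scoring formulas come from the experiment file and are evaluated by a
purpose-built recursive-descent parser over a whitelisted grammar
(arithmetic, comparisons, `sum/mean/sqrt/abs/min/max`, variables
`expt/sim/sem/range`) — experiment files are untrusted input, so no general
code evaluation. The default formula is the range-normalized RMS deviation
`sqrt(mean(((expt - sim)/range)**2))` with `range = max(expt) - min(expt)`
(fallback `max|expt|` for flat readouts); it is scale-invariant and zero
iff the fit is exact. Normalization modes (`foldChange`, `percentOfMax`)
are applied to the experimental and simulated series *independently* before
scoring, so relative readouts (gels, fluorescence fold-changes) compare
shapes rather than absolute concentrations. Subjective reliability
judgements enter only through the per-experiment weight; the battery score
is the weighted mean `sum(w_i s_i)/sum(w_i)`, with failed experiments
recorded but excluded.

## Optimization

`optimize_parameters` does derivative-free local minimization (Nelder-Mead)
of the battery score over a user-listed set of positive parameters, in
log10 space (rates and concentrations are scale parameters), with hard
bounds enforced by clipping plus a quadratic penalty. The best *evaluated*
point is returned, so the tuned model never scores worse than the input;
a search whose score is flat to 1e-12 emits an unidentifiability warning.
The method choice is recorded in the trace header. Global/multi-start
optimization is out of scope.

## Synthetic fixtures: what they emulate and what they do not

The fixtures module generates the toy systems the test-suite and the
acceptance script run on, in the same formats users consume:

- reversible binding R + L <-> RL (defaults Rtot 1 mM, Kf 1 /mM/s, Kb
  1 /s, so Kd = 1 mM) — every equilibrium claim has the closed form
  `RL_ss = Rtot*L/(Kd+L)` to check against;
- a three-tier activation cascade (1 mM totals, activation Km 0.3 mM,
  kcat 1/s, first-order relaxation 0.1/s) with EGF-like and Ca-like input
  pathways converging on tier 1, to exercise subset selection and
  multi-stimulus bars;
- a two-pool mutual-activation switch (activation Km 0.1 mM kcat 1/s,
  buffered 1 mM phosphatases with Km 0.05 mM kcat 0.1/s). The saturable
  deactivation makes both the inactive state and a ~0.99 mM active state
  stable: near zero, deactivation slope (kcat*P/Km = 2/s) exceeds the
  activation slope (~0.9/s), while at high activity deactivation saturates
  at 0.1 mM/s below the near-saturated activation rate. A 1 mM, 10 s
  calcium pulse train (onsets 600 s apart) flips low -> high; a 1000-fold
  smaller pulse does not;
- a translation-initiation fragment (40S + eIF4E-mRNA <-> 43S, Kf 1 /mM/s,
  Kb 0.1/s) carrying a 4E-BP sequestration branch that the in-vitro
  experiment deletes, exercising extraction and deletion;
- the squid-axon HH membrane with a 10 uA/cm^2, 40 ms step.

Experiment documents are generated by running the *same* pipeline that
later scores them and writing the simulated values (plus optional Gaussian
noise of stated sd and recorded seed) into the readout block. Passing
self-consistency tests therefore demonstrates that the pipeline is
deterministic and internally coherent — stimulus mapping, extraction,
integration, interpolation, and scoring invert each other — not that any
model reproduces real measurements. Real data add observation noise,
model misspecification, and unit/mapping ambiguity that these fixtures
deliberately lack (noise can be switched on, misspecification is exercised
only through deliberate parameter perturbation). Fixture sizes are chosen
so each simulation completes in seconds on one CPU; they stand in for
composite cellular models orders of magnitude larger.

## Interchange formats

Native model files are a line-oriented, diffable text dialect (exact float
round trip via `repr`). SBML Level 3 (core + groups) import/export covers
compartments, species (buffered pools as boundary-condition species),
mass-action and Michaelis-Menten kinetic laws — recognized by their
local-parameter signature (`Kf`/`Kb` or `k1`/`k2`; `Km`/`kcat` with a
modifier) with anything else rejected naming the reaction — plus the
pathway hierarchy as groups and time-series stimuli as events. Dose clamps
export as boundary species; multi-stimulus combination sets have no SBML
counterpart and are not exported. Experiment documents round-trip through
tsv and JSON with floats reproduced to 12 significant digits (unit
conversion is multiplicative, so bit-exactness is not promised across a
unit change).

## Known limitations

- Path selectors are exact-match, no wildcards; subtree selection makes
  globbing unnecessary for pathway extraction, and ambiguous matches would
  complicate the strict dangling policy.
- Mass-action rate laws only (plus MM enzymes); arbitrary SBML kinetic
  laws are rejected, not approximated.
- No chemical-electrical coupling: the HH membrane and the chemical engine
  share the pipeline, not state.
- The battery runner is sequential; the per-experiment independence
  contract (report invariant under ordering and the jobs flag) is what
  matters for correctness and is tested.
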