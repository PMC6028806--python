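"""Self-contained toy models and matching experiment documents.

Every stage of the pipeline is testable with zero downloads: these
generators build small reaction networks with known closed-form or
reference behaviour, plus experiment documents whose readouts are the
model's own simulated output (optionally with Gaussian noise of stated sd
and recorded seed).  Parameters are chosen so each run completes in a few
seconds on one CPU.

Models:

* reversible bimolecular binding R + L <-> RL (analytic equilibrium
  isotherm, Kd = Kb/Kf);
* an N-tier kinase-like activation cascade with two converging input
  pathways (EGF-like and Ca-like) and first-order deactivation, for subset
  selection and multi-stimulus tests;
* a two-pool mutual-activation positive-feedback switch with two stable
  fixed points (saturable activation, zero-order-like deactivation), which
  a suprathreshold calcium pulse train flips from low to sustained high;
* a translation-initiation fragment (40S + eIF4E-mRNA <-> 43S) carrying an
  extraneous 4E-BP blocking branch that the in-vitro experiment deletes;
* the classic squid-axon Hodgkin-Huxley membrane.
"""

from __future__ import annotations

import numpy as np

from .experiment import (Combination, ExperimentDoc, ExperimentMetadata,
                         ModelMap, ReadoutEntry, StimulusEntry)
from .model import (Compartment, Enzyme, HHCompartment, Pool, Reaction,
                    ReactionModel)
from .subset import SubsetSpec

__all__ = ["make_binding_model", "make_cascade_model", "make_bistable_model",
           "make_translation_fixture", "make_hh_fixture",
           "make_experiment_fixture", "BISTABLE_PULSE_TIMES",
           "BISTABLE_PULSE_AMPLITUDE", "BISTABLE_PULSE_WIDTH"]

def _meta() -> ExperimentMetadata:
    return ExperimentMetadata(transcriber="fixture generator",
                              organization="simexpt", exptSource="inHouse")


def make_binding_model(Rtot: float = 1.0, Kf: float = 1.0,
                       Kb: float = 1.0) -> ReactionModel:
    """Reversible binding R + L <-> RL with known Kd = Kb/Kf (mM).

    At a clamped ligand dose L the equilibrium complex is
    RL_ss = Rtot * L / (Kd + L).
    """
    if min(Rtot, Kf, Kb) <= 0:
        raise ValueError("Rtot, Kf, Kb must all be > 0")
    m = ReactionModel()
    m.add_compartment(Compartment("cyto", 1e-15))
    m.add_group("/kinetics/binding")
    m.add_pool(Pool("/kinetics/binding/R", "cyto", Rtot))
    m.add_pool(Pool("/kinetics/binding/L", "cyto", 0.0))
    m.add_pool(Pool("/kinetics/binding/RL", "cyto", 0.0))
    m.add_reaction(Reaction("/kinetics/binding/bind",
                            [("/kinetics/binding/R", 1),
                             ("/kinetics/binding/L", 1)],
                            [("/kinetics/binding/RL", 1)], Kf, Kb))
    return m


def make_cascade_model(tiers: int = 3) -> ReactionModel:
    """Activation cascade with two converging input pathways.

    Each tier holds an inactive/active pool pair (1 mM total); the active
    form of tier k catalyzes activation of tier k+1 (Km 0.3 mM, kcat 1/s)
    and a first-order back reaction (0.1/s) deactivates each tier.  Two
    input pathway groups (EGF-like and Ca-like entry enzymes) converge on
    tier 1, exercising subset selection.  With zero input every tier rests
    fully inactive (low basal activity).
    """
    if not 1 <= tiers <= 4:
        raise ValueError("tiers must be in 1..4")
    m = ReactionModel()
    m.add_compartment(Compartment("cyto", 1e-15))
    core = "/kinetics/cascade"
    for k in range(1, tiers + 1):
        g = f"{core}/tier{k}"
        m.add_group(g)
        m.add_pool(Pool(f"{g}/X{k}", "cyto", 1.0))
        m.add_pool(Pool(f"{g}/X{k}_act", "cyto", 0.0))
        m.add_reaction(Reaction(f"{g}/relax{k}", [(f"{g}/X{k}_act", 1)],
                                [(f"{g}/X{k}", 1)], 0.1, 0.0))
        if k > 1:
            up = f"{core}/tier{k - 1}/X{k - 1}_act"
            m.add_enzyme(Enzyme(f"{g}/act{k}", up, f"{g}/X{k}",
                                f"{g}/X{k}_act", 0.3, 1.0))
    for tag in ("EGF", "Ca"):
        g = f"/kinetics/input_{tag}"
        m.add_group(g)
        m.add_pool(Pool(f"{g}/{tag}", "cyto", 0.0))
        m.add_enzyme(Enzyme(f"{g}/{tag}_act", f"{g}/{tag}",
                            f"{core}/tier1/X1", f"{core}/tier1/X1_act",
                            0.3, 1.0))
    return m


# calcium pulse protocol that flips the switch: three pulses, onsets 600 s
# apart, 10 s wide, 1 mM amplitude
BISTABLE_PULSE_TIMES = (10.0, 610.0, 1210.0)
BISTABLE_PULSE_WIDTH = 10.0
BISTABLE_PULSE_AMPLITUDE = 1.0


def make_bistable_model() -> ReactionModel:
    """Two-pool mutual-activation positive-feedback switch.

    A_act catalyzes activation of B and B_act of A (Km 0.1 mM, kcat 1/s,
    1 mM totals); buffered phosphatases deactivate each (Km 0.05 mM,
    kcat 0.1/s).  The saturable deactivation makes both the all-inactive
    state and a highly-active state (~0.99 mM) stable; a transient
    suprathreshold calcium input (enzyme on A) flips low -> high, and the
    high state is self-sustaining after the stimulus ends.
    """
    m = ReactionModel()
    m.add_compartment(Compartment("cyto", 1e-15))
    g = "/kinetics/switch"
    m.add_group(g)
    for x in ("A", "B"):
        m.add_pool(Pool(f"{g}/{x}", "cyto", 1.0))
        m.add_pool(Pool(f"{g}/{x}_act", "cyto", 0.0))
        m.add_pool(Pool(f"{g}/P{x}", "cyto", 1.0, buffered=True))
    m.add_enzyme(Enzyme(f"{g}/actA", f"{g}/B_act", f"{g}/A", f"{g}/A_act",
                        0.1, 1.0))
    m.add_enzyme(Enzyme(f"{g}/actB", f"{g}/A_act", f"{g}/B", f"{g}/B_act",
                        0.1, 1.0))
    m.add_enzyme(Enzyme(f"{g}/inactA", f"{g}/PA", f"{g}/A_act", f"{g}/A",
                        0.05, 0.1))
    m.add_enzyme(Enzyme(f"{g}/inactB", f"{g}/PB", f"{g}/B_act", f"{g}/B",
                        0.05, 0.1))
    gi = "/kinetics/input_Ca"
    m.add_group(gi)
    m.add_pool(Pool(f"{gi}/Ca", "cyto", 0.0))
    m.add_enzyme(Enzyme(f"{gi}/Ca_act", f"{gi}/Ca", f"{g}/A", f"{g}/A_act",
                        0.1, 1.0))
    return m


def bistable_pulse_schedule(amplitude: float = BISTABLE_PULSE_AMPLITUDE,
                            n_pulses: int = 3) -> list[tuple[float, float]]:
    """(time, Ca concentration) pairs encoding the pulse train."""
    points = []
    for t in BISTABLE_PULSE_TIMES[:n_pulses]:
        points.append((t, amplitude))
        points.append((t + BISTABLE_PULSE_WIDTH, 0.0))
    return points


def make_translation_fixture(noise_sd: float = 0.0,
                             seed: int = 0) -> tuple[ReactionModel, ExperimentDoc]:
    """Translation-initiation fragment plus its time-series experiment.

    The model binds the small ribosomal subunit to an eIF4E-mRNA complex
    (40S + eIF4E-mRNA <-> 43S, Kf 1 /mM/s, Kb 0.1/s) and carries an
    extraneous branch (4E-BP sequestering eIF4E-mRNA) that is absent from
    the in-vitro preparation: the experiment's model mapping deletes the
    4E-BP pool and its blocking reaction.  The stimulus applies 0.5 mM 40S
    at t = 0; the 43S readout is the model's own simulated time course.
    """
    m = ReactionModel()
    m.add_compartment(Compartment("tube", 1e-15))
    g = "/kinetics/translation"
    m.add_group(g)
    m.add_pool(Pool(f"{g}/40S", "tube", 0.0))
    m.add_pool(Pool(f"{g}/eIF4E-mRNA", "tube", 1.0))
    m.add_pool(Pool(f"{g}/43S", "tube", 0.0))
    m.add_reaction(Reaction(f"{g}/bind43S",
                            [(f"{g}/40S", 1), (f"{g}/eIF4E-mRNA", 1)],
                            [(f"{g}/43S", 1)], 1.0, 0.1))
    m.add_pool(Pool(f"{g}/4E-BP", "tube", 0.5))
    m.add_pool(Pool(f"{g}/blocked-mRNA", "tube", 0.0))
    m.add_reaction(Reaction(f"{g}/block",
                            [(f"{g}/eIF4E-mRNA", 1), (f"{g}/4E-BP", 1)],
                            [(f"{g}/blocked-mRNA", 1)], 5.0, 0.01))

    doc = ExperimentDoc(
        exptType="TimeSeries",
        metadata=_meta(),
        stimuli=[StimulusEntry("40S", "conc", "mM", [(0.0, 0.5)])],
        readouts=[ReadoutEntry("43S", "conc", "mM", "absolute")],
        modelMap=ModelMap(
            refModel="translation.model",
            subset=SubsetSpec(
                includePaths=[g],
                deletePaths=[f"{g}/4E-BP", f"{g}/block",
                             f"{g}/blocked-mRNA"],
                entityMap={"40S": [f"{g}/40S"], "43S": [f"{g}/43S"]}),
            solver="ode_stiff"))
    _fill_readouts(m, doc, coords=[float(t) for t in range(5, 65, 10)],
                   noise_sd=noise_sd, seed=seed)
    return m, doc


def make_hh_fixture(step: float = 10.0, noise_sd: float = 0.0,
                    seed: int = 0) -> tuple[HHCompartment, ExperimentDoc]:
    """Squid-axon HH membrane plus a current-clamp time-series experiment.

    A *step* uA/cm^2 current is injected from 10 to 50 ms; the Vm readout
    is the model's own trace sampled every 2 ms.  This is an original
    demonstration fixture for the electrical experiment class.
    """
    comp = HHCompartment()
    doc = ExperimentDoc(
        exptType="TimeSeries",
        metadata=_meta(),
        stimuli=[StimulusEntry("electrode", "current", "uA",
                               [(0.010, step), (0.050, 0.0)])],
        readouts=[ReadoutEntry("soma", "Vm", "mV", "absolute")],
        modelMap=ModelMap(refModel="squid.model", solver="hh",
                          settleBeforeStart=False))
    coords = [round(0.002 * k, 6) for k in range(1, 36)]
    _fill_readouts(comp, doc, coords=coords, noise_sd=noise_sd, seed=seed)
    return comp, doc


def _fill_readouts(model, doc: ExperimentDoc, *, coords=None, labels=None,
                   noise_sd: float = 0.0, seed: int = 0) -> None:
    """Run the experiment through the pipeline and write the simulated
    values (plus optional Gaussian noise) into the document's readouts."""
    from .pipeline import simulate_experiment

    rng = np.random.default_rng(seed)
    if coords is not None:
        for r in doc.readouts:
            r.points = [(c, 0.0, None) for c in coords]
    if labels is not None:
        for r in doc.readouts:
            r.points = [(lab, 0.0, None) for lab in labels]
    out, _, _ = simulate_experiment(model, doc)
    for r in doc.readouts:
        series = out.trajectories[r.entityName]
        new_points = []
        for coord, _, _ in r.points:
            if out.labels is not None:
                val = float(series[out.labels.index(coord)])
            else:
                val = float(np.interp(coord, out.times, series))
            noise = float(rng.normal(0.0, noise_sd)) if noise_sd > 0 else 0.0
            stderr = noise_sd if noise_sd > 0 else None
            new_points.append((coord, val + noise, stderr))
        r.points = new_points


def make_experiment_fixture(expt_class: str, model: ReactionModel | None = None,
                            *, noise_sd: float = 0.0,
                            seed: int = 0) -> ExperimentDoc:
    """Generate a valid experiment document of the requested class whose
    readouts are the paired model's own simulated output.

    ``expt_class`` is ``TimeSeries`` or ``DoseResponse`` (binding model by
    default) or ``MultiStimulus`` (cascade model by default).  With
    ``noise_sd`` 0 the document scores < 1e-6 against its source model;
    regeneration with the same seed is bit-identical.
    """
    b = "/kinetics/binding"
    if expt_class == "TimeSeries":
        model = model if model is not None else make_binding_model()
        doc = ExperimentDoc(
            exptType="TimeSeries", metadata=_meta(),
            stimuli=[StimulusEntry("ligand", "conc", "mM", [(0.0, 1.0)])],
            readouts=[ReadoutEntry("complex", "conc", "mM", "absolute")],
            modelMap=ModelMap(
                refModel="binding.model",
                subset=SubsetSpec(includePaths=["/kinetics"],
                                  entityMap={"ligand": [f"{b}/L"],
                                             "complex": [f"{b}/RL"]})))
        _fill_readouts(model, doc, coords=[float(t) for t in
                                           range(1, 22, 2)],
                       noise_sd=noise_sd, seed=seed)
        return doc
    if expt_class == "DoseResponse":
        model = model if model is not None else make_binding_model()
        doses = [0.01, 0.03, 0.1, 0.3, 1.0, 3.0, 10.0, 30.0, 100.0]
        doc = ExperimentDoc(
            exptType="DoseResponse", metadata=_meta(),
            stimuli=[StimulusEntry("ligand", "conc", "mM",
                                   [(d, d) for d in doses])],
            readouts=[ReadoutEntry("complex", "conc", "mM", "absolute")],
            modelMap=ModelMap(
                refModel="binding.model",
                subset=SubsetSpec(includePaths=["/kinetics"],
                                  entityMap={"ligand": [f"{b}/L"],
                                             "complex": [f"{b}/RL"]})))
        _fill_readouts(model, doc, coords=doses, noise_sd=noise_sd, seed=seed)
        return doc
    if expt_class == "MultiStimulus":
        model = model if model is not None else make_cascade_model(3)
        top = "/kinetics/cascade/tier3/X3_act"
        doc = ExperimentDoc(
            exptType="MultiStimulus", metadata=_meta(),
            combinations=[
                Combination("control", []),
                Combination("EGF", [("EGF", 0.3)]),
                Combination("Ca", [("Ca", 0.3)]),
                Combination("EGF+Ca", [("EGF", 0.3), ("Ca", 0.3)]),
            ],
            readouts=[ReadoutEntry("MAPK_act", "conc", "mM", "absolute",
                                   settle=300.0)],
            modelMap=ModelMap(
                refModel="cascade.model",
                subset=SubsetSpec(
                    includePaths=["/kinetics"],
                    entityMap={"EGF": ["/kinetics/input_EGF/EGF"],
                               "Ca": ["/kinetics/input_Ca/Ca"],
                               "MAPK_act": [top]})))
        _fill_readouts(model, doc,
                       labels=["control", "EGF", "Ca", "EGF+Ca"],
                       noise_sd=noise_sd, seed=seed)
        return doc
    raise ValueError(f"unknown experiment class {expt_class!r}; expected "
                     "TimeSeries, DoseResponse or MultiStimulus")
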