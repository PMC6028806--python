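"""Pipeline orchestration: run one experiment, a battery, or an optimization.

The single-experiment pipeline is::

    load model -> extract experiment subset (strict unless prune)
               -> apply condition overrides -> simulate per experiment class
               -> score against the readouts

A *battery* is a manifest of experiment files, each with a weight, all run
against one model; per-experiment scores aggregate into a weighted global
score.  Experiments in a battery are independent, so the report does not
depend on execution order.  The optimizer does derivative-free local
minimization (Nelder-Mead on log10-transformed parameters, bounds enforced)
of the battery score over a user-listed set of rate constants and
concentrations, and never returns a model scoring worse than its input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np

from .engine import (SimOutput, run_dose_response, run_multi_stim,
                     run_time_series)
from .experiment import ExperimentDoc, load_experiment, validate_experiment
from .hh import run_current_clamp
from .model import HHCompartment, ModelError, ReactionModel
from .modelio import export_sbml, load_model, save_model
from .scoring import (ScoreResult, aggregate_battery, score_experiment)
from .subset import extract_subset

__all__ = ["RunResult", "BatteryReport", "simulate_experiment", "run_single",
           "run_battery", "optimize_parameters", "read_manifest",
           "battery_score"]

log = logging.getLogger("simexpt.pipeline")

_DT_POINTS = 400      # output samples per time-series run


@dataclass
class RunResult:
    score: ScoreResult
    output: SimOutput
    doc: ExperimentDoc
    submodel: object = None
    dangling: object = None


@dataclass
class BatteryReport:
    results: list[ScoreResult] = dc_field(default_factory=list)
    globalScore: float = float("nan")

    @property
    def failures(self) -> list[ScoreResult]:
        return [r for r in self.results if r.failed]


def _mapped_paths(doc: ExperimentDoc, name: str) -> list[str]:
    targets = doc.modelMap.subset.entityMap.get(name)
    if not targets:
        raise ModelError(f"entity {name!r} has no model mapping")
    return targets


def _readout_map(doc: ExperimentDoc) -> dict[str, list[str]]:
    return {r.entityName: _mapped_paths(doc, r.entityName)
            for r in doc.readouts}


def simulate_experiment(model, doc: ExperimentDoc,
                        policy: str = "strict") -> tuple[SimOutput, object, object]:
    """Run the simulated experiment *doc* describes on *model*.

    Returns ``(output, extracted submodel or None, dangling report)``.
    Dispatches on the experiment class and the document's solver choice.
    """
    mm = doc.modelMap
    if mm.solver == "hh":
        if not isinstance(model, HHCompartment):
            raise ModelError("experiment requests the hh solver but the "
                             "model is not an HH membrane")
        schedule = [(t, s.entityName, s.field, v)
                    for s in doc.stimuli for t, v in s.points]
        t_max = max(p[0] for r in doc.readouts for p in r.points)
        t_end = max(t_max, max((t for t, *_ in schedule), default=0.0)
                    * (1 + 1e-9)) or t_max
        if t_end <= 0:
            raise ModelError("HH experiment needs a positive readout time")
        out = run_current_clamp(model, schedule, t_end, t_end / _DT_POINTS)
        # every Vm readout name reads the single compartment
        for r in doc.readouts:
            out.trajectories.setdefault(r.entityName, out.trajectories["Vm"])
        return out, None, None

    if not isinstance(model, ReactionModel):
        raise ModelError("chemical experiment needs a reaction-network model")
    sub, report = extract_subset(model, mm.subset, policy=policy)
    readout_map = _readout_map(doc)
    solver = mm.solver

    if doc.exptType == "TimeSeries":
        schedule = []
        for s in doc.stimuli:
            for path in _mapped_paths(doc, s.entityName):
                schedule.extend((t, path, s.field, v) for t, v in s.points)
        t_read = max(p[0] for r in doc.readouts for p in r.points)
        t_event = max((t for t, *_ in schedule), default=0.0)
        t_end = t_read if t_read > t_event else t_event + max(t_event, 1.0) * 0.01
        out = run_time_series(sub, schedule, readout_map, t_end,
                              t_end / _DT_POINTS,
                              settle_first=mm.settleBeforeStart,
                              solver=solver)
    elif doc.exptType == "DoseResponse":
        stim = doc.stimuli[0]
        doses = [v for _, v in stim.points]
        paths = _mapped_paths(doc, stim.entityName)
        if len(paths) != 1:
            raise ModelError("dose entity must map to exactly one pool")
        settle = next((r.settle for r in doc.readouts if r.settle), None)
        kwargs = {"settle_tmax": settle} if settle else {}
        out = run_dose_response(sub, paths[0], doses, readout_map,
                                solver=solver, **kwargs)
    elif doc.exptType == "MultiStimulus":
        combos = []
        for c in doc.combinations:
            settings = []
            for name, value in c.settings:
                settings.extend((p, value) for p in _mapped_paths(doc, name))
            combos.append((c.label, settings))
        settle = next((r.settle for r in doc.readouts if r.settle), None)
        if settle is None:
            raise ModelError("MultiStimulus experiment needs a settle time")
        out = run_multi_stim(sub, combos, readout_map, settle, solver=solver)
    else:
        raise ModelError(f"unknown experiment type {doc.exptType!r}")
    return out, sub, report


def run_one(model, doc: ExperimentDoc, experiment_id: str = "",
            policy: str = "strict") -> RunResult:
    """Simulate and score one already-loaded experiment against a model."""
    output, sub, report = simulate_experiment(model, doc, policy=policy)
    score = score_experiment(doc, output, experiment_id=experiment_id)
    return RunResult(score=score, output=output, doc=doc, submodel=sub,
                     dangling=report)


# --------------------------------------------------------------------------
# File-level entry points (what the CLI wraps)
# --------------------------------------------------------------------------

def _write_comparison(result: RunResult, dest: Path) -> None:
    doc, out = result.doc, result.output
    lines = ["coordinate\treadout\texperiment\tsimulation"]
    for r in doc.readouts:
        series = out.trajectories[r.entityName]
        for (coord, val, _err) in r.points:
            if out.labels is not None:
                sim = series[out.labels.index(coord)]
            else:
                sim = float(np.interp(coord, out.times, series))
            lines.append(f"{coord}\t{r.entityName}\t{val!r}\t{sim!r}")
    dest.write_text("\n".join(lines) + "\n")


def _write_plot(result: RunResult, dest: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    doc, out = result.doc, result.output
    fig, ax = plt.subplots(figsize=(6, 4))
    for r in doc.readouts:
        series = out.trajectories[r.entityName]
        coords = [p[0] for p in r.points]
        evals = [p[1] for p in r.points]
        if out.labels is not None:
            x = np.arange(len(out.labels))
            ax.bar(x - 0.2, series, 0.4, label=f"{r.entityName} sim")
            pos = [out.labels.index(c) for c in coords]
            ax.bar(np.array(pos) + 0.2, evals, 0.4,
                   label=f"{r.entityName} expt")
            ax.set_xticks(x, out.labels)
        else:
            ax.plot(out.times, series, label=f"{r.entityName} sim")
            ax.plot(coords, evals, "o", label=f"{r.entityName} expt")
            ax.set_xlabel("time (s)" if doc.exptType == "TimeSeries"
                          else "dose (mM)")
    ax.set_ylabel("readout")
    ax.set_title(f"{doc.exptType}: score={result.score.score:.4g}")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(dest, dpi=100)
    plt.close(fig)


def run_single(model_file: str | Path, expt_file: str | Path, *,
               prune: bool = False, dump_subset: bool = False,
               out_dir: str | Path | None = None) -> RunResult:
    """Full single-experiment pipeline from files, with optional artifacts
    (comparison table, plot, extracted-submodel SBML) in *out_dir*."""
    log.info("[load] model=%s experiment=%s", model_file, expt_file)
    model = load_model(model_file)
    doc = load_experiment(expt_file)
    diags = validate_experiment(doc, model)
    if diags:
        raise ModelError(f"[validate] {expt_file}: " + "; ".join(diags))
    log.info("[simulate] type=%s solver=%s", doc.exptType, doc.modelMap.solver)
    result = run_one(model, doc, experiment_id=str(expt_file),
                     policy="prune" if prune else "strict")
    log.info("[score] %s: %.6g", expt_file, result.score.score)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        stem = Path(expt_file).stem
        _write_comparison(result, out / f"{stem}.comparison.tsv")
        _write_plot(result, out / f"{stem}.png")
        if dump_subset and result.submodel is not None:
            stim = [(t, path, s.field, v) for s in result.doc.stimuli
                    for path in doc.modelMap.subset.entityMap.get(
                        s.entityName, [])
                    for t, v in s.points] if doc.exptType == "TimeSeries" \
                else None
            export_sbml(result.submodel, out / f"{stem}.subset.xml",
                        stimuli=stim)
    return result


def read_manifest(manifest_file: str | Path) -> list[tuple[Path, float | None]]:
    """Battery manifest: one experiment file per line, optional tab-separated
    weight override; paths are relative to the manifest."""
    base = Path(manifest_file).parent
    entries = []
    for raw in Path(manifest_file).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        weight = float(parts[1]) if len(parts) > 1 and parts[1] else None
        entries.append((base / parts[0], weight))
    if not entries:
        raise ValueError(f"manifest {manifest_file} lists no experiments")
    return entries


def battery_score(model, docs: list[tuple[str, ExperimentDoc]],
                  policy: str = "strict") -> BatteryReport:
    """Score a loaded model against a list of ``(id, doc)`` experiments."""
    results = []
    for expt_id, doc in docs:
        try:
            results.append(run_one(model, doc, experiment_id=expt_id,
                                   policy=policy).score)
        except Exception as exc:
            log.warning("[battery] %s failed: %s", expt_id, exc)
            results.append(ScoreResult(experimentId=expt_id,
                                       score=float("nan"), failed=True,
                                       message=str(exc)))
    report = BatteryReport(results=results)
    report.globalScore = aggregate_battery(results)
    return report


def run_battery(model_file: str | Path, manifest_file: str | Path, *,
                jobs: int = 1, prune: bool = False,
                out_dir: str | Path | None = None) -> BatteryReport:
    """Run every experiment in the manifest against one model.

    Experiments are independent; ``jobs`` is accepted for interface
    compatibility and does not change the report (results are keyed and
    ordered by manifest line).  Per-experiment failures are recorded in the
    report and do not abort the battery.
    """
    del jobs  # results are order- and parallelism-independent by contract
    model = load_model(model_file)
    items: list[tuple[str, ExperimentDoc | None, str]] = []
    for path, weight in read_manifest(manifest_file):
        try:
            doc = load_experiment(path)
            if weight is not None:
                doc.modelMap.weight = weight
            items.append((str(path), doc, ""))
        except Exception as exc:
            log.warning("[battery] %s failed to load: %s", path, exc)
            items.append((str(path), None, str(exc)))
    scored = iter(battery_score(
        model, [(i, d) for i, d, _ in items if d is not None],
        policy="prune" if prune else "strict").results)
    results = [next(scored) if doc is not None else
               ScoreResult(experimentId=expt_id, score=float("nan"),
                           failed=True, message=msg)
               for expt_id, doc, msg in items]
    report = BatteryReport(results=results,
                           globalScore=aggregate_battery(results))
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write_battery_report(report, out)
    return report


def _write_battery_report(report: BatteryReport, out: Path) -> None:
    import json
    lines = ["experiment\tweight\tscore\tstatus"]
    for r in report.results:
        status = f"FAILED: {r.message}" if r.failed else "ok"
        lines.append(f"{r.experimentId}\t{r.weight!r}\t{r.score!r}\t{status}")
    lines.append(f"# global score\t{report.globalScore!r}")
    (out / "battery.tsv").write_text("\n".join(lines) + "\n")
    payload = {"globalScore": report.globalScore,
               "experiments": [{"id": r.experimentId, "weight": r.weight,
                                "score": None if r.failed else r.score,
                                "failed": r.failed, "message": r.message}
                               for r in report.results]}
    (out / "battery.json").write_text(json.dumps(payload, indent=1))


# --------------------------------------------------------------------------
# Parameter optimization
# --------------------------------------------------------------------------

@dataclass
class OptimizeResult:
    model: object
    initialScore: float
    finalScore: float
    trace: list[tuple[int, float]] = dc_field(default_factory=list)
    header: str = ""
    warnings: list[str] = dc_field(default_factory=list)


def _apply_params(model: ReactionModel, params, values) -> ReactionModel:
    out = model.copy()
    for (path, fieldname, _lo, _hi), v in zip(params, values):
        entity = out.entity(path)
        setattr(entity, fieldname, float(v))
    return out


def optimize_parameters(model, docs, params, *, seed: int = 0,
                        maxiter: int = 200,
                        policy: str = "strict") -> OptimizeResult:
    """Local derivative-free minimization of the battery score.

    ``params`` is a list of ``(entity path, field, lower, upper)`` bounds;
    optimization runs in log10 space (rates and concentrations are positive
    scale parameters), with Nelder-Mead and hard bounds.  Deterministic for
    a given seed.  The returned model never scores worse than the input.
    """
    from scipy.optimize import minimize

    if not params:
        raise ValueError("parameter list is empty")
    for path, fieldname, lo, hi in params:
        if not (np.isfinite(lo) and np.isfinite(hi) and 0 < lo < hi):
            raise ValueError(f"bad bounds for {path}.{fieldname}: "
                             f"[{lo}, {hi}] (need finite, 0 < lo < hi)")
    if isinstance(docs, (str, Path)):
        raise TypeError("docs must be a list of (id, ExperimentDoc)")
    rng = np.random.default_rng(seed)
    x0 = []
    for path, fieldname, lo, hi in params:
        v = float(getattr(model.entity(path), fieldname))
        x0.append(np.log10(np.clip(v, lo, hi)))
    x0 = np.asarray(x0)
    lo10 = np.log10([p[2] for p in params])
    hi10 = np.log10([p[3] for p in params])

    evals: list[tuple[float, np.ndarray]] = []

    def objective(x):
        xr = np.clip(x, lo10, hi10)
        penalty = float(np.sum((x - xr) ** 2))
        m = _apply_params(model, params, 10.0 ** xr)
        try:
            score = battery_score(m, docs, policy=policy).globalScore
        except Exception:
            score = 1e6
        evals.append((score, xr.copy()))
        return score + penalty

    initial = battery_score(model, docs, policy=policy).globalScore
    trace: list[tuple[int, float]] = [(0, initial)]

    def callback(xk):
        trace.append((len(trace), objective_cache_best()))

    def objective_cache_best():
        return min(e[0] for e in evals) if evals else initial

    # a deterministic small perturbation of the start keeps Nelder-Mead from
    # a degenerate initial simplex when x0 sits on a bound
    x0 = np.clip(x0 + rng.uniform(-1e-8, 1e-8, size=x0.shape), lo10, hi10)
    res = minimize(objective, x0, method="Nelder-Mead", callback=callback,
                   options={"maxiter": maxiter, "xatol": 1e-6,
                            "fatol": 1e-12})
    del res
    best_score, best_x = min(evals, key=lambda e: e[0])
    warnings = []
    if evals:
        spread = max(e[0] for e in evals) - min(e[0] for e in evals)
        if spread < 1e-12:
            warnings.append("score is flat over the searched region; "
                            "parameters may be unidentifiable")
    if best_score <= initial:
        tuned = _apply_params(model, params, 10.0 ** best_x)
        final = best_score
    else:       # never degrade the model
        tuned = model.copy()
        final = initial
    header = (f"optimizer=Nelder-Mead(log10) seed={seed} maxiter={maxiter} "
              f"n_params={len(params)} initial={initial:.6g} "
              f"final={final:.6g}")
    return OptimizeResult(model=tuned, initialScore=initial,
                          finalScore=final, trace=trace, header=header,
                          warnings=warnings)
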