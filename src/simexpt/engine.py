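"""Deterministic ODE simulation of reaction-network models.

State is the vector of pool concentrations (mM).  Each reversible reaction
contributes a mass-action flux ``Kf*prod([S]^nS) - Kb*prod([P]^nP)``; each
enzyme contributes a Michaelis-Menten flux ``kcat*[E]*[S]/(Km+[S])`` from
substrate to product.  Buffered pools have derivative exactly zero.

Three protocols mirror the common experiment classes:

* :func:`run_time_series` — timed assignments ("add ligand at t=300 s"),
  with the integrator restarted at every event;
* :func:`run_dose_response` — the dose entity clamped (buffered) at each
  dose, the model relaxed to steady state, one readout per dose;
* :func:`run_multi_stim` — independent named stimulus combinations, each
  applied at t=0 and read out after a settle period.

The default integrator is LSODA (stiff/non-stiff switching) with
rtol=1e-6, atol=1e-9 mM; kinase cascades are routinely stiff so the stiff
solver is the default.  All runs are fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .model import ModelError, ReactionModel

__all__ = ["SimOutput", "SolverError", "StimulusEvent", "compile_rates",
           "stoichiometry_matrix", "run_time_series", "run_dose_response",
           "run_multi_stim", "find_steady_state"]

RTOL = 1e-6
ATOL = 1e-9          # mM
SS_TOL = 1e-6        # 1/s, relative steady-state criterion
SS_TMAX = 1e5        # s
_NEG_CLIP = 100 * ATOL   # tolerated undershoot before declaring failure

_METHODS = {"ode_stiff": "LSODA", "ode_nonstiff": "RK45"}


class SolverError(RuntimeError):
    pass


# (time_s, pool_path, field, value); field in {conc, concInit, buffered}
StimulusEvent = tuple[float, str, str, object]


@dataclass
class SimOutput:
    """Simulated readouts: a coordinate grid (time, dose, or labelled bars)
    and one concentration/voltage series per readout name."""

    times: np.ndarray
    trajectories: dict[str, np.ndarray]
    labels: list[str] | None = None
    steadyStateReached: list[bool] = field(default_factory=list)

    def series(self, name: str) -> np.ndarray:
        return self.trajectories[name]


class _Compiled:
    """Rate function plus the pool indexing it was compiled against."""

    def __init__(self, model: ReactionModel):
        from .subset import find_dangling
        dang = find_dangling(model)
        if dang:
            raise ModelError(
                "cannot compile rates: dangling reactions present: "
                + "; ".join(p for p, _ in dang.entries))
        self.pool_paths = sorted(model.pools)
        self.index = {p: i for i, p in enumerate(self.pool_paths)}
        self.y0 = np.array([model.pools[p].concInit for p in self.pool_paths])
        self.buffered = np.array([model.pools[p].buffered
                                  for p in self.pool_paths], dtype=bool)
        self.reactions = []
        for path in sorted(model.reactions):
            r = model.reactions[path]
            subs = [(self.index[p], n) for p, n in r.substrates]
            prods = [(self.index[p], n) for p, n in r.products]
            self.reactions.append((subs, prods, r.Kf, r.Kb))
        self.enzymes = []
        for path in sorted(model.enzymes):
            e = model.enzymes[path]
            self.enzymes.append((self.index[e.enzymePool],
                                 self.index[e.substrate],
                                 self.index[e.product], e.Km, e.kcat))

    def __call__(self, t: float, y: np.ndarray) -> np.ndarray:
        dy = np.zeros_like(y)
        yc = np.maximum(y, 0.0)   # guard tiny negative excursions
        for subs, prods, kf, kb in self.reactions:
            fwd = kf
            for i, n in subs:
                fwd *= yc[i] ** n
            back = kb
            for i, n in prods:
                back *= yc[i] ** n
            flux = fwd - back
            for i, n in subs:
                dy[i] -= n * flux
            for i, n in prods:
                dy[i] += n * flux
        for ie, isub, iprod, km, kcat in self.enzymes:
            v = kcat * yc[ie] * yc[isub] / (km + yc[isub])
            dy[isub] -= v
            dy[iprod] += v
        dy[self.buffered] = 0.0
        return dy


def compile_rates(model: ReactionModel):
    """Compile the model into a callable ``f(t, y) -> dy/dt``.

    The callable exposes ``pool_paths`` (state ordering), ``y0``
    (initial concentrations) and ``buffered`` (clamp mask).
    """
    return _Compiled(model)


def stoichiometry_matrix(model: ReactionModel) -> tuple[np.ndarray, list[str]]:
    """Pools x (reactions + enzymes) stoichiometry matrix, for moiety
    (conserved total) analysis."""
    pool_paths = sorted(model.pools)
    index = {p: i for i, p in enumerate(pool_paths)}
    cols = []
    for path in sorted(model.reactions):
        r = model.reactions[path]
        col = np.zeros(len(pool_paths))
        for p, n in r.substrates:
            col[index[p]] -= n
        for p, n in r.products:
            col[index[p]] += n
        cols.append(col)
    for path in sorted(model.enzymes):
        e = model.enzymes[path]
        col = np.zeros(len(pool_paths))
        col[index[e.substrate]] -= 1
        col[index[e.product]] += 1
        cols.append(col)
    S = np.column_stack(cols) if cols else np.zeros((len(pool_paths), 0))
    return S, pool_paths


def _clip_negatives(y: np.ndarray) -> np.ndarray:
    low = y.min(initial=0.0)
    if low < -_NEG_CLIP:
        raise SolverError(f"concentration went negative ({low:g} mM) beyond "
                          "solver tolerance; integration is unreliable")
    return np.maximum(y, 0.0)


def _readout_series(Y: np.ndarray, rates: _Compiled, readout_map) -> dict:
    """Sum trajectories over the pools each readout name maps to."""
    out = {}
    for name, paths in readout_map.items():
        idx = [rates.index[p] for p in paths]
        out[name] = Y[idx].sum(axis=0)
    return out


def _apply_event(rates: _Compiled, y: np.ndarray, path: str, fieldname: str,
                 value) -> None:
    if path not in rates.index:
        raise ModelError(f"stimulus target {path!r} is not a pool in the model")
    i = rates.index[path]
    if fieldname in ("conc", "concInit"):
        v = float(value)
        if v < 0:
            raise ModelError(f"stimulus sets {path} to negative "
                             f"concentration {v}")
        y[i] = v
    elif fieldname == "buffered":
        rates.buffered[i] = bool(value) if not isinstance(value, str) \
            else value.strip().lower() in ("1", "true", "yes")
    else:
        raise ModelError(f"unsupported stimulus field {fieldname!r}")


def run_time_series(model: ReactionModel, schedule: list[StimulusEvent],
                    readout_map: dict[str, list[str]], t_end: float,
                    dt_out: float, *, settle_first: bool = False,
                    solver: str = "ode_stiff", rtol: float = RTOL,
                    atol: float = ATOL) -> SimOutput:
    """Integrate under a timed-assignment stimulus protocol.

    Events are applied instantaneously (state at the left limit, field set,
    integration restarted); simultaneous events on distinct entities commute.
    With ``settle_first`` the model is relaxed to steady state before t=0,
    emulating an equilibrated preparation.
    """
    method = _METHODS.get(solver, "LSODA")
    rates = compile_rates(model)
    schedule = sorted(schedule, key=lambda e: e[0])
    if schedule and schedule[0][0] < 0:
        raise ModelError("stimulus events must have time >= 0")
    if schedule and t_end <= schedule[-1][0]:
        raise ModelError(f"t_end={t_end:g} must exceed the last event time "
                         f"{schedule[-1][0]:g}")
    y = rates.y0.copy()
    if settle_first:
        y, _ = _relax(rates, y, method, rtol, atol, SS_TMAX, SS_TOL)
        y = _clip_negatives(y)

    grid = np.minimum(np.arange(0.0, t_end + dt_out / 2, dt_out), t_end)
    Y = np.empty((len(y), len(grid)))
    filled = np.zeros(len(grid), dtype=bool)

    # segment boundaries at every distinct event time
    times = sorted({t for t, *_ in schedule})
    bounds = [0.0] + [t for t in times if 0.0 < t <= t_end] + [t_end]
    for t, path, fieldname, value in schedule:
        if t == 0.0:
            _apply_event(rates, y, path, fieldname, value)
    t_cursor = 0.0
    for b in bounds[1:]:
        mask = (~filled) & (grid >= t_cursor - 1e-12) & (grid <= b + 1e-12)
        idxs = np.nonzero(mask)[0]
        te = np.clip(grid[idxs], t_cursor, b)
        sol = solve_ivp(rates, (t_cursor, b), y, method=method,
                        t_eval=np.unique(np.concatenate([te, [b]])),
                        rtol=rtol, atol=atol)
        if not sol.success:
            raise SolverError(f"integration failed in segment "
                              f"[{t_cursor:g}, {b:g}] s: {sol.message}")
        yt = _clip_negatives(sol.y)
        for row in range(yt.shape[0]):
            Y[row, idxs] = np.interp(te, sol.t, yt[row])
        filled |= mask
        y = yt[:, -1].copy()
        for t, path, fieldname, value in schedule:
            if t == b:
                _apply_event(rates, y, path, fieldname, value)
        t_cursor = b
    if not filled.all():    # e.g. t_end exactly on an event: fill last point
        for j in np.nonzero(~filled)[0]:
            Y[:, j] = y
    return SimOutput(times=grid,
                     trajectories=_readout_series(Y, rates, readout_map))


def _relax(rates: _Compiled, y0, method, rtol, atol, t_max, tol):
    """Integrate in doubling windows until the relative rate criterion
    max|dC/dt| / max(1, max|C|) < tol, or t_max."""
    y = np.array(y0, dtype=float)
    t, window = 0.0, 10.0

    def _settled(yv):
        dy = rates(0.0, yv)
        return np.max(np.abs(dy)) / max(1.0, np.max(np.abs(yv))) < tol

    if _settled(y):
        return y, True
    while t < t_max:
        t1 = min(t + window, t_max)
        sol = solve_ivp(rates, (t, t1), y, method=method, rtol=rtol,
                        atol=atol, t_eval=[t1])
        if not sol.success:
            raise SolverError(f"steady-state relaxation failed at t={t:g} s: "
                              f"{sol.message}")
        y = sol.y[:, -1]
        t = t1
        if _settled(y):
            return y, True
        window *= 2
    return y, False


def find_steady_state(model: ReactionModel, t_max: float = SS_TMAX,
                      tol: float = SS_TOL, *, solver: str = "ode_stiff",
                      rtol: float = RTOL, atol: float = ATOL):
    """Relax the model from its initial conditions toward steady state.

    Returns ``(state dict pool path -> mM, reached)``; ``reached`` is False
    when the criterion ``max|dC/dt| / max(1, max|C|) < tol`` was not met by
    ``t_max`` (e.g. unbalanced zero-order production grows without bound).
    """
    rates = compile_rates(model)
    y, reached = _relax(rates, rates.y0, _METHODS.get(solver, "LSODA"),
                        rtol, atol, t_max, tol)
    y = _clip_negatives(y)
    return dict(zip(rates.pool_paths, y)), reached


def run_dose_response(model: ReactionModel, dose_entity: str,
                      doses: list[float], readout_map: dict[str, list[str]],
                      *, settle_tmax: float = SS_TMAX, ss_tol: float = SS_TOL,
                      solver: str = "ode_stiff", rtol: float = RTOL,
                      atol: float = ATOL) -> SimOutput:
    """Steady-state readout at each clamped dose of ``dose_entity``.

    Dose semantics are a clamp (bath application): the dose pool is buffered
    at the dose for the whole relaxation.  Each dose starts from the model's
    initial conditions — doses are independent.  Doses that failed to settle
    by ``settle_tmax`` are still reported but flagged.
    """
    doses = list(doses)
    if not doses:
        raise ValueError("dose list is empty")
    if any(b <= a for a, b in zip(doses, doses[1:])):
        raise ValueError("doses must be strictly increasing")
    if any(d < 0 for d in doses):
        raise ValueError("doses must be >= 0")
    method = _METHODS.get(solver, "LSODA")
    rates = compile_rates(model)
    if dose_entity not in rates.index:
        raise ModelError(f"dose entity {dose_entity!r} is not a pool")
    idose = rates.index[dose_entity]
    base_buffered = rates.buffered.copy()
    cols = {name: [] for name in readout_map}
    reached_flags = []
    for dose in doses:
        rates.buffered = base_buffered.copy()
        rates.buffered[idose] = True
        y0 = rates.y0.copy()
        y0[idose] = dose
        y, reached = _relax(rates, y0, method, rtol, atol, settle_tmax, ss_tol)
        y = _clip_negatives(y)
        reached_flags.append(bool(reached))
        series = _readout_series(y[:, None], rates, readout_map)
        for name in readout_map:
            cols[name].append(series[name][0])
    return SimOutput(times=np.asarray(doses, dtype=float),
                     trajectories={k: np.asarray(v) for k, v in cols.items()},
                     steadyStateReached=reached_flags)


def run_multi_stim(model: ReactionModel,
                   combinations: list[tuple[str, list[tuple[str, float]]]],
                   readout_map: dict[str, list[str]], settle: float, *,
                   solver: str = "ode_stiff", rtol: float = RTOL,
                   atol: float = ATOL) -> SimOutput:
    """One readout bar per named stimulus combination.

    Each combination is ``(label, [(pool path, clamp value mM), ...])``; the
    listed pools are buffered at their values at t=0, the model integrates
    for ``settle`` seconds, and the readout is recorded.  Combinations are
    independent (no state carry-over) and duplicated combinations give
    identical values.
    """
    if settle <= 0:
        raise ValueError("settle time must be > 0")
    method = _METHODS.get(solver, "LSODA")
    labels, cols = [], {name: [] for name in readout_map}
    for label, settings in combinations:
        rates = compile_rates(model)
        y = rates.y0.copy()
        for path, value in settings:
            if path not in rates.index:
                raise ModelError(f"combination {label!r}: {path!r} is not a "
                                 "pool in the model")
            i = rates.index[path]
            y[i] = float(value)
            rates.buffered[i] = True
        sol = solve_ivp(rates, (0.0, settle), y, method=method,
                        t_eval=[settle], rtol=rtol, atol=atol)
        if not sol.success:
            raise SolverError(f"combination {label!r}: {sol.message}")
        yf = _clip_negatives(sol.y[:, -1])
        series = _readout_series(yf[:, None], rates, readout_map)
        labels.append(label)
        for name in readout_map:
            cols[name].append(series[name][0])
    return SimOutput(times=np.arange(len(labels), dtype=float),
                     trajectories={k: np.asarray(v) for k, v in cols.items()},
                     labels=labels)
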