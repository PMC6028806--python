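"""Single-compartment Hodgkin-Huxley current-clamp simulator.

Electrical time-series experiments (step current in, membrane-potential
trace out) run through the same experiment pipeline as chemical ones; this
module supplies the membrane model.  The classic squid-axon formulation is
used: three currents (Na+ with m^3*h gating, K+ with n^4, ohmic leak), rate
constants in 1/ms with voltage in mV, no temperature correction.

    Cm dV/dt = I_inj - gNa m^3 h (V-ENa) - gK n^4 (V-EK) - gLeak (V-ELeak)

External times are seconds (the pipeline's canonical frame); the integrator
works in milliseconds internally.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .engine import SimOutput, SolverError, StimulusEvent
from .model import HHCompartment

__all__ = ["run_current_clamp", "resting_potential", "gate_steady_state",
            "spike_count"]


def _alpha_m(v):
    x = v + 40.0
    return np.where(np.abs(x) < 1e-7, 1.0, 0.1 * x / (-np.expm1(-x / 10.0)))


def _beta_m(v):
    return 4.0 * np.exp(-(v + 65.0) / 18.0)


def _alpha_h(v):
    return 0.07 * np.exp(-(v + 65.0) / 20.0)


def _beta_h(v):
    return 1.0 / (1.0 + np.exp(-(v + 35.0) / 10.0))


def _alpha_n(v):
    x = v + 55.0
    return np.where(np.abs(x) < 1e-7, 0.1, 0.01 * x / (-np.expm1(-x / 10.0)))


def _beta_n(v):
    return 0.125 * np.exp(-(v + 65.0) / 80.0)


def gate_steady_state(v: float) -> tuple[float, float, float]:
    """(m_inf, h_inf, n_inf) at clamped potential *v* (mV)."""
    m = _alpha_m(v) / (_alpha_m(v) + _beta_m(v))
    h = _alpha_h(v) / (_alpha_h(v) + _beta_h(v))
    n = _alpha_n(v) / (_alpha_n(v) + _beta_n(v))
    return float(m), float(h), float(n)


def _membrane_current(comp: HHCompartment, v: float) -> float:
    """Net steady-state ionic current at clamped v (uA/cm^2, outward > 0)."""
    m, h, n = gate_steady_state(v)
    return (comp.gNa * m ** 3 * h * (v - comp.ENa)
            + comp.gK * n ** 4 * (v - comp.EK)
            + comp.gLeak * (v - comp.ELeak))


def resting_potential(comp: HHCompartment) -> float:
    """Root of the steady-state current equation between EK and ENa (mV)."""
    return float(brentq(lambda v: _membrane_current(comp, v),
                        comp.EK + 1e-6, comp.ENa - 1e-6, xtol=1e-10))


def _rhs(comp: HHCompartment, current_of_t):
    def f(t_ms, y):
        v, m, h, n = y
        i_inj = current_of_t(t_ms)
        i_ion = (comp.gNa * m ** 3 * h * (v - comp.ENa)
                 + comp.gK * n ** 4 * (v - comp.EK)
                 + comp.gLeak * (v - comp.ELeak))
        return [
            (i_inj - i_ion) / comp.Cm,
            _alpha_m(v) * (1 - m) - _beta_m(v) * m,
            _alpha_h(v) * (1 - h) - _beta_h(v) * h,
            _alpha_n(v) * (1 - n) - _beta_n(v) * n,
        ]
    return f


def run_current_clamp(comp: HHCompartment, schedule: list[StimulusEvent],
                      t_end: float, dt_out: float, *,
                      rtol: float = 1e-7, atol: float = 1e-9) -> SimOutput:
    """Integrate the membrane under a piecewise-constant injected current.

    ``schedule`` events are ``(time_s, entity, 'current', value_uA_per_cm2)``;
    the entity name is ignored (single compartment).  The injected current
    holds its last assigned value between events and starts at 0.  Gating
    variables are initialized at their steady state for the starting Vm.
    Returns a :class:`SimOutput` with a ``Vm`` trace in mV on the seconds
    time grid.
    """
    for _, _, fieldname, _ in schedule:
        if fieldname != "current":
            raise ValueError(f"current clamp accepts only 'current' events, "
                             f"got {fieldname!r}")
    events = sorted(((float(t), float(v)) for t, _, _, v in schedule))
    grid_s = np.minimum(np.arange(0.0, t_end + dt_out / 2, dt_out), t_end)
    grid_ms = grid_s * 1e3

    m, h, n = gate_steady_state(comp.Vm)
    y = np.array([comp.Vm, m, h, n])
    bounds_ms = [0.0] + [t * 1e3 for t, _ in events if 0 < t <= t_end] \
        + [t_end * 1e3]
    current = 0.0
    for t, v in events:
        if t == 0.0:
            current = v
    vm = np.empty(len(grid_ms))
    filled = np.zeros(len(grid_ms), dtype=bool)
    t_cursor = 0.0
    for b in bounds_ms[1:]:
        mask = (~filled) & (grid_ms >= t_cursor - 1e-9) & (grid_ms <= b + 1e-9)
        idxs = np.nonzero(mask)[0]
        te = np.clip(grid_ms[idxs], t_cursor, b)
        t_eval = np.unique(np.concatenate([te, [b]]))
        i_now = current
        sol = solve_ivp(_rhs(comp, lambda t_ms, i=i_now: i), (t_cursor, b), y,
                        method="LSODA", t_eval=t_eval, rtol=rtol, atol=atol,
                        max_step=0.25)  # ms; resolves the ~1 ms spike upstroke
        if not sol.success:
            raise SolverError(f"HH integration failed: {sol.message}")
        if len(idxs):
            vm[idxs] = np.interp(te, sol.t, sol.y[0])
        filled |= mask
        y = sol.y[:, -1].copy()
        gates = np.clip(y[1:], 0.0, 1.0)
        if np.max(np.abs(gates - y[1:])) > 1e-6:
            raise SolverError("gating variable left [0, 1] beyond tolerance")
        y[1:] = gates
        for t, v in events:
            if t * 1e3 == b:
                current = v
        t_cursor = b
    if not filled.all():
        vm[~filled] = y[0]
    return SimOutput(times=grid_s, trajectories={"Vm": vm})


def spike_count(vm: np.ndarray, threshold: float = 0.0) -> int:
    """Number of upward crossings of *threshold* (mV) in a Vm trace."""
    above = np.asarray(vm) > threshold
    return int(np.sum(~above[:-1] & above[1:]))
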