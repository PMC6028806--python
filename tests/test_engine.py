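"""ODE engine: closed-form agreement, conservation, events, steady states,
and the bistable-switch behaviour."""

import math

import numpy as np
import pytest
from scipy.linalg import null_space

import simexpt as sx
from simexpt import fixtures as fx
from simexpt.model import Compartment, Enzyme, Pool, Reaction, ReactionModel

B = "/kinetics/binding"
RTOL = 1e-6


def two_pool_model(Kf=1.0, Kb=2.0, A0=1.0, B0=1.0):
    m = ReactionModel()
    m.add_compartment(Compartment("c"))
    m.add_pool(Pool("/m/A", "c", A0))
    m.add_pool(Pool("/m/B", "c", B0))
    m.add_reaction(Reaction("/m/r", [("/m/A", 1)], [("/m/B", 1)], Kf, Kb))
    return m


class TestCompileRates:
    def test_hand_evaluated_mass_action(self):
        # A<->B, Kf=1, Kb=2 at (A,B)=(1,1): dA/dt = -1*1 + 2*1 = +1 mM/s
        rates = sx.compile_rates(two_pool_model())
        dy = rates(0.0, np.array([1.0, 1.0]))
        iA = rates.pool_paths.index("/m/A")
        iB = rates.pool_paths.index("/m/B")
        assert dy[iA] == pytest.approx(1.0)
        assert dy[iB] == pytest.approx(-1.0)

    def test_buffered_pool_derivative_zero(self):
        m = two_pool_model()
        m.pools["/m/A"].buffered = True
        rates = sx.compile_rates(m)
        for state in ([1.0, 1.0], [5.0, 0.1], [0.0, 3.0]):
            dy = rates(0.0, np.array(state))
            assert dy[rates.pool_paths.index("/m/A")] == 0.0

    def test_enzyme_half_saturation(self):
        m = ReactionModel()
        m.add_compartment(Compartment("c"))
        m.add_pool(Pool("/m/E", "c", 0.5))
        m.add_pool(Pool("/m/S", "c", 0.3))   # == Km
        m.add_pool(Pool("/m/P", "c", 0.0))
        m.add_enzyme(Enzyme("/m/enz", "/m/E", "/m/S", "/m/P", 0.3, 2.0))
        rates = sx.compile_rates(m)
        dy = rates(0.0, rates.y0)
        iP = rates.pool_paths.index("/m/P")
        # v = kcat*E/2 at [S]=Km
        assert dy[iP] == pytest.approx(2.0 * 0.5 / 2)

    def test_dangling_model_refused(self, binding_model):
        del binding_model.pools[f"{B}/L"]
        with pytest.raises(sx.ModelError, match="dangling"):
            sx.compile_rates(binding_model)


class TestTimeSeries:
    def test_exponential_decay_closed_form(self):
        m = ReactionModel()
        m.add_compartment(Compartment("c"))
        m.add_pool(Pool("/m/A", "c", 1.0))
        m.add_pool(Pool("/m/B", "c", 0.0))
        m.add_reaction(Reaction("/m/r", [("/m/A", 1)], [("/m/B", 1)],
                                0.1, 0.0))
        out = sx.run_time_series(m, [], {"A": ["/m/A"]}, 10.0, 0.1)
        assert out.series("A")[-1] == pytest.approx(math.exp(-1.0),
                                                    rel=10 * RTOL)

    def test_equilibrium_is_invariant(self):
        # start exactly at the A<->B fixed point: B/A = Kf/Kb
        m = two_pool_model(Kf=1.0, Kb=2.0, A0=2.0 / 3, B0=1.0 / 3)
        out = sx.run_time_series(m, [], {"A": ["/m/A"], "B": ["/m/B"]},
                                 100.0, 1.0)
        assert np.allclose(out.series("A"), 2.0 / 3, rtol=1e-5)

    def test_three_pulses_appear_in_input_trajectory(self, bistable_model):
        sched = [(t, "/kinetics/input_Ca/Ca", "conc", v)
                 for t, v in fx.bistable_pulse_schedule()]
        out = sx.run_time_series(bistable_model, sched,
                                 {"Ca": ["/kinetics/input_Ca/Ca"]},
                                 2000.0, 1.0)
        ca = out.series("Ca")
        rising = np.sum((ca[1:] > 0.5) & (ca[:-1] < 0.5))
        assert rising == 3

    def test_simultaneous_event_order_irrelevant(self, cascade_model):
        ev = [(5.0, "/kinetics/input_EGF/EGF", "conc", 0.2),
              (5.0, "/kinetics/input_Ca/Ca", "conc", 0.1)]
        rmap = {"top": ["/kinetics/cascade/tier3/X3_act"]}
        a = sx.run_time_series(cascade_model, ev, rmap, 50.0, 0.5)
        b = sx.run_time_series(cascade_model, list(reversed(ev)), rmap,
                               50.0, 0.5)
        assert np.array_equal(a.series("top"), b.series("top"))

    def test_bit_identical_reruns(self, cascade_model):
        ev = [(5.0, "/kinetics/input_EGF/EGF", "conc", 0.2)]
        rmap = {"top": ["/kinetics/cascade/tier3/X3_act"]}
        a = sx.run_time_series(cascade_model, ev, rmap, 50.0, 0.5)
        b = sx.run_time_series(cascade_model, ev, rmap, 50.0, 0.5)
        assert np.array_equal(a.series("top"), b.series("top"))


@pytest.mark.parametrize("maker", [fx.make_binding_model,
                                   fx.make_bistable_model])
def test_moiety_conservation(maker):
    """Null-space moiety totals stay constant to 1e-6 relative over a
    stimulated trajectory."""
    m = maker()
    for pool in m.pools.values():
        pool.buffered = False     # closed system
    S, pool_paths = sx.stoichiometry_matrix(m)
    moieties = null_space(S.T).T
    assert moieties.shape[0] >= 1
    rmap = {p: [p] for p in pool_paths}
    first = sorted(m.pools)[0]
    out = sx.run_time_series(m, [(0.0, first, "conc", 0.8)], rmap,
                             200.0, 1.0)
    Y = np.vstack([out.series(p) for p in pool_paths])
    for w in moieties:
        tot = w @ Y
        scale = max(1e-12, np.abs(tot[0]))
        assert np.max(np.abs(tot - tot[0])) / scale < 1e-6


class TestDoseResponse:
    def test_binding_isotherm_closed_form(self, binding_model):
        # Kd = Kb/Kf = 1 mM; dose L=Kd gives RL = Rtot/2
        out = sx.run_dose_response(binding_model, f"{B}/L", [1.0],
                                   {"RL": [f"{B}/RL"]})
        assert out.series("RL")[0] == pytest.approx(0.5, rel=10 * RTOL)
        assert out.steadyStateReached == [True]

    def test_zero_dose_equals_unstimulated_steady_state(self, binding_model):
        out = sx.run_dose_response(binding_model, f"{B}/L", [0.0],
                                   {"RL": [f"{B}/RL"]})
        assert out.series("RL")[0] == pytest.approx(0.0, abs=1e-9)

    def test_isotherm_monotone_over_four_decades(self, binding_model):
        doses = [0.01, 0.1, 0.5, 1.0, 5.0, 10.0, 100.0]
        out = sx.run_dose_response(binding_model, f"{B}/L", doses,
                                   {"RL": [f"{B}/RL"]})
        rl = out.series("RL")
        assert np.all(np.diff(rl) >= -1e-9)
        expected = [1.0 * d / (1.0 + d) for d in doses]
        # shape check; the sharp tolerance check lives in the Kd-dose test
        assert np.allclose(rl, expected, rtol=1e-3)

    def test_bad_dose_lists_rejected(self, binding_model):
        with pytest.raises(ValueError):
            sx.run_dose_response(binding_model, f"{B}/L", [1.0, 1.0],
                                 {"RL": [f"{B}/RL"]})
        with pytest.raises(ValueError):
            sx.run_dose_response(binding_model, f"{B}/L", [],
                                 {"RL": [f"{B}/RL"]})


class TestMultiStim:
    def test_activator_beats_control(self, cascade_model):
        rmap = {"top": ["/kinetics/cascade/tier3/X3_act"]}
        out = sx.run_multi_stim(
            cascade_model,
            [("control", []), ("EGF", [("/kinetics/input_EGF/EGF", 0.3)])],
            rmap, 300.0)
        ctrl, egf = out.series("top")
        assert egf > ctrl

    def test_duplicate_combination_identical(self, cascade_model):
        rmap = {"top": ["/kinetics/cascade/tier3/X3_act"]}
        combo = ("EGF", [("/kinetics/input_EGF/EGF", 0.3)])
        out = sx.run_multi_stim(cascade_model, [combo, combo], rmap, 300.0)
        vals = out.series("top")
        assert vals[0] == vals[1]

    def test_buffering_the_readout_clamps_the_bar(self, cascade_model):
        top = "/kinetics/cascade/tier3/X3_act"
        out = sx.run_multi_stim(cascade_model,
                                [("clamp", [(top, 0.42)])],
                                {"top": [top]}, 100.0)
        assert out.series("top")[0] == pytest.approx(0.42, abs=1e-9)


class TestSteadyState:
    def test_reversible_pair_detailed_balance(self):
        m = two_pool_model(Kf=1.0, Kb=2.0, A0=0.9, B0=0.1)
        state, reached = sx.find_steady_state(m)
        assert reached
        ratio = state["/m/B"] / state["/m/A"]
        assert ratio == pytest.approx(0.5, rel=1e-5)   # Kf/Kb

    def test_isolated_pool_settles_immediately(self):
        m = ReactionModel()
        m.add_compartment(Compartment("c"))
        m.add_pool(Pool("/m/X", "c", 0.7))
        state, reached = sx.find_steady_state(m)
        assert reached and state["/m/X"] == 0.7

    def test_unbounded_production_never_settles(self):
        m = ReactionModel()
        m.add_compartment(Compartment("c"))
        m.add_pool(Pool("/m/src", "c", 1.0, buffered=True))
        m.add_pool(Pool("/m/P", "c", 0.0))
        m.add_reaction(Reaction("/m/make", [("/m/src", 1)], [("/m/P", 1)],
                                1.0, 0.0))
        state, reached = sx.find_steady_state(m, t_max=100.0)
        assert not reached
        assert state["/m/P"] > 50.0


class TestBistableSwitch:
    """Positive-feedback switch: sustained activation after a pulse train."""

    RMAP = {"A_act": ["/kinetics/switch/A_act"]}
    CA = "/kinetics/input_Ca/Ca"

    def test_no_stimulus_stays_low(self, bistable_model):
        out = sx.run_time_series(bistable_model, [], self.RMAP, 3600.0, 30.0)
        assert np.all(out.series("A_act") < 0.05)

    def test_three_pulses_flip_to_sustained_high(self, bistable_model):
        sched = [(t, self.CA, "conc", v)
                 for t, v in fx.bistable_pulse_schedule()]
        t_end = fx.BISTABLE_PULSE_TIMES[-1] + fx.BISTABLE_PULSE_WIDTH + 3600.0
        out = sx.run_time_series(bistable_model, sched, self.RMAP, t_end, 5.0)
        act = out.series("A_act")
        after = act[out.times >= fx.BISTABLE_PULSE_TIMES[-1] + 60.0]
        assert np.all(after > 0.9)      # high and sustained >= 3600 s

    def test_thousandfold_subthreshold_pulse_stays_low(self, bistable_model):
        sched = [(t, self.CA, "conc", v * 1e-3)
                 for t, v in fx.bistable_pulse_schedule()]
        out = sx.run_time_series(bistable_model, sched, self.RMAP,
                                 5000.0, 10.0)
        assert np.all(out.series("A_act") < 0.05)
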