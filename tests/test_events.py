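"""Event semantics: edge detection, the priority cascade, persistence,
delayed assignments with value capture, and the history buffer."""

import math
import random

import numpy as np
import pytest

from sbmlsim import MethodSpec, SimulationConfig, load_model, simulate
from sbmlsim.equations import build_ode_system
from sbmlsim.events import (
    EventPrograms,
    HistoryBuffer,
    TriggerMemory,
    detect_triggers,
    fire_due_assignments,
    history_lookup,
    run_event_cascade,
    schedule_delayed,
)
from sbmlsim.fixtures import make_fixture
from sbmlsim.loader import resolve_initial_state


# ---------------------------------------------------------------------------
# Trigger edge detection
# ---------------------------------------------------------------------------

class TestDetect:
    def _setup(self, **fixture_kw):
        model = load_model(make_fixture("event_basic", **fixture_kw))
        system = build_ode_system(model)
        programs = EventPrograms(model)
        state = resolve_initial_state(model)
        return model, system, programs, state

    def test_rising_edge_fires(self):
        model, system, programs, state = self._setup()
        memory = TriggerMemory()
        memory.previous["E1"] = False
        idx = model.variable_index
        state[idx["S1"]] = 2.1  # trigger is S1 < 5 -> true
        fired = detect_triggers(programs, system.context_values(state, 0.0),
                                0.0, memory)
        assert [e.id for e in fired] == ["E1"]
        assert memory.previous["E1"] is True

    def test_level_high_does_not_refire(self):
        model, system, programs, state = self._setup()
        memory = TriggerMemory()
        memory.previous["E1"] = True
        state[model.variable_index["S1"]] = 2.0  # still true
        fired = detect_triggers(programs, system.context_values(state, 0.0),
                                0.0, memory)
        assert fired == []

    def test_true_at_t0_does_not_fire_under_l2_semantics(self):
        # trigger S1 < 5 already true at t=0 with s0 = 1
        model = load_model(make_fixture("event_basic", s0=1.0, level=(2, 4)))
        tc = simulate(model, SimulationConfig(duration=0.5, output_steps=5))
        # no reset to 10 at t=0; S1 decays from 1 until the *next* edge
        assert tc["S1"][0] == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# The worked cascade regression (locked step by step)
# ---------------------------------------------------------------------------

def _cascade_setup(tag):
    model = load_model(make_fixture(tag))
    system = build_ode_system(model)
    programs = EventPrograms(model)
    state = resolve_initial_state(model)
    memory = TriggerMemory.initialize(programs)
    return model, system, programs, state, memory


def test_priority_persistence_cascade_trace():
    """Two events fire together: E1 (priority 2) zeroes S1; E2
    (priority 1, persistent=false, trigger needs S1 > 0.5) must be
    re-checked, found lapsed, and removed without executing."""
    model, system, programs, state, memory = _cascade_setup("event_priority")
    idx = model.variable_index
    t = 1.0
    fired = [programs.by_id("E1"), programs.by_id("E2")]
    memory.previous["E1"] = memory.previous["E2"] = True
    log = []
    pending = []
    run_event_cascade(programs, fired, system, state, t,
                      random.Random(0), memory, pending, log_list=log)
    assert log == ["E1"]                       # E2 never executed
    assert state[idx["S1"]] == 0.0
    assert state[idx["S2"]] == 0.0             # unchanged
    assert pending == []


def test_persistent_variant_executes_both():
    model, system, programs, state, memory = _cascade_setup("event_persistent")
    idx = model.variable_index
    fired = [programs.by_id("E1"), programs.by_id("E2")]
    log = []
    run_event_cascade(programs, fired, system, state, 1.0,
                      random.Random(0), memory, [], log_list=log)
    assert log == ["E1", "E2"]                 # priority order, both run
    assert state[idx["S2"]] == 9.0


def test_assignment_can_chain_trigger_another_event():
    """E1's assignment flips E2's trigger false -> true mid-cascade, so
    E2 is enqueued (step v) and executed."""
    xml = make_fixture("event_priority")
    # change E2's trigger to fire when S1 drops BELOW 0.5 (E1's doing)
    xml = xml.replace("<apply><gt/><ci> S1 </ci><cn> 0.5 </cn></apply>",
                      "<apply><lt/><ci> S1 </ci><cn> 0.5 </cn></apply>")
    model = load_model(xml)
    system = build_ode_system(model)
    programs = EventPrograms(model)
    state = resolve_initial_state(model)
    memory = TriggerMemory.initialize(programs)
    memory.previous["E1"] = True
    memory.previous["E2"] = False
    log = []
    run_event_cascade(programs, [programs.by_id("E1")], system, state, 1.0,
                      random.Random(0), memory, [], log_list=log)
    assert log == ["E1", "E2"]
    assert state[model.variable_index["S2"]] == 9.0


def test_three_event_priority_total_order():
    xml = make_fixture("event_priority")
    extra = ('<event id="E3" useValuesFromTriggerTime="true">'
             '<trigger persistent="true" initialValue="true">'
             '<math xmlns="http://www.w3.org/1998/Math/MathML">'
             "<apply><geq/><csymbol encoding=\"text\" definitionURL="
             "\"http://www.sbml.org/sbml/symbols/time\"> t </csymbol>"
             "<cn> 1 </cn></apply></math></trigger>"
             "<priority><math xmlns=\"http://www.w3.org/1998/Math/MathML\">"
             "<cn> 3 </cn></math></priority>"
             "<listOfEventAssignments>"
             '<eventAssignment variable="S2">'
             '<math xmlns="http://www.w3.org/1998/Math/MathML">'
             "<cn> 1 </cn></math></eventAssignment>"
             "</listOfEventAssignments></event>")
    xml = xml.replace("</listOfEvents>", extra + "</listOfEvents>")
    model = load_model(xml)
    system = build_ode_system(model)
    programs = EventPrograms(model)
    state = resolve_initial_state(model)
    # make E2 persistent so all three run: execution must descend 3,2,1
    programs.by_id("E2").persistent = True
    memory = TriggerMemory.initialize(programs)
    log = []
    fired = [programs.by_id(e) for e in ("E1", "E2", "E3")]
    run_event_cascade(programs, fired, system, state, 1.0,
                      random.Random(1), memory, [], log_list=log)
    assert log == ["E3", "E1", "E2"]


def test_cascade_determinism_with_fixed_seed():
    results = []
    for _ in range(2):
        model = load_model(make_fixture("event_priority"))
        tc = simulate(model, SimulationConfig(duration=2.0, output_steps=10,
                                              seed=123))
        results.append((tuple(tc["S1"]), tuple(tc["S2"])))
    assert results[0] == results[1]  # bitwise


# ---------------------------------------------------------------------------
# Delayed assignments
# ---------------------------------------------------------------------------

def test_delay_capture_at_trigger_time():
    # trigger at t=1, delay 2, p_tracked = 4 + t: captured value is 5
    model = load_model(make_fixture("event_delay", uvftt=True))
    tc = simulate(model, SimulationConfig(duration=5.0, output_steps=10))
    t = tc.times
    s1 = tc["S1"]
    assert s1[t < 3.0][-1] == 0.0       # nothing before fire time
    assert s1[t >= 3.0][0] == pytest.approx(5.0)


def test_delay_evaluation_at_fire_time():
    model = load_model(make_fixture("event_delay", uvftt=False))
    tc = simulate(model, SimulationConfig(duration=5.0, output_steps=10))
    assert tc["S1"][tc.times >= 3.0][0] == pytest.approx(7.0)


def test_negative_delay_rejected():
    model = load_model(make_fixture("event_delay"))
    programs = EventPrograms(model)
    ev = programs.by_id("E1")
    from sbmlsim.errors import EventError
    programs.delay["E1"].instructions[:] = [("const", -1.0)]
    with pytest.raises(EventError):
        schedule_delayed(programs, ev, 1.0, {"p_tracked": 5.0, "S1": 0.0})


def test_zero_delay_fires_at_trigger_time():
    xml = make_fixture("event_delay").replace(
        "<delay><math xmlns=\"http://www.w3.org/1998/Math/MathML\">"
        '<cn type="integer"> 2 </cn></math></delay>',
        "<delay><math xmlns=\"http://www.w3.org/1998/Math/MathML\">"
        '<cn type="integer"> 0 </cn></math></delay>')
    model = load_model(xml)
    tc = simulate(model, SimulationConfig(duration=2.0, output_steps=4))
    assert tc["S1"][tc.times >= 1.0][0] == pytest.approx(5.0)


def test_empty_pending_is_identity():
    model = load_model(make_fixture("event_delay"))
    system = build_ode_system(model)
    programs = EventPrograms(model)
    state = resolve_initial_state(model)
    before = state.copy()
    assert not fire_due_assignments(programs, [], system, state, 1.0,
                                    random.Random(0))
    assert np.array_equal(state, before)


# ---------------------------------------------------------------------------
# History buffer
# ---------------------------------------------------------------------------

class TestHistory:
    def _buffer(self, model):
        buf = HistoryBuffer()
        idx = model.variable_index
        s0 = np.zeros(len(idx))
        s1 = np.zeros(len(idx))
        s0[idx["S1"]] = 1.0
        s1[idx["S1"]] = 3.0
        s0[idx["c"]] = s1[idx["c"]] = 1.0
        buf.append(0.0, s0)
        buf.append(1.0, s1)
        return buf

    def test_midpoint_interpolation(self, decay_model):
        buf = self._buffer(decay_model)
        assert history_lookup(buf, decay_model, "S1", 0.5) == pytest.approx(2.0)

    def test_before_history_returns_initial(self, decay_model):
        buf = self._buffer(decay_model)
        assert history_lookup(buf, decay_model, "S1", -5.0) == 1.0

    def test_beyond_last_clamps(self, decay_model):
        buf = self._buffer(decay_model)
        assert history_lookup(buf, decay_model, "S1", 99.0) == 3.0

    def test_unknown_variable_rejected(self, decay_model):
        from sbmlsim.errors import ModelSemanticError
        buf = self._buffer(decay_model)
        with pytest.raises(ModelSemanticError):
            history_lookup(buf, decay_model, "ghost", 0.5)

    def test_strictly_increasing_enforced(self, decay_model):
        buf = self._buffer(decay_model)
        with pytest.raises(ValueError):
            buf.append(0.5, np.zeros(2))


def test_dde_first_interval_matches_method_of_steps():
    """y'(t) = -y(t-1) with y = 1 for t <= 0 has the exact solution
    y(t) = 1 - t on [0, 1]."""
    model = load_model(make_fixture("delay_expression", lag=1.0))
    tc = simulate(model, SimulationConfig(
        duration=1.0, output_steps=10, refinement=100,  # h = 1e-3, RK4
        method=MethodSpec("rk4")))
    assert np.max(np.abs(tc["y"] - (1.0 - tc.times))) < 1e-6
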