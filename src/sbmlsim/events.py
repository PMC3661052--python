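"""SBML event semantics and delay-expression support.

Events fire on the rising edge of their boolean trigger (false -> true
between two checks).  Simultaneously fired events run through a priority
cascade: (i) fired events enter a queue; (ii) all priorities are
evaluated in the current state; (iii) the maximum-priority event
executes its assignments (all right-hand sides evaluated before any
target is written); (iv) queued events with persistent=false whose
trigger has meanwhile gone false are dropped; (v) events whose trigger
was flipped false -> true by the assignment join the queue; (vi) repeat
while the queue is non-empty.

Events carrying a Delay element are not executed in-cascade: the delay
expression is evaluated at trigger time and the assignment scheduled; if
useValuesFromTriggerTime the right-hand sides are evaluated immediately
and frozen.

The :class:`HistoryBuffer` records the full state vector at every
accepted step and serves both delay-csymbol lookups (linear
interpolation between bracketing samples) and delayed-event bookkeeping.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np

from . import mathml
from .errors import EventError, ModelSemanticError

_CASCADE_CAP = 10_000


# ---------------------------------------------------------------------------
# History buffer
# ---------------------------------------------------------------------------

@dataclass
class HistoryBuffer:
    """Time-ordered record of (t, full state vector) at accepted steps."""

    times: list = field(default_factory=list)
    states: list = field(default_factory=list)

    def append(self, t, state):
        if self.times and t <= self.times[-1]:
            # replace the sample if an event rewrote the state at the same t
            if t == self.times[-1]:
                self.states[-1] = np.array(state, copy=True)
                return
            raise ValueError("history times must be strictly increasing")
        self.times.append(float(t))
        self.states.append(np.array(state, copy=True))

    def interpolate(self, t):
        """Full state at time ``t``: clamped to the first sample for
        t below the record, to the last sample beyond it, linear in
        between."""
        if not self.times:
            raise ValueError("empty history buffer")
        if t <= self.times[0]:
            return self.states[0]
        if t >= self.times[-1]:
            return self.states[-1]
        i = bisect.bisect_right(self.times, t)
        t0, t1 = self.times[i - 1], self.times[i]
        w = (t - t0) / (t1 - t0)
        return (1.0 - w) * self.states[i - 1] + w * self.states[i]


def history_lookup(buffer: HistoryBuffer, model, variable, t_query):
    """Value of one variable (expression-level units) at ``t_query``;
    times before the record return the initial value, times beyond the
    last sample the newest one."""
    if variable not in model.variable_index:
        raise ModelSemanticError(f"unknown variable '{variable}' in delay lookup")
    state = buffer.interpolate(t_query)
    return model.value_map(state)[variable]


def make_delay_lookup(buffer: HistoryBuffer, model, eval_time):
    """Build the ``delay(sub_program, lag)`` callable used by the RPN
    evaluator for an expression evaluated at ``eval_time``: the delayed
    sub-expression is evaluated against the recorded (interpolated)
    state at ``eval_time - lag``, with nested delays resolved
    recursively relative to that earlier time."""

    def delay(sub_program, lag):
        tq = eval_time - lag
        state = buffer.interpolate(tq)
        ctx = mathml.EvalContext(time=tq, values=model.value_map(state),
                                 delay=make_delay_lookup(buffer, model, tq))
        return mathml.evaluate(sub_program, ctx)

    return delay


# ---------------------------------------------------------------------------
# Triggers
# ---------------------------------------------------------------------------

@dataclass
class TriggerMemory:
    """Previous boolean trigger value per event id."""

    previous: dict = field(default_factory=dict)

    @staticmethod
    def initialize(programs):
        """Per-level initialization: events whose ``initialValue`` is true
        (all Level 2 events) start with memory 'true' so a trigger that is
        already satisfied at t=0 does not fire; Level 3 events with
        initialValue=false start 'false' and may fire immediately."""
        mem = TriggerMemory()
        for ev in programs.events:
            mem.previous[ev.id] = bool(ev.initial_trigger_value)
        return mem


class EventPrograms:
    """Compiled triggers/priorities/delays/assignments for all events."""

    def __init__(self, model):
        self.model = model
        self.events = list(model.events)
        self.trigger = {}
        self.priority = {}
        self.delay = {}
        self.assignments = {}
        for ev in self.events:
            self.trigger[ev.id] = mathml.compile_to_rpn(ev.trigger)
            if ev.priority is not None:
                self.priority[ev.id] = mathml.compile_to_rpn(ev.priority)
            if ev.delay is not None:
                self.delay[ev.id] = mathml.compile_to_rpn(ev.delay)
            self.assignments[ev.id] = [
                (tgt, mathml.compile_to_rpn(ast)) for tgt, ast in ev.assignments]

    def __iter__(self):
        return iter((ev, self.trigger[ev.id]) for ev in self.events)

    def by_id(self, eid):
        for ev in self.events:
            if ev.id == eid:
                return ev
        raise KeyError(eid)

    def trigger_true(self, ev, values, t, delay=None) -> bool:
        ctx = mathml.EvalContext(time=t, values=values, delay=delay)
        return mathml.evaluate(self.trigger[ev.id], ctx) != 0.0

    def priority_value(self, ev, values, t, delay=None):
        prog = self.priority.get(ev.id)
        if prog is None:
            return None
        ctx = mathml.EvalContext(time=t, values=values, delay=delay)
        return mathml.evaluate(prog, ctx)


def detect_triggers(programs: EventPrograms, values, t, memory: TriggerMemory,
                    delay=None):
    """Rising-edge detection: returns the list of events whose trigger is
    true now and was false at the previous check; updates the memory for
    every event."""
    fired = []
    for ev in programs.events:
        now = programs.trigger_true(ev, values, t, delay)
        if now and not memory.previous.get(ev.id, False):
            fired.append(ev)
        memory.previous[ev.id] = now
    return fired


# ---------------------------------------------------------------------------
# Delayed assignments
# ---------------------------------------------------------------------------

@dataclass
class PendingAssignment:
    """A delayed event execution scheduled for ``fire_time``."""

    event_id: str
    fire_time: float
    trigger_time: float
    priority: float | None
    captured: dict | None  # target -> frozen value, iff useValuesFromTriggerTime

    def __post_init__(self):
        if self.fire_time < self.trigger_time:
            raise EventError(
                f"event '{self.event_id}': negative delay "
                f"({self.fire_time - self.trigger_time:g})")


def schedule_delayed(programs: EventPrograms, ev, t_trigger, values,
                     delay=None) -> PendingAssignment:
    """Evaluate the Delay expression at trigger time and build the
    pending record; with useValuesFromTriggerTime the assignment
    right-hand sides are evaluated now and frozen."""
    ctx = mathml.EvalContext(time=t_trigger, values=values, delay=delay)
    lag = mathml.evaluate(programs.delay[ev.id], ctx)
    if lag < 0:
        raise EventError(f"event '{ev.id}': evaluated delay is negative ({lag:g})")
    captured = None
    if ev.use_values_from_trigger_time:
        captured = {tgt: mathml.evaluate(prog, ctx)
                    for tgt, prog in programs.assignments[ev.id]}
    return PendingAssignment(
        event_id=ev.id,
        fire_time=t_trigger + lag,
        trigger_time=t_trigger,
        priority=programs.priority_value(ev, values, t_trigger, delay),
        captured=captured,
    )


def fire_due_assignments(programs: EventPrograms, pending: list, system,
                         state, t, rng, delay=None, log_list=None):
    """Apply every pending assignment whose fire time has been reached,
    in fire-time order (ties broken by descending priority, then by the
    seeded rng); mutates ``state`` and prunes ``pending`` in place.
    Returns True when anything fired."""
    due = [p for p in pending if p.fire_time <= t]
    if not due:
        return False
    rng_key = {id(p): rng.random() for p in due}
    due.sort(key=lambda p: (
        p.fire_time,
        -(p.priority if p.priority is not None else -float("inf")),
        rng_key[id(p)]))
    for p in due:
        ev = programs.by_id(p.event_id)
        if p.captured is not None:
            writes = dict(p.captured)
        else:
            system.apply_assignment_closure(state, t, delay)
            values = system.context_values(state, t, delay)
            ctx = mathml.EvalContext(time=t, values=values, delay=delay)
            writes = {tgt: mathml.evaluate(prog, ctx)
                      for tgt, prog in programs.assignments[ev.id]}
        for tgt, value in writes.items():
            programs.model.write_value(state, tgt, value)
        if log_list is not None:
            log_list.append(ev.id)
        pending.remove(p)
    return True


def cancel_lapsed(programs: EventPrograms, pending: list, values, t,
                  delay=None):
    """Drop pending delayed executions of persistent=false events whose
    trigger has gone false again before the fire time."""
    keep = []
    for p in pending:
        ev = programs.by_id(p.event_id)
        if not ev.persistent and not programs.trigger_true(ev, values, t, delay):
            continue
        keep.append(p)
    pending[:] = keep


# ---------------------------------------------------------------------------
# Cascade
# ---------------------------------------------------------------------------

def run_event_cascade(programs: EventPrograms, fired, system, state, t, rng,
                      memory: TriggerMemory, pending: list, delay=None,
                      log_list=None):
    """Execute simultaneously fired events by descending priority,
    re-checking non-persistent triggers and picking up newly triggered
    events after every execution; delayed events are scheduled instead of
    executed.  Mutates ``state``, ``memory`` and ``pending``; returns
    True when any assignment was applied or scheduled."""
    queue = list(fired)
    changed = False
    executions = 0
    while queue:
        executions += 1
        if executions > _CASCADE_CAP:
            raise EventError(
                f"event cascade exceeded {_CASCADE_CAP} executions at t={t:g} "
                f"(livelock)")
        system.apply_assignment_closure(state, t, delay)
        values = system.context_values(state, t, delay)

        # (ii) evaluate all priorities in the current state; (iii) pick max.
        # Absent priorities rank below every numeric priority; ties and
        # absent-vs-absent order are broken by the seeded rng.
        ranked = []
        for ev in queue:
            pr = programs.priority_value(ev, values, t, delay)
            key = (0, pr) if pr is not None else (1, 0.0)
            ranked.append((key[0], -(key[1]), rng.random(), ev))
        ranked.sort(key=lambda r: (r[0], r[1], r[2]))
        ev = ranked[0][3]
        queue.remove(ev)

        if ev.delay is not None:
            pending.append(schedule_delayed(programs, ev, t, values, delay))
            changed = True
        else:
            # simultaneous-assignment semantics: all right-hand sides are
            # evaluated in the pre-assignment state
            writes = {tgt: mathml.evaluate(
                prog, mathml.EvalContext(time=t, values=values, delay=delay))
                for tgt, prog in programs.assignments[ev.id]}
            for tgt, value in writes.items():
                programs.model.write_value(state, tgt, value)
            if log_list is not None:
                log_list.append(ev.id)
            changed = True

        # state changed: recompute rules, then re-check triggers
        system.apply_assignment_closure(state, t, delay)
        values = system.context_values(state, t, delay)

        # (iv) drop non-persistent queued events whose trigger lapsed
        queue = [e for e in queue
                 if e.persistent or programs.trigger_true(e, values, t, delay)]
        cancel_lapsed(programs, pending, values, t, delay)

        # (v) enqueue events whose trigger flipped false -> true
        for other in programs.events:
            now = programs.trigger_true(other, values, t, delay)
            was = memory.previous.get(other.id, False)
            if now and not was and other not in queue:
                queue.append(other)
            memory.previous[other.id] = now
    return changed
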