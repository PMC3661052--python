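"""Simulation main loop and time-course output.

``simulate`` binds everything: the ODE/DAE system from
:mod:`sbmlsim.equations`, a stepper from :mod:`sbmlsim.integrators`, the
event machinery from :mod:`sbmlsim.events` and the history buffer that
serves delay expressions.  Internal steps are clamped so the trajectory
lands exactly on every output time and every pending delayed-event fire
time; output times are computed as ``i * duration / steps`` (never by
repeated addition) so the grid carries no floating drift.

Fixed-step methods integrate at ``h = duration / (steps * refinement)``
(refinement defaults to 10); the adaptive pairs free-run under their own
error control, clamped to the same stopping points.  Triggers are
checked at accepted-step boundaries, so the internal step density bounds
the event-time resolution.
"""

from __future__ import annotations

import logging
import math
import random
from dataclasses import dataclass, field

import numpy as np

from . import events as ev_mod
from . import integrators as integ
from .equations import build_ode_system, equilibrate_fast, partition_fast_reactions
from .errors import NumericBlowupError, StepError
from .integrators import History, MethodSpec
from .loader import CompiledModel, SpeciesDef, resolve_initial_state
from .numerics import NewtonSettings

log = logging.getLogger(__name__)

_TIME_EPS_FACTOR = 1e-12


@dataclass
class SimulationConfig:
    """Everything the main loop needs besides the model itself."""

    duration: float = 10.0
    output_steps: int = 100
    method: MethodSpec = field(default_factory=MethodSpec)
    newton: NewtonSettings = field(default_factory=NewtonSettings)
    refinement: int = 10          # internal steps per output interval (fixed-step)
    print_targets: list | None = None  # [(id, "amount"|"concentration"|None)]
    seed: int = 0

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.output_steps < 1:
            raise ValueError("output steps must be >= 1")
        if self.refinement < 1:
            raise ValueError("refinement must be >= 1")


@dataclass
class TimeCourse:
    """Output table: uniform times plus one column per print target."""

    times: np.ndarray
    columns: dict            # id -> np.ndarray
    column_order: list

    def __getitem__(self, key):
        return self.columns[key]


def _default_targets(model: CompiledModel):
    targets = [(s.id, None) for s in model.species]
    targets += [(c.id, None) for c in model.compartments if not c.constant]
    targets += [(p.id, None) for p in model.parameters if not p.constant]
    return targets


def _output_value(model, state, ident, mode):
    d = model.entity(ident)
    if isinstance(d, SpeciesDef):
        amount = state[model.variable_index[ident]]
        as_conc = (mode == "concentration"
                   or (mode is None and model.reads_as_concentration(d)))
        if as_conc:
            size = state[model.variable_index[d.compartment]]
            return amount / size if size != 0.0 else math.nan
        return amount
    return state[model.variable_index[ident]]


def simulate(model: CompiledModel, config: SimulationConfig) -> TimeCourse:
    """Integrate the model over [0, duration] and sample it at
    ``output_steps + 1`` uniform times."""
    system = build_ode_system(model)
    partition = partition_fast_reactions(model)
    programs = ev_mod.EventPrograms(model)
    buffer = ev_mod.HistoryBuffer()
    rng = random.Random(config.seed)
    method = config.method
    newton = config.newton
    duration = config.duration
    eps = duration * _TIME_EPS_FACTOR

    def delay_at(t):
        return ev_mod.make_delay_lookup(buffer, model, t)

    def f(t, y):
        return system.derivative(t, y, delay=delay_at(t))

    # ---- initial condition -------------------------------------------
    state = resolve_initial_state(model)
    t = 0.0
    system.apply_assignment_closure(state, t, delay_at(t))
    if partition:
        equilibrate_fast(partition, system, state, t, newton)
    system.solve_algebraic(state, t, newton, delay_at(t))
    buffer.append(t, state)

    memory = ev_mod.TriggerMemory.initialize(programs)
    pending: list = []
    hist = History(max_len=max(4, method.order))
    exec_log: list = []

    def handle_events(t):
        """Trigger detection, cascades and due delayed assignments at an
        accepted-step boundary; returns True on any discontinuity."""
        changed = False
        for _ in range(ev_mod._CASCADE_CAP):
            values = system.context_values(state, t, delay_at(t))
            fired = ev_mod.detect_triggers(programs, values, t, memory,
                                           delay_at(t))
            ev_mod.cancel_lapsed(programs, pending, values, t, delay_at(t))
            any_now = False
            if fired:
                any_now |= ev_mod.run_event_cascade(
                    programs, fired, system, state, t, rng, memory, pending,
                    delay_at(t), exec_log)
            any_now |= ev_mod.fire_due_assignments(
                programs, pending, system, state, t, rng, delay_at(t), exec_log)
            if not any_now:
                break
            system.apply_assignment_closure(state, t, delay_at(t))
            changed = True
        if changed:
            if partition:
                equilibrate_fast(partition, system, state, t, newton)
            system.solve_algebraic(state, t, newton, delay_at(t))
            buffer.append(t, state)  # overwrite the sample at this t
        return changed

    # events whose trigger is satisfied from the start (L3 initialValue=false)
    if handle_events(t):
        hist.clear()

    out_times = [i * duration / config.output_steps
                 for i in range(config.output_steps + 1)]
    targets = (config.print_targets if config.print_targets is not None
               else _default_targets(model))
    rows = [[_output_value(model, state, ident, mode)
             for ident, mode in targets]]
    next_out = 1

    h_fixed = duration / (config.output_steps * config.refinement)
    h_adapt = h_fixed  # starting guess for the adaptive controller

    while t < duration - eps:
        fire_times = [p.fire_time for p in pending if p.fire_time > t + eps]
        t_stop = min([out_times[next_out]] + fire_times)
        h_max = t_stop - t

        if method.is_adaptive:
            state_new, t_new, h_adapt = _adaptive_advance(
                f, t, state, min(h_adapt, h_max), h_max, method, duration)
        elif method.is_multistep:
            state_new, t_new = _multistep_advance(
                f, t, state, min(h_fixed, h_max), method, newton, hist)
        else:
            h = min(h_fixed, h_max)
            if method.family == "euler":
                res = integ.step_explicit_euler(f, t, state, h)
            elif method.family == "rk4":
                res = integ.step_rk4(f, t, state, h)
            else:  # backward_euler
                res = _implicit_with_retry(f, t, state, h, newton)
            state_new, t_new = res.y, t + h

        # land exactly on the stopping point when we clamped to it
        if abs(t_new - t_stop) <= eps:
            t_new = t_stop
        state = np.asarray(state_new, dtype=float)
        t = t_new

        system.apply_assignment_closure(state, t, delay_at(t))
        if partition:
            equilibrate_fast(partition, system, state, t, newton)
        system.solve_algebraic(state, t, newton, delay_at(t))
        _check_state(model, state, t)
        buffer.append(t, state)
        if method.is_multistep:
            hist.push(t, state, f(t, state))

        if handle_events(t):
            hist.clear()  # discontinuity: restart multistep from RK4
        system.check_constraints(state, t)

        while next_out <= config.output_steps and out_times[next_out] <= t + eps:
            rows.append([_output_value(model, state, ident, mode)
                         for ident, mode in targets])
            next_out += 1

    times = np.array(out_times[:len(rows)])
    cols = {ident: np.array([row[i] for row in rows])
            for i, (ident, _) in enumerate(targets)}
    return TimeCourse(times=times, columns=cols,
                      column_order=[ident for ident, _ in targets])


def _check_state(model, state, t):
    if np.all(np.isfinite(state)):
        return
    bad = int(np.flatnonzero(~np.isfinite(state))[0])
    for ident, i in model.variable_index.items():
        if i == bad:
            raise NumericBlowupError(ident, t)
    raise NumericBlowupError(f"state[{bad}]", t)


def _implicit_with_retry(f, t, state, h, newton, max_halvings=10):
    """Backward Euler with step halving on Newton failure: the full
    interval [t, t+h] is covered by progressively smaller sub-steps."""
    from .errors import ConvergenceError
    try:
        return integ.step_backward_euler(f, t, state, h, newton)
    except ConvergenceError:
        pass
    sub = h
    for _ in range(max_halvings):
        sub /= 2.0
        try:
            y = np.asarray(state, dtype=float)
            tt = t
            n = int(round(h / sub))
            for _ in range(n):
                y = integ.step_backward_euler(f, tt, y, sub, newton).y
                tt += sub
            return integ.StepResult(y=y)
        except ConvergenceError:
            continue
    raise StepError(
        f"backward Euler: Newton failed down to h={sub:g} at t={t:g}")


def _multistep_advance(f, t, state, h, method, newton, hist):
    """One multistep step; falls back to RK4 while the history is short
    (startup or after a discontinuity)."""
    # invalidate history if spacing changed (clamped step near a stop point)
    if len(hist) >= 1:
        t0 = hist.points[0][0]
        if abs(t0 - t) > 1e-12 * max(1.0, abs(t)):
            hist.clear()
    if len(hist) >= 2:
        spacing = hist.points[0][0] - hist.points[1][0]
        if abs(spacing - h) > 1e-9 * max(h, spacing):
            hist.clear()
    needed = method.history_needed
    if len(hist) < needed:
        if len(hist) == 0:
            hist.push(t, state, f(t, state))
        if needed > len(hist):
            # startup: one-step method of matching stability class
            if method.is_implicit:
                res = _implicit_with_retry(f, t, state, h, newton)
            else:
                res = integ.step_rk4(f, t, state, h)
            return res.y, t + h
    res = integ.step_multistep(f, hist, h, method.family, method.order, newton)
    return res.y, t + h


def _adaptive_advance(f, t, state, h, h_max, method, duration):
    """Attempt adaptive steps until one is accepted; returns
    (new state, new t, suggested next h)."""
    h_min = duration * 1e-12
    h = min(h, h_max)
    while True:
        if h < h_min:
            raise StepError(
                f"adaptive step underflow (h={h:g}) at t={t:g}: the system "
                f"appears stiff; try an implicit method (backward-euler, gear)")
        res = integ.step_adaptive(f, t, state, h, method.family,
                                  method.atol, method.rtol)
        if res.accepted:
            return res.y, t + h, min(res.h_next, duration)
        h = min(res.h_next, h_max)


# ---------------------------------------------------------------------------
# CSV output (SBML-test-suite dialect)
# ---------------------------------------------------------------------------

def write_csv(tc: TimeCourse, path):
    """Write ``time,<id1>,<id2>,...`` with one row per output time, full
    double precision (repr-shortest round-trip), LF line endings."""
    with open(path, "w", newline="\n") as fh:
        fh.write(",".join(["time"] + tc.column_order) + "\n")
        for i, t in enumerate(tc.times):
            row = [repr(float(t))]
            row += [repr(float(tc.columns[c][i])) for c in tc.column_order]
            fh.write(",".join(row) + "\n")


def read_csv(path):
    """Parse a time-course CSV written by :func:`write_csv` (or by the
    SBML test suite); returns a :class:`TimeCourse`."""
    with open(path) as fh:
        header = fh.readline().strip().split(",")
        data = [[float(x) for x in line.strip().split(",")]
                for line in fh if line.strip()]
    arr = np.array(data)
    names = [h.strip() for h in header]
    cols = {name: arr[:, i] for i, name in enumerate(names) if i > 0}
    return TimeCourse(times=arr[:, 0], columns=cols, column_order=names[1:])
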