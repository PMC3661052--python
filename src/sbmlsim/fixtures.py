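"""Programmatic SBML fixtures and an SBML-test-suite case harness.

``make_fixture`` emits small, valid SBML documents — one per supported
feature — used throughout the test suite and handy as CLI demo inputs.
Documents are deterministic given the spec and are generated for Level 2
Version 4 or Level 3 Version 1 (features that exist only in L3, such as
event priorities, are L3-only).

``run_suite_case`` runs one case of the SBML test suite (if a local copy
is available) against this simulator using the case's own settings file
and expected-results table.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np

from .errors import SbmlSimError, UnsupportedFeatureError
from .integrators import MethodSpec
from .loader import load_model
from .numerics import NewtonSettings
from .runner import SimulationConfig, read_csv, simulate

FEATURE_TAGS = (
    "decay", "chain", "stiff", "function_def", "piecewise",
    "assignment_rule", "rate_rule", "algebraic_rule",
    "event_basic", "event_priority", "event_persistent", "event_delay",
    "delay_expression", "fast_reaction", "boundary_species",
)

_L3_ONLY = {"event_priority", "event_persistent"}


@dataclass
class FixtureSpec:
    tag: str
    level: tuple = (2, 4)
    params: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Tiny MathML writer: prefix tuples -> XML
#   ("ci", "k"), ("cn", 2.5), ("time",), ("delay", expr, lag),
#   ("plus", a, b, ...), ("times", ...), ("gt", a, b), ("and", a, b), ...
# ---------------------------------------------------------------------------

_CSYMBOL = {
    "time": "http://www.sbml.org/sbml/symbols/time",
    "delay": "http://www.sbml.org/sbml/symbols/delay",
    "avogadro": "http://www.sbml.org/sbml/symbols/avogadro",
}


def _mml(expr) -> str:
    op = expr[0]
    if op == "ci":
        return f"<ci> {expr[1]} </ci>"
    if op == "cn":
        v = expr[1]
        if isinstance(v, int) or (isinstance(v, float) and v == int(v)):
            return f'<cn type="integer"> {int(v)} </cn>'
        return f"<cn> {v!r} </cn>"
    if op == "time":
        return ('<csymbol encoding="text" definitionURL='
                f'"{_CSYMBOL["time"]}"> t </csymbol>')
    if op == "delay":
        inner = "".join(_mml(a) for a in expr[1:])
        return ("<apply><csymbol encoding=\"text\" definitionURL="
                f"\"{_CSYMBOL['delay']}\"> delay </csymbol>{inner}</apply>")
    if op == "piecewise":
        # ("piecewise", (value, cond), ..., otherwise_or_None)
        *pieces, otherwise = expr[1:]
        parts = "".join(
            f"<piece>{_mml(v)}{_mml(c)}</piece>" for v, c in pieces)
        if otherwise is not None:
            parts += f"<otherwise>{_mml(otherwise)}</otherwise>"
        return f"<piecewise>{parts}</piecewise>"
    if op == "call":
        inner = "".join(_mml(a) for a in expr[2:])
        return f"<apply><ci> {expr[1]} </ci>{inner}</apply>"
    inner = "".join(_mml(a) for a in expr[1:])
    return f"<apply><{op}/>{inner}</apply>"


def _math(expr) -> str:
    return ('<math xmlns="http://www.w3.org/1998/Math/MathML">'
            + _mml(expr) + "</math>")


# ---------------------------------------------------------------------------
# Document assembly
# ---------------------------------------------------------------------------

_NS = {
    (2, 4): "http://www.sbml.org/sbml/level2/version4",
    (3, 1): "http://www.sbml.org/sbml/level3/version1/core",
}


class _Doc:
    def __init__(self, level):
        self.level = level
        self.compartments = []
        self.species = []
        self.parameters = []
        self.reactions = []
        self.rules = []
        self.events = []
        self.function_defs = []
        self.initial_assignments = []

    def compartment(self, cid, size=1.0, constant=True):
        attrs = f'id="{cid}" size="{size!r}"'
        if self.level[0] >= 3:
            attrs += f' constant="{_b(constant)}" spatialDimensions="3"'
        elif not constant:
            attrs += ' constant="false"'
        self.compartments.append(f"<compartment {attrs}/>")

    def specie(self, sid, comp, amount=None, conc=None, boundary=False,
               constant=False, substance_only=False):
        attrs = f'id="{sid}" compartment="{comp}"'
        if amount is not None:
            attrs += f' initialAmount="{amount!r}"'
        if conc is not None:
            attrs += f' initialConcentration="{conc!r}"'
        if boundary:
            attrs += ' boundaryCondition="true"'
        if constant:
            attrs += ' constant="true"'
        elif self.level[0] >= 3:
            attrs += ' constant="false"'
        if substance_only:
            attrs += ' hasOnlySubstanceUnits="true"'
        elif self.level[0] >= 3:
            attrs += ' hasOnlySubstanceUnits="false"'
        if self.level[0] >= 3 and not boundary:
            attrs += ' boundaryCondition="false"'
        self.species.append(f"<species {attrs}/>")

    def parameter(self, pid, value, constant=True):
        attrs = f'id="{pid}" value="{value!r}"'
        if not constant:
            attrs += ' constant="false"'
        elif self.level[0] >= 3:
            attrs += ' constant="true"'
        self.parameters.append(f"<parameter {attrs}/>")

    def reaction(self, rid, reactants, products, kinetic, fast=False,
                 local_params=(), reversible=False):
        def refs(pairs):
            out = []
            for sid, st in pairs:
                a = f'species="{sid}"'
                if st != 1:
                    a += f' stoichiometry="{st!r}"'
                elif self.level[0] >= 3:
                    a += ' stoichiometry="1"'
                if self.level[0] >= 3:
                    a += ' constant="true"'
                out.append(f"<speciesReference {a}/>")
            return "".join(out)

        attrs = f'id="{rid}" reversible="{_b(reversible)}"'
        if fast:
            attrs += ' fast="true"'
        elif self.level[0] >= 3:
            attrs += ' fast="false"'
        body = ""
        if reactants:
            body += f"<listOfReactants>{refs(reactants)}</listOfReactants>"
        if products:
            body += f"<listOfProducts>{refs(products)}</listOfProducts>"
        lp = ""
        if local_params:
            tag = ("listOfLocalParameters" if self.level[0] >= 3
                   else "listOfParameters")
            ptag = "localParameter" if self.level[0] >= 3 else "parameter"
            lp = "".join(f'<{ptag} id="{p}" value="{v!r}"/>'
                         for p, v in local_params)
            lp = f"<{tag}>{lp}</{tag}>"
        body += f"<kineticLaw>{_math(kinetic)}{lp}</kineticLaw>"
        self.reactions.append(f"<reaction {attrs}>{body}</reaction>")

    def assignment_rule(self, target, expr):
        self.rules.append(
            f'<assignmentRule variable="{target}">{_math(expr)}</assignmentRule>')

    def rate_rule(self, target, expr):
        self.rules.append(
            f'<rateRule variable="{target}">{_math(expr)}</rateRule>')

    def algebraic_rule(self, expr):
        self.rules.append(f"<algebraicRule>{_math(expr)}</algebraicRule>")

    def initial_assignment(self, target, expr):
        self.initial_assignments.append(
            f'<initialAssignment symbol="{target}">{_math(expr)}'
            f"</initialAssignment>")

    def function_def(self, fid, args, body):
        bvars = "".join(f"<bvar><ci> {a} </ci></bvar>" for a in args)
        self.function_defs.append(
            f'<functionDefinition id="{fid}">'
            f'<math xmlns="http://www.w3.org/1998/Math/MathML">'
            f"<lambda>{bvars}{_mml(body)}</lambda></math></functionDefinition>")

    def event(self, eid, trigger, assignments, priority=None, delay=None,
              persistent=True, initial_value=True, uvftt=True):
        l3 = self.level[0] >= 3
        tattrs = ""
        if l3:
            tattrs = (f' persistent="{_b(persistent)}"'
                      f' initialValue="{_b(initial_value)}"')
        body = f"<trigger{tattrs}>{_math(trigger)}</trigger>"
        if delay is not None:
            body += f"<delay>{_math(delay)}</delay>"
        if priority is not None:
            if not l3:
                raise UnsupportedFeatureError("priority requires SBML Level 3")
            body += f"<priority>{_math(priority)}</priority>"
        eas = "".join(
            f'<eventAssignment variable="{t}">{_math(e)}</eventAssignment>'
            for t, e in assignments)
        body += f"<listOfEventAssignments>{eas}</listOfEventAssignments>"
        attrs = f'id="{eid}"'
        if l3:
            attrs += f' useValuesFromTriggerTime="{_b(uvftt)}"'
        elif not uvftt:
            attrs += ' useValuesFromTriggerTime="false"'
        self.events.append(f"<event {attrs}>{body}</event>")

    def render(self) -> str:
        level, version = self.level
        parts = []

        def block(name, items):
            if items:
                parts.append(f"<{name}>" + "".join(items) + f"</{name}>")

        block("listOfFunctionDefinitions", self.function_defs)
        block("listOfCompartments", self.compartments)
        block("listOfSpecies", self.species)
        block("listOfParameters", self.parameters)
        block("listOfInitialAssignments", self.initial_assignments)
        block("listOfRules", self.rules)
        block("listOfReactions", self.reactions)
        block("listOfEvents", self.events)
        return (
            '<?xml version="1.0" encoding="UTF-8"?>\n'
            f'<sbml xmlns="{_NS[self.level]}" level="{level}" '
            f'version="{version}">\n'
            f'<model id="fixture">' + "".join(parts) + "</model>\n</sbml>\n"
        )


def _b(v):
    return "true" if v else "false"


# ---------------------------------------------------------------------------
# Feature fixtures
# ---------------------------------------------------------------------------

def make_fixture(spec: FixtureSpec | str, level=None, **params) -> str:
    """SBML XML text for one feature tag.

    Accepts either a :class:`FixtureSpec` or the tag with keyword
    parameters, e.g. ``make_fixture("decay", k=0.5, s0=10)``.
    """
    if isinstance(spec, str):
        spec = FixtureSpec(tag=spec, level=level or (2, 4), params=params)
    tag = spec.tag
    if tag not in FEATURE_TAGS:
        raise SbmlSimError(f"unknown fixture tag '{tag}'")
    lvl = spec.level
    if tag in _L3_ONLY:
        lvl = (3, 1)
    p = spec.params
    builder = _BUILDERS[tag]
    return builder(_Doc(lvl), p)


def _fx_decay(d, p):
    k, s0 = p.get("k", 0.5), p.get("s0", 10.0)
    d.compartment("c")
    d.specie("S1", "c", amount=s0, substance_only=True)
    d.reaction("J1", [("S1", 1)], [],
               ("times", ("ci", "k"), ("ci", "S1")),
               local_params=[("k", k)])
    return d.render()


def _fx_chain(d, p):
    k1, k2, s0 = p.get("k1", 0.3), p.get("k2", 0.2), p.get("s0", 10.0)
    d.compartment("c")
    d.specie("S1", "c", amount=s0, substance_only=True)
    d.specie("S2", "c", amount=0.0, substance_only=True)
    d.specie("S3", "c", amount=0.0, substance_only=True)
    d.reaction("J1", [("S1", 1)], [("S2", 1)],
               ("times", ("ci", "k1"), ("ci", "S1")),
               local_params=[("k1", k1)])
    d.reaction("J2", [("S2", 1)], [("S3", 1)],
               ("times", ("ci", "k2"), ("ci", "S2")),
               local_params=[("k2", k2)])
    return d.render()


def _fx_stiff(d, p):
    k, s0 = p.get("k", 1000.0), p.get("s0", 1.0)
    d.compartment("c")
    d.specie("S1", "c", amount=s0, substance_only=True)
    d.reaction("J1", [("S1", 1)], [],
               ("times", ("ci", "k"), ("ci", "S1")),
               local_params=[("k", k)])
    return d.render()


def _fx_function_def(d, p):
    k, s0 = p.get("k", 0.5), p.get("s0", 10.0)
    d.function_def("f", ["x"], ("times", ("cn", 2), ("ci", "x")))
    d.compartment("c")
    d.specie("S1", "c", amount=s0, substance_only=True)
    d.parameter("k", k)
    d.reaction("J1", [("S1", 1)], [],
               ("times", ("ci", "k"), ("call", "f", ("ci", "S1"))))
    return d.render()


def _fx_piecewise(d, p):
    # production switches off after t_switch: dS1/dt = piecewise(v, t<ts, 0)
    v, ts = p.get("v", 1.0), p.get("t_switch", 2.0)
    d.compartment("c")
    d.specie("S1", "c", amount=0.0, substance_only=True)
    d.reaction("J1", [], [("S1", 1)],
               ("piecewise",
                (("ci", "v"), ("lt", ("time",), ("ci", "ts"))),
                ("cn", 0)),
               local_params=[("v", v), ("ts", ts)])
    return d.render()


def _fx_assignment_rule(d, p):
    d.compartment("c")
    d.specie("S1", "c", amount=p.get("s0", 10.0), substance_only=True)
    d.parameter("a", 0.0, constant=False)
    d.parameter("b", 0.0, constant=False)
    d.reaction("J1", [("S1", 1)], [],
               ("times", ("cn", p.get("k", 0.5)), ("ci", "S1")))
    d.assignment_rule("a", ("plus", ("ci", "b"), ("cn", 1)))
    d.assignment_rule("b", ("ci", "S1"))
    return d.render()


def _fx_rate_rule(d, p):
    d.compartment("c")
    d.parameter("q", p.get("q0", 0.0), constant=False)
    d.parameter("k", p.get("k", 2.0))
    d.rate_rule("q", ("ci", "k"))
    return d.render()


def _fx_algebraic_rule(d, p):
    # S1 decays; 0 = S1 + S2 - T determines S2
    d.compartment("c")
    d.specie("S1", "c", amount=p.get("s0", 1.0), substance_only=True)
    d.specie("S2", "c", amount=p.get("s2_0", 2.0), substance_only=True)
    d.parameter("T", p.get("total", 3.0))
    d.reaction("J1", [("S1", 1)], [],
               ("times", ("cn", p.get("k", 0.5)), ("ci", "S1")))
    d.algebraic_rule(("minus",
                      ("plus", ("ci", "S1"), ("ci", "S2")),
                      ("ci", "T")))
    return d.render()


def _fx_event_basic(d, p):
    k, s0 = p.get("k", 0.5), p.get("s0", 10.0)
    low, reset = p.get("low", 5.0), p.get("reset", 10.0)
    d.compartment("c")
    d.specie("S1", "c", amount=s0, substance_only=True)
    d.reaction("J1", [("S1", 1)], [],
               ("times", ("cn", k), ("ci", "S1")))
    d.event("E1",
            ("lt", ("ci", "S1"), ("cn", low)),
            [("S1", ("cn", reset))])
    return d.render()


def _fx_event_priority(d, p):
    # the two-event priority/persistence cascade: at t=1 both events fire;
    # E1 (priority 2) zeroes S1, which de-triggers non-persistent E2
    # before it can set S2
    d.compartment("c")
    d.parameter("S1", p.get("s1", 1.0), constant=False)
    d.parameter("S2", p.get("s2", 0.0), constant=False)
    both = ("and",
            ("geq", ("time",), ("cn", 1)),
            ("gt", ("ci", "S1"), ("cn", 0.5)))
    d.event("E1", ("geq", ("time",), ("cn", 1)),
            [("S1", ("cn", 0))], priority=("cn", 2))
    d.event("E2", both, [("S2", ("cn", 9))],
            priority=("cn", 1), persistent=False)
    return d.render()


def _fx_event_persistent(d, p):
    # persistent variant of the same race: E2 keeps its right to fire
    # even though E1's assignment made its trigger false
    d.compartment("c")
    d.parameter("S1", p.get("s1", 1.0), constant=False)
    d.parameter("S2", p.get("s2", 0.0), constant=False)
    both = ("and",
            ("geq", ("time",), ("cn", 1)),
            ("gt", ("ci", "S1"), ("cn", 0.5)))
    d.event("E1", ("geq", ("time",), ("cn", 1)),
            [("S1", ("cn", 0))], priority=("cn", 2))
    d.event("E2", both, [("S2", ("cn", 9))],
            priority=("cn", 1), persistent=True)
    return d.render()


def _fx_event_delay(d, p):
    # triggered at t=1 with delay 2; p_tracked = 4 + t, so the assigned
    # value is 5 with trigger-time capture and 7 without
    uvftt = p.get("uvftt", True)
    d.compartment("c")
    d.parameter("S1", p.get("s0", 0.0), constant=False)
    d.parameter("p_tracked", 0.0, constant=False)
    d.assignment_rule("p_tracked", ("plus", ("cn", 4), ("time",)))
    d.event("E1", ("geq", ("time",), ("cn", 1)),
            [("S1", ("ci", "p_tracked"))],
            delay=("cn", 2), uvftt=uvftt)
    return d.render()


def _fx_delay_expression(d, p):
    # DDE y'(t) = -y(t - lag), y(0)=1, pre-history = initial value
    lag = p.get("lag", 1.0)
    d.compartment("c")
    d.parameter("y", p.get("y0", 1.0), constant=False)
    d.rate_rule("y", ("minus", ("delay", ("ci", "y"), ("cn", lag))))
    return d.render()


def _fx_fast_reaction(d, p):
    # fast A <=> B with net rate 2A - B: equilibrium 2A = B under A+B const
    a0, b0 = p.get("a0", 3.0), p.get("b0", 0.0)
    d.compartment("c")
    d.specie("A", "c", amount=a0, substance_only=True)
    d.specie("B", "c", amount=b0, substance_only=True)
    kinetic = ("minus",
               ("times", ("cn", 2), ("ci", "A")),
               ("ci", "B"))
    d.reaction("Jfast", [("A", 1)], [("B", 1)], kinetic,
               fast=True, reversible=True)
    if p.get("slow_chain", False):
        d.specie("S", "c", amount=0.0, substance_only=True)
        d.reaction("Jin", [], [("A", 1)], ("cn", p.get("kin", 0.4)))
        d.reaction("Jout", [("B", 1)], [("S", 1)],
                   ("times", ("cn", p.get("kout", 0.3)), ("ci", "B")))
    return d.render()


def _fx_boundary_species(d, p):
    d.compartment("c")
    d.specie("Bnd", "c", amount=p.get("b0", 2.0), boundary=True,
             substance_only=True)
    d.specie("S1", "c", amount=0.0, substance_only=True)
    d.reaction("J1", [("Bnd", 1)], [("S1", 1)],
               ("times", ("cn", p.get("k", 0.5)), ("ci", "Bnd")))
    return d.render()


_BUILDERS = {
    "decay": _fx_decay,
    "chain": _fx_chain,
    "stiff": _fx_stiff,
    "function_def": _fx_function_def,
    "piecewise": _fx_piecewise,
    "assignment_rule": _fx_assignment_rule,
    "rate_rule": _fx_rate_rule,
    "algebraic_rule": _fx_algebraic_rule,
    "event_basic": _fx_event_basic,
    "event_priority": _fx_event_priority,
    "event_persistent": _fx_event_persistent,
    "event_delay": _fx_event_delay,
    "delay_expression": _fx_delay_expression,
    "fast_reaction": _fx_fast_reaction,
    "boundary_species": _fx_boundary_species,
}


# ---------------------------------------------------------------------------
# SBML test suite harness (optional local corpus)
# ---------------------------------------------------------------------------

@dataclass
class SuiteCase:
    directory: str
    case_id: str
    model_path: str = ""
    start: float = 0.0
    duration: float = 0.0
    steps: int = 0
    variables: list = field(default_factory=list)
    absolute: float = 1e-6
    relative: float = 1e-4
    amount_vars: set = field(default_factory=set)
    concentration_vars: set = field(default_factory=set)
    expected_path: str = ""


def load_suite_case(directory) -> SuiteCase:
    """Read one test-suite case directory (``NNNNN-sbml-l3v1.xml``,
    ``NNNNN-settings.txt``, ``NNNNN-results.csv``)."""
    case_id = os.path.basename(os.path.normpath(directory))
    case = SuiteCase(directory=directory, case_id=case_id)
    for suffix in ("sbml-l3v1.xml", "sbml-l2v4.xml", "sbml-l2v5.xml"):
        p = os.path.join(directory, f"{case_id}-{suffix}")
        if os.path.exists(p):
            case.model_path = p
            break
    if not case.model_path:
        raise SbmlSimError(f"case {case_id}: no supported model file")
    settings = os.path.join(directory, f"{case_id}-settings.txt")
    if not os.path.exists(settings):
        raise SbmlSimError(f"case {case_id}: missing settings file")
    with open(settings) as fh:
        for line in fh:
            if ":" not in line:
                continue
            key, _, value = line.partition(":")
            key, value = key.strip(), value.strip()
            if key == "start":
                case.start = float(value)
            elif key == "duration":
                case.duration = float(value)
            elif key == "steps":
                case.steps = int(value)
            elif key == "variables":
                case.variables = [v.strip() for v in value.split(",") if v.strip()]
            elif key == "absolute":
                case.absolute = float(value)
            elif key == "relative":
                case.relative = float(value)
            elif key == "amount":
                case.amount_vars = {v.strip() for v in value.split(",") if v.strip()}
            elif key == "concentration":
                case.concentration_vars = {v.strip()
                                           for v in value.split(",") if v.strip()}
    case.expected_path = os.path.join(directory, f"{case_id}-results.csv")
    if not os.path.exists(case.expected_path):
        raise SbmlSimError(f"case {case_id}: missing expected results")
    return case


@dataclass
class SuiteResult:
    case_id: str
    passed: bool
    max_deviation: float
    n_points: int
    skipped: bool = False
    reason: str = ""


def run_suite_case(case: SuiteCase | str, method: MethodSpec | None = None,
                   refinement: int = 50) -> SuiteResult:
    """Simulate one suite case and compare against its expected results:
    pass iff |computed - expected| <= atol + rtol * |expected| at every
    required point.  Unsupported constructs yield a skip, not a failure."""
    if isinstance(case, str):
        case = load_suite_case(case)
    if case.start != 0.0:
        return SuiteResult(case.case_id, False, math.nan, 0, skipped=True,
                           reason="nonzero start time not supported")
    method = method or MethodSpec(family="rk4")
    try:
        model = load_model(case.model_path)
        targets = []
        for v in case.variables:
            mode = None
            if v in case.amount_vars:
                mode = "amount"
            elif v in case.concentration_vars:
                mode = "concentration"
            targets.append((v, mode))
        tc = simulate(model, SimulationConfig(
            duration=case.duration, output_steps=case.steps, method=method,
            newton=NewtonSettings(), refinement=refinement,
            print_targets=targets))
    except UnsupportedFeatureError as exc:
        return SuiteResult(case.case_id, False, math.nan, 0, skipped=True,
                           reason=str(exc))
    expected = read_csv(case.expected_path)
    max_dev = 0.0
    ok = True
    n = 0
    for v in case.variables:
        exp = expected.columns[v]
        got = tc.columns[v]
        m = min(len(exp), len(got))
        dev = np.abs(got[:m] - exp[:m])
        allowed = case.absolute + case.relative * np.abs(exp[:m])
        max_dev = max(max_dev, float(np.max(dev - allowed)))
        ok = ok and bool(np.all(dev <= allowed))
        n += m
    return SuiteResult(case.case_id, ok, max_dev, n)
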