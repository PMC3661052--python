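"""SBML document loading: XML -> :class:`CompiledModel`.

Supports the ODE-relevant core of SBML Level 2 (v1-v5) and Level 3
Version 1: compartments, species (amounts or concentrations), parameters,
reactions with kinetic laws and local parameters, assignment/rate/
algebraic rules, initial assignments, constraints, events (trigger,
priority, delay, persistent, useValuesFromTriggerTime) and function
definitions.  Every MathML expression is parsed into an AST and
normalized at load time: FunctionDefinition calls are inlined and
piecewise nodes rewritten into arithmetic/logical form.

Species are represented internally as amounts; concentrations are
materialized on demand as amount / compartment size, which stays correct
when compartment sizes vary over time.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field

import numpy as np
from lxml import etree

from . import mathml
from .errors import (
    CycleError,
    ModelParseError,
    ModelSemanticError,
    UnsupportedFeatureError,
)
from .mathml import MathNode, parse_lambda, parse_mathml

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Definition records
# ---------------------------------------------------------------------------

@dataclass
class CompartmentDef:
    id: str
    size: float = 1.0
    constant: bool = True
    spatial_dimensions: float = 3.0


@dataclass
class SpeciesDef:
    id: str
    initial_value: float = math.nan
    initial_is_concentration: bool = False
    compartment: str = ""
    boundary_condition: bool = False
    constant: bool = False
    has_only_substance_units: bool = False


@dataclass
class ParameterDef:
    id: str
    value: float = math.nan
    constant: bool = True


@dataclass
class ReactionDef:
    id: str
    reactants: list = field(default_factory=list)   # (species id, stoichiometry)
    products: list = field(default_factory=list)
    modifiers: list = field(default_factory=list)
    kinetic_math: MathNode | None = None
    reversible: bool = True
    fast: bool = False


@dataclass
class RuleDef:
    kind: str            # "assignment" | "rate" | "algebraic"
    target: str | None   # None for algebraic rules
    math: MathNode = None


@dataclass
class InitialAssignmentDef:
    target: str
    math: MathNode = None


@dataclass
class ConstraintDef:
    math: MathNode = None
    message: str = ""


@dataclass
class EventDef:
    id: str
    trigger: MathNode = None
    persistent: bool = True
    initial_trigger_value: bool = True
    priority: MathNode | None = None
    delay: MathNode | None = None
    use_values_from_trigger_time: bool = True
    assignments: list = field(default_factory=list)  # (target id, MathNode)


@dataclass
class CompiledModel:
    """Normalized in-memory image of one SBML document.

    ``variable_index`` maps every compartment, species and parameter id
    to its slot in the state vector (species slots hold amounts).
    """

    sbml_level: int = 2
    sbml_version: int = 4
    compartments: list = field(default_factory=list)
    species: list = field(default_factory=list)
    parameters: list = field(default_factory=list)
    reactions: list = field(default_factory=list)
    assignment_rules: list = field(default_factory=list)
    rate_rules: list = field(default_factory=list)
    algebraic_rules: list = field(default_factory=list)
    initial_assignments: list = field(default_factory=list)
    constraints: list = field(default_factory=list)
    events: list = field(default_factory=list)
    function_defs: dict = field(default_factory=dict)
    variable_index: dict = field(default_factory=dict)

    # ---- id lookups -------------------------------------------------------
    def __post_init__(self):
        self._by_id = {}
        for group in (self.compartments, self.species, self.parameters):
            for d in group:
                self._by_id[d.id] = d

    def entity(self, ident):
        return self._by_id.get(ident)

    def is_constant(self, ident) -> bool:
        d = self._by_id.get(ident)
        return d is not None and d.constant

    def species_ids(self):
        return [s.id for s in self.species]

    # ---- state <-> value-map conversions ---------------------------------
    def reads_as_concentration(self, sp: SpeciesDef) -> bool:
        return not sp.has_only_substance_units

    def value_map(self, state) -> dict:
        """Mapping id -> value as seen by MathML expressions: compartment
        sizes, parameter values, and species as concentration unless
        hasOnlySubstanceUnits."""
        out = {}
        idx = self.variable_index
        for c in self.compartments:
            out[c.id] = state[idx[c.id]]
        for p in self.parameters:
            out[p.id] = state[idx[p.id]]
        for s in self.species:
            amount = state[idx[s.id]]
            if self.reads_as_concentration(s):
                size = out[s.compartment]
                out[s.id] = amount / size if size != 0.0 else math.nan
            else:
                out[s.id] = amount
        return out

    def write_value(self, state, ident, value):
        """Write an expression-level value back into the state vector,
        converting species concentrations to internal amounts."""
        d = self._by_id[ident]
        if isinstance(d, SpeciesDef) and self.reads_as_concentration(d):
            size = state[self.variable_index[d.compartment]]
            state[self.variable_index[ident]] = value * size
        else:
            state[self.variable_index[ident]] = value


# ---------------------------------------------------------------------------
# XML helpers
# ---------------------------------------------------------------------------

def _local(tag):
    return tag.rsplit("}", 1)[-1] if isinstance(tag, str) else ""


def _find(elem, name):
    for c in elem:
        if _local(c.tag) == name:
            return c
    return None


def _find_all(elem, name):
    return [c for c in elem if _local(c.tag) == name]


def _bool(elem, attr, default):
    v = elem.get(attr)
    if v is None:
        return default
    return v in ("true", "1")


def _float(elem, attr, default=math.nan):
    v = elem.get(attr)
    return float(v) if v is not None else default


def _math_of(elem, container):
    m = _find(elem, "math")
    if m is None:
        raise ModelSemanticError(f"missing <math> in {container}")
    return parse_mathml(m)


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

def load_model(source) -> CompiledModel:
    """Read an SBML document (file path or XML text/bytes) and return a
    :class:`CompiledModel` with all expressions normalized.

    Raises :class:`ModelParseError` for bad XML,
    :class:`ModelSemanticError` for unresolvable identifiers or
    conflicting rules, :class:`UnsupportedFeatureError` for constructs
    outside the supported subset.
    """
    root = _parse_xml(source)
    if _local(root.tag) != "sbml":
        raise ModelParseError("root element is not <sbml>")
    try:
        level = int(root.get("level"))
        version = int(root.get("version"))
    except (TypeError, ValueError):
        raise ModelParseError("<sbml> missing integer level/version") from None
    if level not in (2, 3):
        raise UnsupportedFeatureError(f"SBML Level {level} is not supported")

    melem = _find(root, "model")
    if melem is None:
        raise ModelParseError("document has no <model> element")

    model = CompiledModel(sbml_level=level, sbml_version=version)
    _load_function_defs(model, melem)
    _load_compartments(model, melem)
    _load_species(model, melem)
    _load_parameters(model, melem)
    _load_reactions(model, melem)
    _load_rules(model, melem)
    _load_initial_assignments(model, melem)
    _load_constraints(model, melem)
    _load_events(model, melem)
    model.__post_init__()  # rebuild id table after population

    _build_variable_index(model)
    _normalize_all_math(model)
    _validate(model)
    return model


def _parse_xml(source):
    parser = etree.XMLParser(remove_comments=True)
    try:
        if isinstance(source, bytes):
            return etree.fromstring(source, parser)
        if isinstance(source, str):
            if source.lstrip().startswith("<"):
                return etree.fromstring(source.encode(), parser)
            if not os.path.exists(source):
                raise ModelParseError(f"no such file: {source}")
            return etree.parse(source, parser).getroot()
        raise ModelParseError(f"cannot read SBML from {type(source).__name__}")
    except etree.XMLSyntaxError as exc:
        raise ModelParseError(f"ill-formed XML: {exc}") from exc


def _load_function_defs(model, melem):
    lst = _find(melem, "listOfFunctionDefinitions")
    if lst is None:
        return
    for fd in _find_all(lst, "functionDefinition"):
        fid = fd.get("id")
        m = _find(fd, "math")
        if m is None:
            raise ModelSemanticError(f"functionDefinition '{fid}' has no math")
        model.function_defs[fid] = parse_lambda(m)


def _load_compartments(model, melem):
    lst = _find(melem, "listOfCompartments")
    if lst is None:
        return
    for c in _find_all(lst, "compartment"):
        size = _float(c, "size", math.nan)
        if math.isnan(size):
            size = _float(c, "volume", math.nan)  # L1 leftover name, L2 allows
        dims = _float(c, "spatialDimensions", 3.0)
        if math.isnan(size):
            size = 1.0 if dims > 0 else 1.0
        model.compartments.append(CompartmentDef(
            id=c.get("id"),
            size=size,
            constant=_bool(c, "constant", True),
            spatial_dimensions=dims,
        ))


def _load_species(model, melem):
    lst = _find(melem, "listOfSpecies")
    if lst is None:
        return
    for s in _find_all(lst, "species"):
        amount = _float(s, "initialAmount", math.nan)
        conc = _float(s, "initialConcentration", math.nan)
        if not math.isnan(amount):
            init, is_conc = amount, False
        elif not math.isnan(conc):
            init, is_conc = conc, True
        else:
            init, is_conc = math.nan, False  # must come from InitialAssignment
        model.species.append(SpeciesDef(
            id=s.get("id"),
            initial_value=init,
            initial_is_concentration=is_conc,
            compartment=s.get("compartment", ""),
            boundary_condition=_bool(s, "boundaryCondition", False),
            constant=_bool(s, "constant", False),
            has_only_substance_units=_bool(s, "hasOnlySubstanceUnits", False),
        ))


def _load_parameters(model, melem):
    lst = _find(melem, "listOfParameters")
    if lst is None:
        return
    for p in _find_all(lst, "parameter"):
        model.parameters.append(ParameterDef(
            id=p.get("id"),
            value=_float(p, "value", math.nan),
            constant=_bool(p, "constant", True),
        ))


def _load_reactions(model, melem):
    lst = _find(melem, "listOfReactions")
    if lst is None:
        return
    for r in _find_all(lst, "reaction"):
        rid = r.get("id")
        rd = ReactionDef(
            id=rid,
            reversible=_bool(r, "reversible", True),
            fast=_bool(r, "fast", False),
        )
        for list_name, target in (("listOfReactants", rd.reactants),
                                  ("listOfProducts", rd.products)):
            le = _find(r, list_name)
            if le is None:
                continue
            for sr in _find_all(le, "speciesReference"):
                if _find(sr, "stoichiometryMath") is not None:
                    raise UnsupportedFeatureError(
                        f"stoichiometryMath in reaction '{rid}' is not supported")
                target.append((sr.get("species"),
                               _float(sr, "stoichiometry", 1.0)))
        me = _find(r, "listOfModifiers")
        if me is not None:
            rd.modifiers = [sr.get("species")
                            for sr in _find_all(me, "modifierSpeciesReference")]
        kl = _find(r, "kineticLaw")
        if kl is None:
            raise ModelSemanticError(f"reaction '{rid}' has no kineticLaw")
        math_ast = _math_of(kl, f"kineticLaw of reaction '{rid}'")
        # local parameters are constants scoped to this kinetic law:
        # substitute their numeric values directly into the AST
        locals_ = {}
        for lname in ("listOfLocalParameters", "listOfParameters"):
            lp = _find(kl, lname)
            if lp is None:
                continue
            for p in list(lp):
                if _local(p.tag) in ("localParameter", "parameter"):
                    locals_[p.get("id")] = MathNode.num(_float(p, "value", math.nan))
        if locals_:
            math_ast = mathml.substitute(math_ast, locals_)
        rd.kinetic_math = math_ast
        model.reactions.append(rd)


def _load_rules(model, melem):
    lst = _find(melem, "listOfRules")
    if lst is None:
        return
    for r in list(lst):
        tag = _local(r.tag)
        if tag == "assignmentRule":
            model.assignment_rules.append(RuleDef(
                "assignment", r.get("variable"), _math_of(r, "assignmentRule")))
        elif tag == "rateRule":
            model.rate_rules.append(RuleDef(
                "rate", r.get("variable"), _math_of(r, "rateRule")))
        elif tag == "algebraicRule":
            model.algebraic_rules.append(RuleDef(
                "algebraic", None, _math_of(r, "algebraicRule")))
        elif tag is not None and tag != "":
            raise UnsupportedFeatureError(f"unsupported rule type <{tag}>")


def _load_initial_assignments(model, melem):
    lst = _find(melem, "listOfInitialAssignments")
    if lst is None:
        return
    for ia in _find_all(lst, "initialAssignment"):
        model.initial_assignments.append(InitialAssignmentDef(
            target=ia.get("symbol"),
            math=_math_of(ia, "initialAssignment"),
        ))


def _load_constraints(model, melem):
    lst = _find(melem, "listOfConstraints")
    if lst is None:
        return
    for c in _find_all(lst, "constraint"):
        msg = _find(c, "message")
        text = "".join(msg.itertext()).strip() if msg is not None else ""
        model.constraints.append(ConstraintDef(
            math=_math_of(c, "constraint"), message=text))


def _load_events(model, melem):
    lst = _find(melem, "listOfEvents")
    if lst is None:
        return
    level = model.sbml_level
    for i, e in enumerate(_find_all(lst, "event")):
        eid = e.get("id") or f"_event{i}"
        te = _find(e, "trigger")
        if te is None:
            raise ModelSemanticError(f"event '{eid}' has no trigger")
        if level >= 3:
            persistent = _bool(te, "persistent", True)
            initial_value = _bool(te, "initialValue", True)
            uvftt = _bool(e, "useValuesFromTriggerTime", True)
        else:
            # L2: triggers are persistent and assumed true at t=0 (no
            # firing from the initial condition); assignments use
            # trigger-time values
            persistent = True
            initial_value = True
            uvftt = _bool(e, "useValuesFromTriggerTime", True)
        ev = EventDef(
            id=eid,
            trigger=_math_of(te, f"trigger of event '{eid}'"),
            persistent=persistent,
            initial_trigger_value=initial_value,
            use_values_from_trigger_time=uvftt,
        )
        pe = _find(e, "priority")
        if pe is not None:
            ev.priority = _math_of(pe, f"priority of event '{eid}'")
        de = _find(e, "delay")
        if de is not None:
            ev.delay = _math_of(de, f"delay of event '{eid}'")
        la = _find(e, "listOfEventAssignments")
        if la is not None:
            for ea in _find_all(la, "eventAssignment"):
                ev.assignments.append((
                    ea.get("variable"),
                    _math_of(ea, f"eventAssignment of event '{eid}'"),
                ))
        model.events.append(ev)


def _build_variable_index(model):
    idx = {}
    for group in (model.species, model.compartments, model.parameters):
        for d in group:
            if d.id in idx:
                raise ModelSemanticError(f"duplicate id '{d.id}'")
            idx[d.id] = len(idx)
    model.variable_index = idx


def _normalize_all_math(model):
    defs = model.function_defs
    norm = lambda ast: mathml.normalize(ast, defs)
    for r in model.reactions:
        r.kinetic_math = norm(r.kinetic_math)
    for group in (model.assignment_rules, model.rate_rules, model.algebraic_rules):
        for rule in group:
            rule.math = norm(rule.math)
    for ia in model.initial_assignments:
        ia.math = norm(ia.math)
    for c in model.constraints:
        c.math = norm(c.math)
    for ev in model.events:
        ev.trigger = norm(ev.trigger)
        if ev.priority is not None:
            ev.priority = norm(ev.priority)
        if ev.delay is not None:
            ev.delay = norm(ev.delay)
        ev.assignments = [(t, norm(a)) for t, a in ev.assignments]


def _validate(model):
    known = set(model.variable_index)
    reaction_ids = {r.id for r in model.reactions}

    def check(ast, container):
        for ident in ast.referenced_ids():
            if ident not in known and ident not in reaction_ids:
                raise ModelSemanticError(
                    f"unresolvable identifier '{ident}' in {container}")

    for r in model.reactions:
        check(r.kinetic_math, f"kineticLaw of reaction '{r.id}'")
        for sid, _ in r.reactants + r.products:
            if sid not in known:
                raise ModelSemanticError(
                    f"unknown species '{sid}' in reaction '{r.id}'")
    for rule in model.assignment_rules + model.rate_rules:
        if rule.target not in known:
            raise ModelSemanticError(
                f"rule targets unknown variable '{rule.target}'")
        if model.is_constant(rule.target):
            raise ModelSemanticError(
                f"rule targets constant '{rule.target}'")
        check(rule.math, f"{rule.kind} rule for '{rule.target}'")
    for rule in model.algebraic_rules:
        check(rule.math, "algebraicRule")
    for ia in model.initial_assignments:
        if ia.target not in known:
            raise ModelSemanticError(
                f"initialAssignment targets unknown symbol '{ia.target}'")
        check(ia.math, f"initialAssignment of '{ia.target}'")
    for c in model.constraints:
        check(c.math, "constraint")
    for ev in model.events:
        check(ev.trigger, f"trigger of event '{ev.id}'")
        if ev.priority is not None:
            check(ev.priority, f"priority of event '{ev.id}'")
        if ev.delay is not None:
            check(ev.delay, f"delay of event '{ev.id}'")
        for tgt, ast in ev.assignments:
            if tgt not in known:
                raise ModelSemanticError(
                    f"event '{ev.id}' assigns unknown variable '{tgt}'")
            if model.is_constant(tgt):
                raise ModelSemanticError(
                    f"event '{ev.id}' assigns constant '{tgt}'")
            check(ast, f"eventAssignment of '{ev.id}'")

    # one-determiner check: a variable may be governed by at most one of
    # {assignment rule, rate rule}
    seen = {}
    for rule in model.assignment_rules + model.rate_rules:
        if rule.target in seen:
            raise ModelSemanticError(
                f"variable '{rule.target}' is the target of both a "
                f"{seen[rule.target]} rule and a {rule.kind} rule")
        seen[rule.target] = rule.kind


# ---------------------------------------------------------------------------
# Initial state
# ---------------------------------------------------------------------------

def resolve_initial_state(model: CompiledModel):
    """State vector at t=0 (species as amounts).

    Declared values are installed first; initial assignments are then
    evaluated in dependency order (a species declared by
    initialConcentration implicitly depends on its compartment's size);
    finally assignment rules are applied, also in dependency order.
    Raises :class:`CycleError` on circular dependencies.
    """
    n = len(model.variable_index)
    state = np.zeros(n)
    idx = model.variable_index

    for c in model.compartments:
        state[idx[c.id]] = c.size
    for p in model.parameters:
        state[idx[p.id]] = p.value if not math.isnan(p.value) else 0.0

    ia_targets = {ia.target for ia in model.initial_assignments}

    # phase 1 nodes: explicit initial assignments plus implicit
    # concentration->amount conversions for declared species
    nodes = []  # (target, math-or-None, species-def-or-None)
    for ia in model.initial_assignments:
        nodes.append((ia.target, ia.math, None))
    for s in model.species:
        if s.id in ia_targets:
            continue
        if math.isnan(s.initial_value):
            raise ModelSemanticError(
                f"species '{s.id}' has no initial value and no initialAssignment")
        nodes.append((s.id, None, s))

    for target, ast, sdef in _topo_order(nodes, model):
        if sdef is not None:
            size = state[idx[sdef.compartment]] if sdef.initial_is_concentration else 1.0
            state[idx[sdef.id]] = (sdef.initial_value * size
                                   if sdef.initial_is_concentration
                                   else sdef.initial_value)
        else:
            value = _eval_ast(ast, model, state, t=0.0)
            model.write_value(state, target, value)

    # phase 2: assignment rules in dependency order
    rule_nodes = [(r.target, r.math, None) for r in model.assignment_rules]
    for target, ast, _ in _topo_order(rule_nodes, model):
        value = _eval_ast(ast, model, state, t=0.0)
        model.write_value(state, target, value)

    return state


def _topo_order(nodes, model):
    """Kahn topological sort of (target, math, species) nodes; an edge
    a -> b exists when b's expression references a's target (or, for a
    concentration species, its compartment)."""
    targets = {t for t, _, _ in nodes}
    deps = {}
    for t, ast, sdef in nodes:
        if ast is not None:
            refs = ast.referenced_ids()
        elif sdef is not None and sdef.initial_is_concentration:
            refs = {sdef.compartment}
        else:
            refs = set()
        deps[t] = {r for r in refs if r in targets and r != t}
    order = []
    ready = sorted(t for t, d in deps.items() if not d)
    remaining = {t: set(d) for t, d in deps.items() if d}
    node_of = {t: (t, ast, sdef) for t, ast, sdef in nodes}
    while ready:
        t = ready.pop(0)
        order.append(node_of[t])
        newly = []
        for u, d in remaining.items():
            d.discard(t)
            if not d:
                newly.append(u)
        for u in sorted(newly):
            del remaining[u]
            ready.append(u)
    if remaining:
        cycle = sorted(remaining)
        raise CycleError(cycle + [cycle[0]])
    return order


def _eval_ast(ast, model, state, t):
    prog = mathml.compile_to_rpn(ast)
    ctx = mathml.EvalContext(time=t, values=model.value_map(state))
    return mathml.evaluate(prog, ctx)
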