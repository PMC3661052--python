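"""Assemble the ODE/DAE system from a loaded model.

The time derivative of each non-boundary, non-constant species is the
stoichiometry-weighted sum of the kinetic laws of the reactions it
participates in; kinetic laws are extensive rates (amount/time), so the
sum is directly d(amount)/dt.  Rate rules contribute derivatives for
their targets; assignment rules form a dependency-ordered closure that is
re-applied before every derivative evaluation and before output; each
AlgebraicRule contributes one constraint g(state) = 0 that implicitly
determines one otherwise-undetermined variable, solved by Newton
iteration after every accepted step.

Reactions carrying the ``fast`` flag form a quasi-equilibrium subsystem:
after every accepted step their participating species are projected onto
the manifold where every fast rate is zero, while conserving the totals
given by the left null space of the fast stoichiometric matrix.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from . import mathml
from .errors import ConvergenceError, ModelSemanticError
from .loader import CompiledModel, SpeciesDef
from .numerics import NewtonSettings, left_null_space, newton_solve

log = logging.getLogger(__name__)


@dataclass
class OdeSystem:
    """Compiled right-hand side of one model."""

    model: CompiledModel
    n_vars: int = 0
    # var index -> list of (stoichiometric coefficient, reaction id)
    reaction_terms: dict = field(default_factory=dict)
    # reaction id -> RpnProgram of the kinetic law (document order preserved)
    reaction_programs: dict = field(default_factory=dict)
    # var index -> (RpnProgram, compartment index for conc->amount scaling or None)
    rate_rule_programs: dict = field(default_factory=dict)
    # dependency-ordered list of (target id, RpnProgram)
    assignment_closure: list = field(default_factory=list)
    # list of RpnPrograms required to equal zero
    algebraic_constraints: list = field(default_factory=list)
    # ids solved from the constraints, one per constraint
    algebraic_variables: list = field(default_factory=list)
    constraint_programs: list = field(default_factory=list)  # SBML Constraints

    # ------------------------------------------------------------------
    @property
    def n_differential(self) -> int:
        return len(self.differential_indices())

    def differential_indices(self) -> set:
        return set(self.reaction_terms) | set(self.rate_rule_programs)

    def uses_delay(self) -> bool:
        progs = list(self.reaction_programs.values())
        progs += [p for p, _ in self.rate_rule_programs.values()]
        progs += [p for _, p in self.assignment_closure]
        progs += self.algebraic_constraints
        return any(p.uses_delay for p in progs)

    # ------------------------------------------------------------------
    def context_values(self, state, t, delay=None) -> dict:
        """id -> value mapping for expression evaluation, including
        current reaction rates (evaluated in document order so later
        kinetic laws may reference earlier reaction ids)."""
        values = self.model.value_map(state)
        ctx = mathml.EvalContext(time=t, values=values, delay=delay)
        for rid, prog in self.reaction_programs.items():
            values[rid] = mathml.evaluate(prog, ctx)
        return values

    def apply_assignment_closure(self, state, t, delay=None):
        """Recompute every assignment-rule target in dependency order;
        mutates and returns ``state``."""
        for target, prog in self.assignment_closure:
            values = self.model.value_map(state)
            ctx = mathml.EvalContext(time=t, values=values, delay=delay)
            self.model.write_value(state, target, mathml.evaluate(prog, ctx))
        return state

    def derivative(self, t, state, delay=None):
        """d(state)/dt as an array (zero for non-differential slots).

        The assignment closure is applied (on a scratch copy) before
        evaluation so that rule targets are consistent with ``state``.
        """
        work = self.apply_assignment_closure(np.array(state, copy=True), t, delay)
        values = self.context_values(work, t, delay)
        ctx = mathml.EvalContext(time=t, values=values, delay=delay)
        dydt = np.zeros(self.n_vars)
        for vi, terms in self.reaction_terms.items():
            acc = 0.0
            for coef, rid in terms:
                acc += coef * values[rid]
            dydt[vi] = acc
        for vi, (prog, comp_idx) in self.rate_rule_programs.items():
            rate = mathml.evaluate(prog, ctx)
            if comp_idx is not None:
                rate *= work[comp_idx]  # d(conc)/dt -> d(amount)/dt
            dydt[vi] = rate
        return dydt

    def solve_algebraic(self, state, t, settings=None, delay=None):
        """Adjust the algebraic variables so every AlgebraicRule
        constraint is zero; mutates and returns ``state``."""
        if not self.algebraic_constraints:
            return state
        settings = settings or NewtonSettings()
        idx = self.model.variable_index
        var_idx = [idx[v] for v in self.algebraic_variables]
        conc = []
        for v in self.algebraic_variables:
            d = self.model.entity(v)
            conc.append(isinstance(d, SpeciesDef)
                        and self.model.reads_as_concentration(d))

        def residual(x):
            work = np.array(state, copy=True)
            for i, vi in enumerate(var_idx):
                work[vi] = x[i]
            self.apply_assignment_closure(work, t, delay)
            values = self.context_values(work, t, delay)
            ctx = mathml.EvalContext(time=t, values=values, delay=delay)
            return np.array([mathml.evaluate(p, ctx)
                             for p in self.algebraic_constraints])

        x0 = np.array([state[vi] for vi in var_idx])
        x = newton_solve(residual, x0, settings)
        for i, vi in enumerate(var_idx):
            state[vi] = x[i]
        return state

    def check_constraints(self, state, t):
        """Evaluate SBML Constraint elements; log (never halt) on violation."""
        if not self.constraint_programs:
            return
        values = self.context_values(state, t)
        ctx = mathml.EvalContext(time=t, values=values)
        for i, prog in enumerate(self.constraint_programs):
            if mathml.evaluate(prog, ctx) == 0.0:
                log.warning("constraint %d violated at t=%g", i, t)


def build_ode_system(model: CompiledModel) -> OdeSystem:
    """Compile reactions, rules and constraints into an :class:`OdeSystem`."""
    sys_ = OdeSystem(model=model, n_vars=len(model.variable_index))
    idx = model.variable_index
    assignment_targets = {r.target for r in model.assignment_rules}
    rate_targets = {r.target for r in model.rate_rules}

    for r in model.reactions:
        sys_.reaction_programs[r.id] = mathml.compile_to_rpn(r.kinetic_math)
        for sign, refs in ((-1.0, r.reactants), (+1.0, r.products)):
            for sid, stoich in refs:
                sp = model.entity(sid)
                if sp.boundary_condition or sp.constant:
                    continue
                if sid in assignment_targets or sid in rate_targets:
                    raise ModelSemanticError(
                        f"species '{sid}' is both reaction-determined and "
                        f"rule-determined")
                sys_.reaction_terms.setdefault(idx[sid], []).append(
                    (sign * stoich, r.id))

    for rule in model.rate_rules:
        d = model.entity(rule.target)
        comp_idx = None
        if isinstance(d, SpeciesDef) and model.reads_as_concentration(d):
            comp_idx = idx[d.compartment]
        sys_.rate_rule_programs[idx[rule.target]] = (
            mathml.compile_to_rpn(rule.math), comp_idx)

    sys_.assignment_closure = _ordered_closure(model)
    _assign_algebraic_variables(model, sys_, assignment_targets)
    sys_.constraint_programs = [mathml.compile_to_rpn(c.math)
                                for c in model.constraints]
    return sys_


def _ordered_closure(model):
    rules = model.assignment_rules
    targets = {r.target for r in rules}
    deps = {r.target: {i for i in r.math.referenced_ids()
                       if i in targets and i != r.target}
            for r in rules}
    by_target = {r.target: r for r in rules}
    order = []
    ready = sorted(t for t, d in deps.items() if not d)
    remaining = {t: set(d) for t, d in deps.items() if d}
    while ready:
        t = ready.pop(0)
        order.append((t, mathml.compile_to_rpn(by_target[t].math)))
        newly = []
        for u, d in remaining.items():
            d.discard(t)
            if not d:
                newly.append(u)
        for u in sorted(newly):
            del remaining[u]
            ready.append(u)
    if remaining:
        from .errors import CycleError
        cyc = sorted(remaining)
        raise CycleError(cyc + [cyc[0]])
    return order


def _assign_algebraic_variables(model, sys_, assignment_targets):
    if not model.algebraic_rules:
        return
    differential = sys_.differential_indices()
    idx = model.variable_index
    doc_order = sorted(idx, key=idx.get)
    taken = set()
    for rule in model.algebraic_rules:
        refs = rule.math.referenced_ids()
        candidates = [v for v in doc_order
                      if v in refs
                      and not model.is_constant(v)
                      and idx[v] not in differential
                      and v not in assignment_targets
                      and v not in taken]
        if not candidates:
            raise ModelSemanticError(
                "over-determined model: algebraicRule has no free variable")
        if len(candidates) > 1:
            log.info("algebraicRule: ambiguous free variable, choosing '%s' "
                     "(document order)", candidates[0])
        chosen = candidates[0]
        taken.add(chosen)
        sys_.algebraic_variables.append(chosen)
        sys_.algebraic_constraints.append(mathml.compile_to_rpn(rule.math))
    if len(sys_.algebraic_constraints) != len(sys_.algebraic_variables):
        raise ModelSemanticError("algebraic system is not square")


# ---------------------------------------------------------------------------
# Fast reactions
# ---------------------------------------------------------------------------

@dataclass
class FastPartition:
    """Quasi-equilibrium subsystem induced by ``fast`` reactions.

    ``conservation`` rows y satisfy y^T N_fast = 0; the totals y . x are
    invariant under fast kinetics and pin down the equilibrium together
    with the zero-rate conditions.
    """

    fast_reaction_ids: list = field(default_factory=list)
    fast_species: list = field(default_factory=list)      # ids
    stoichiometry: np.ndarray | None = None               # m x r
    conservation: list = field(default_factory=list)      # vectors over fast species

    def __bool__(self):
        return bool(self.fast_reaction_ids)


def partition_fast_reactions(model: CompiledModel) -> FastPartition:
    """Identify the fast subsystem: participating (non-boundary,
    non-constant) species, the fast stoichiometric matrix, and its
    conserved totals.  Empty partition when no reaction is fast."""
    part = FastPartition()
    fast = [r for r in model.reactions if r.fast]
    if not fast:
        return part
    part.fast_reaction_ids = [r.id for r in fast]
    species = []
    for r in fast:
        for sid, _ in r.reactants + r.products:
            sp = model.entity(sid)
            if sp.boundary_condition or sp.constant:
                continue
            if sid not in species:
                species.append(sid)
    part.fast_species = species
    m, rck = len(species), len(fast)
    N = np.zeros((m, rck))
    pos = {s: i for i, s in enumerate(species)}
    for j, r in enumerate(fast):
        for sign, refs in ((-1.0, r.reactants), (+1.0, r.products)):
            for sid, stoich in refs:
                if sid in pos:
                    N[pos[sid], j] += sign * stoich
    part.stoichiometry = N
    part.conservation = left_null_space(N)
    rank = m - len(part.conservation)
    if rank != rck:
        raise ModelSemanticError(
            f"fast subsystem is not square: {rck} fast reactions but "
            f"stoichiometric rank {rank}")
    return part


def equilibrate_fast(partition: FastPartition, system: OdeSystem, state, t,
                     settings=None):
    """Replace the fast species by the root of {every fast rate = 0,
    every conserved total unchanged}; mutates and returns ``state``.

    Raises :class:`ConvergenceError` (with the Newton residual attached)
    when no equilibrium is reachable from the current state.
    """
    if not partition:
        return state
    settings = settings or NewtonSettings()
    model = system.model
    idx = model.variable_index
    var_idx = [idx[s] for s in partition.fast_species]
    totals = [float(np.dot(y, [state[vi] for vi in var_idx]))
              for y in partition.conservation]

    def residual(x):
        work = np.array(state, copy=True)
        for i, vi in enumerate(var_idx):
            work[vi] = x[i]
        system.apply_assignment_closure(work, t)
        values = system.context_values(work, t)
        res = [values[rid] for rid in partition.fast_reaction_ids]
        for y, total in zip(partition.conservation, totals):
            res.append(float(np.dot(y, x)) - total)
        return np.array(res)

    x0 = np.array([state[vi] for vi in var_idx])
    try:
        x = newton_solve(residual, x0, settings)
    except ConvergenceError as exc:
        raise ConvergenceError(
            f"fast-reaction equilibration failed at t={t:g}: {exc}",
            residual=exc.residual, iterations=exc.iterations) from exc
    for i, vi in enumerate(var_idx):
        state[vi] = x[i]
    return state
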