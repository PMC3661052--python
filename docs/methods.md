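# Methods

This note documents the model of computation, the numerical choices and
their defaults, what the generated fixtures do and do not exercise, and
the known limitations.

## From SBML document to equations

A document is parsed (lxml) into a normalized in-memory model. All
MathML is converted to an AST at load time and immediately normalized:

1. **FunctionDefinition inlining.** Every call node is replaced by the
   definition body with formal parameters structurally substituted by
   the actual argument ASTs. SBML forbids recursive definitions;
   recursion is detected and rejected. Substitution is capture-free
   because SBML lambdas contain no nested binders.
2. **Piecewise rewriting.** `piecewise(v₁,c₁,…,v_k,c_k[,w])` becomes
   `Σᵢ vᵢ·(cᵢ ∧ ¬c₁ ∧ … ∧ ¬cᵢ₋₁) + w·(¬c₁ ∧ … ∧ ¬c_k)`, i.e. each
   branch value is multiplied by its guard and the guarded terms are
   summed. Overlapping conditions therefore resolve as
   *first-true-wins*. With no `otherwise` and no true condition the
   expression evaluates to 0; this case is undefined in SBML, so a
   warning is logged when such a piecewise is transformed. Note the
   guard product only preserves the branch value when the guarded-off
   branches are finite (0·∞ = NaN); the test suite respects this.

The normalized AST is compiled once into Reverse Polish notation and
evaluated by a stack machine. Booleans are doubles (relational/logical
opcodes push 1.0/0.0; any non-zero operand counts as true, matching C
semantics). Domain errors (x/0, log of a non-positive) produce IEEE
infinities/NaN with a single logged warning per program rather than
exceptions, so a guarded branch can contain an expression that is
undefined outside its guard. A static stack-balance check validates
every compiled program.

**Species units.** Species are stored internally as *amounts*;
expressions see a species as concentration (amount / compartment size)
unless `hasOnlySubstanceUnits` is set. This convention stays correct
when compartment sizes change over time. Writes (rules, events,
initial assignments) convert in the opposite direction.

## The ODE/DAE system

For each species not fixed by `boundaryCondition`/`constant` and not
governed by a rule, dn/dt is the stoichiometry-weighted sum of kinetic
laws (extensive rates, per the SBML specification). Rate rules supply
derivatives for their targets; a rate rule on a concentration-based
species is integrated as d(amount)/dt = size · d(conc)/dt with the size
taken at evaluation time (the additional product-rule term for a
simultaneously time-varying compartment is not modelled — a known
limitation). Assignment rules are topologically ordered once and
re-applied before every derivative evaluation and before output; cycles
are a load-time error.

**AlgebraicRules.** Each rule contributes one constraint g(x) = 0. Its
*algebraic variable* is the unique referenced variable not otherwise
determined (not constant, not reaction- or rate-rule-driven, not an
assignment target, not claimed by another rule); ambiguity resolves to
document order with a logged note. After every accepted step the
algebraic variables are adjusted by Newton iteration until every
|g| < tolerance, so the reported trajectory always satisfies the
constraints to solver tolerance.

**Fast reactions.** Reactions flagged `fast` form a quasi-equilibrium
subsystem: their participating (non-boundary, non-constant) species are
projected, after every accepted step, onto the manifold where every
fast rate is zero, subject to conservation of the totals y·x for each
left-null-space vector y of the fast stoichiometric matrix. This
equilibrate-after-step scheme is a first-order splitting: its accuracy
is controlled by the step density, and the tests compare it against a
brute-force stiff integration of the same network with the fast
kinetics scaled by 10⁶. A fast subsystem whose reaction count differs
from its stoichiometric rank is rejected as non-square.

## Integrators

All steppers operate on y′ = f(t, y) with f closed over the assignment
closure and delay lookups.

| family | type | notes |
|---|---|---|
| euler | explicit, O(h) | yₙ₊₁ = yₙ + h f(tₙ, yₙ) |
| rk4 | explicit, O(h⁴) | classical 4-stage |
| adams_bashforth 1–4 | explicit multistep | fixed coefficients |
| backward_euler | implicit, O(h), A-stable | Newton-solved |
| adams_moulton 1–4 | implicit multistep | order 1 = backward Euler, 2 = trapezoid |
| gear (BDF) 1–4 | implicit multistep | order 1 ≡ backward Euler bitwise |
| rkf45, cash_karp | adaptive embedded 4(5) | published tableaux |

Implicit updates solve F(z) = z − (explicit part) − h·b·f(t+h, z) = 0
with plain undamped Newton seeded at yₙ (tolerance 1e−10, max 100
iterations, forward-difference Jacobian with step √ε·max(|x|,1)); on
non-convergence the backward-Euler path retries with up to 10 step
halvings. The adaptive controller uses error
max |y₅−y₄| / (atol + rtol·|y|), acceptance at ≤ 1, and next step
h·min(5, max(0.1, 0.9·err^(−1/5))) — the conventional safety/growth/
shrink constants. Step underflow below duration·1e−12 raises a
stiffness error that names the implicit alternatives.

Multistep methods start up with a one-step method of the *same
stability class* (RK4 for Adams–Bashforth, backward Euler for
Adams–Moulton/Gear — an explicit starter would destroy A-stability on
stiff problems) and their history is invalidated whenever an event
assignment or fast equilibration moves the state discontinuously, or
when step clamping changes the spacing.

The main loop clamps internal steps to the next output time and the
next pending delayed-event fire time, and sets t to the stop point
exactly rather than accumulating; output times are computed as
i·duration/steps by multiplication. Fixed-step methods use
h = duration/(steps·refinement), refinement defaulting to 10.

## Events

Triggers are evaluated at accepted-step boundaries; an event fires on a
false→true edge relative to the previous check. There is no
root-finding refinement of the crossing time, so event timing is
resolved to the internal step size — increase `refinement` (or use
denser output) for sharper timing. Level 2 events are persistent and
considered "already true" at t = 0 (no firing from the initial
condition); Level 3 honors `initialValue`, so a satisfied trigger with
`initialValue="false"` fires at t = 0.

Simultaneously fired events run a cascade: evaluate all priorities in
the current state, execute the maximum-priority event (all assignment
right-hand sides evaluated before any target is written), drop queued
non-persistent events whose trigger lapsed, enqueue events whose
trigger was flipped false→true, repeat. Events without a Priority rank
below any numeric priority; order among them (and exact ties) is broken
by a seeded RNG, making runs reproducible for a fixed seed. A cascade
exceeding 10,000 executions raises a livelock error.

Delayed events evaluate their Delay expression at trigger time; with
`useValuesFromTriggerTime` the assignment values are computed
immediately and frozen. Pending executions of non-persistent events are
cancelled if their trigger lapses before the fire time. The integrator
clamps steps to fire times so execution lands exactly on them; ties are
ordered by fire time, then descending priority, then the seeded RNG.

## Delay expressions

`delay(expr, τ)` is served by a history buffer holding the full state
vector at every accepted step (full retention for the whole run; memory
is linear in step count). Lookups linearly interpolate between
bracketing samples; times before the record return the initial state,
and times marginally beyond the newest sample (reachable transiently
inside a step when τ < h) clamp to it. Queries against SBML Constraint
elements are evaluated at step boundaries and log violations without
halting.

## Fixtures and what they show

`sbmlsim.fixtures.make_fixture` generates one minimal SBML document per
feature (decay, chains, stiff decay, function definitions, piecewise,
all three rule types, four event variants, delay expressions, fast
reactions, boundary species), in both L2V4 and L3V1 dialects where the
feature exists in both. Defaults are chosen to make the analytic
solution or the semantic outcome hand-checkable: decay k = 0.5 with
S1(0) = 10; the DDE uses lag 1 with unit pre-history so y = 1 − t on
the first interval; the event-delay model tracks p = 4 + t so the
captured-vs-live values are exactly 5 and 7; the fast pair uses net
rate 2A − B with total 3 so the equilibrium is exactly A = 1, B = 2.

These models are deliberately small and smooth. Passing them
demonstrates the semantics and the numerics at modest scale; it does
not demonstrate performance on large networks, robustness to badly
scaled kinetics beyond the stiff probes, or coverage of SBML constructs
outside the supported subset (see below). A harness for the SBML test
suite's on-disk case layout (`run_suite_case`) is included for users
with a local copy of the corpus; it applies the suite's own
point-by-point tolerance criterion |computed − expected| ≤
atol + rtol·|expected|.

## Problem sizes used in tests and the acceptance script

Decay accuracy uses 500 internal RK4 steps over duration 10;
convergence orders compare global errors at h = 0.05 vs 0.025;
conservation integrates a closed 3-species chain to duration 100
(1000 internal steps); the DDE uses h = 1e−3 over one delay interval;
the fast-reaction comparison runs 800 internal steps against a Gear-2
brute-force reference with kinetics ×10⁶. These sizes make every check
run in well under a second while leaving each method's error signature
clearly measurable.

## Known limitations

- SBML Level 1, `stoichiometryMath`, variable stoichiometries, unit
  inference/validation, and the comp/fbc/other packages are out of
  scope; csymbols other than time/avogadro/delay are rejected.
- Event timing is resolved to the internal step, not root-found.
- Gear/Adams methods are fixed-step, orders 1–4; no variable-order BDF.
- Plain Newton without damping: pathological seeds (e.g. a singular
  Jacobian manifold) fail cleanly rather than being globalized.
- The quasi-equilibrium treatment of `fast` reactions is first-order in
  the step size; tighten `refinement` for sharper agreement with the
  true stiff limit.
- Concentration rate rules assume the compartment size is constant over
  a step (no product-rule term).
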