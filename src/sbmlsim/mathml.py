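"""MathML expression handling: AST, transforms, RPN compilation, evaluation.

Every mathematical expression in an SBML document (kinetic laws, rules,
triggers, priorities, delays, event assignments) is parsed into a small
immutable AST (:class:`MathNode`), normalized by two transforms —
FunctionDefinition inlining and piecewise rewriting — and then compiled
once into postfix form (:class:`RpnProgram`) that a simple stack machine
evaluates without recursion.  The piecewise rewrite multiplies each branch
value with its guard condition and combines branches with addition, using
AND/NOT so that the first true condition wins.

Booleans are represented as doubles: relational and logical opcodes push
1.0 or 0.0, and any non-zero operand is treated as true (C semantics).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping

from .errors import CycleError, ModelSemanticError, UnsupportedFeatureError

log = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# AST
# ---------------------------------------------------------------------------

#: node kinds
NUM = "num"            # payload: float
NAME = "name"          # payload: identifier
TIME = "time"          # csymbol time
AVOGADRO = "avogadro"  # csymbol avogadro
OP = "op"              # payload: one of + - * / ^ neg
FUNC = "func"          # payload: builtin function name, children = args
REL = "rel"            # payload: lt/leq/gt/geq/eq/neq
LOGIC = "logic"        # payload: and/or/xor/not
CALL = "call"          # payload: user FunctionDefinition id
PIECEWISE = "piecewise"  # children: v1,c1,...,vk,ck[,otherwise]
DELAY = "delay"        # children: (expression, lag)

AVOGADRO_VALUE = 6.02214179e23  # value fixed by the SBML L3 specification

_REL_TAGS = {"lt", "leq", "gt", "geq", "eq", "neq"}
_LOGIC_TAGS = {"and", "or", "xor", "not"}

_UNARY_FUNCS = {
    "abs", "exp", "ln", "log10", "sqrt", "floor", "ceiling", "factorial",
    "sin", "cos", "tan", "sec", "csc", "cot",
    "arcsin", "arccos", "arctan", "arcsec", "arccsc", "arccot",
    "sinh", "cosh", "tanh", "sech", "csch", "coth",
    "arcsinh", "arccosh", "arctanh", "arcsech", "arccsch", "arccoth",
}
_BINARY_FUNCS = {"pow", "root", "log"}  # log(base, x), root(degree, x)


@dataclass(frozen=True)
class MathNode:
    """One node of a MathML expression tree.

    ``kind`` selects the interpretation of ``payload`` and the required
    arity of ``children`` (checked in ``__post_init__``).
    """

    kind: str
    payload: object = None
    children: tuple["MathNode", ...] = ()

    def __post_init__(self):
        k = self.kind
        n = len(self.children)
        if k == NUM and not isinstance(self.payload, float):
            object.__setattr__(self, "payload", float(self.payload))
        if k == OP:
            want = 1 if self.payload == "neg" else 2
            if n != want:
                raise ModelSemanticError(
                    f"operator '{self.payload}' expects {want} operands, got {n}")
        elif k == REL and n != 2:
            raise ModelSemanticError(f"relational '{self.payload}' needs 2 operands")
        elif k == LOGIC:
            want = 1 if self.payload == "not" else 2
            if n != want:
                raise ModelSemanticError(f"logical '{self.payload}' arity mismatch")
        elif k == DELAY and n != 2:
            raise ModelSemanticError("delay takes exactly (expression, lag)")
        elif k == FUNC:
            want = 2 if self.payload in _BINARY_FUNCS else 1
            if n != want:
                raise ModelSemanticError(
                    f"function '{self.payload}' expects {want} argument(s), got {n}")

    # -- convenience constructors ------------------------------------------
    @staticmethod
    def num(v) -> "MathNode":
        return MathNode(NUM, float(v))

    @staticmethod
    def name(ident) -> "MathNode":
        return MathNode(NAME, ident)

    def walk(self):
        """Iterative pre-order traversal."""
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def referenced_ids(self) -> set:
        return {n.payload for n in self.walk() if n.kind == NAME}


# ---------------------------------------------------------------------------
# MathML parsing (namespace-agnostic; works for L2 and L3 documents)
# ---------------------------------------------------------------------------

def _local(tag) -> str:
    return tag.rsplit("}", 1)[-1] if isinstance(tag, str) else ""


def _children(elem):
    return [c for c in elem if isinstance(c.tag, str)]


_MATHML_CONSTANTS = {
    "pi": math.pi,
    "exponentiale": math.e,
    "infinity": math.inf,
    "notanumber": math.nan,
    "true": 1.0,
    "false": 0.0,
}

_NARY = {"plus", "times", "and", "or", "xor"}

_OP_TAGS = {"plus": "+", "minus": "-", "times": "*", "divide": "/", "power": "^"}


def parse_mathml(elem) -> MathNode:
    """Convert an lxml element (the ``<math>`` element or its content)
    into a :class:`MathNode` tree.

    Raises :class:`UnsupportedFeatureError` for csymbols other than
    time/avogadro/delay and :class:`ModelSemanticError` for malformed
    expressions.
    """
    tag = _local(elem.tag)
    if tag == "math":
        kids = _children(elem)
        if len(kids) != 1:
            raise ModelSemanticError("<math> must contain exactly one expression")
        return parse_mathml(kids[0])

    if tag == "cn":
        return _parse_cn(elem)
    if tag == "ci":
        return MathNode.name(elem.text.strip())
    if tag == "csymbol":
        return _parse_csymbol_leaf(elem)
    if tag in _MATHML_CONSTANTS:
        return MathNode.num(_MATHML_CONSTANTS[tag])
    if tag == "piecewise":
        return _parse_piecewise(elem)
    if tag == "apply":
        return _parse_apply(elem)
    if tag == "lambda":
        raise ModelSemanticError("<lambda> only allowed inside FunctionDefinition")
    raise UnsupportedFeatureError(f"unsupported MathML element <{tag}>")


def _parse_cn(elem) -> MathNode:
    ctype = elem.get("type", "real")
    if ctype in ("real", "integer"):
        return MathNode.num(float(elem.text.strip()))
    if ctype == "e-notation":
        mant, expo = _sep_parts(elem)
        return MathNode.num(float(mant) * 10.0 ** float(expo))
    if ctype == "rational":
        num, den = _sep_parts(elem)
        return MathNode.num(float(num) / float(den))
    raise UnsupportedFeatureError(f"<cn type='{ctype}'> not supported")


def _sep_parts(elem):
    # <cn type="e-notation"> 1 <sep/> -3 </cn>
    first = (elem.text or "").strip()
    seps = [c for c in elem if _local(c.tag) == "sep"]
    if len(seps) != 1:
        raise ModelSemanticError("<cn> with sep must have exactly one <sep/>")
    second = (seps[0].tail or "").strip()
    return first, second


def _parse_csymbol_leaf(elem) -> MathNode:
    url = elem.get("definitionURL", "")
    if url.endswith("/time"):
        return MathNode(TIME)
    if url.endswith("/avogadro"):
        return MathNode(AVOGADRO)
    if url.endswith("/delay"):
        raise ModelSemanticError("delay csymbol must be applied to arguments")
    raise UnsupportedFeatureError(f"csymbol '{url}' not supported")


def _parse_piecewise(elem) -> MathNode:
    children = []
    saw_otherwise = False
    for part in _children(elem):
        ptag = _local(part.tag)
        kids = _children(part)
        if ptag == "piece":
            if saw_otherwise:
                raise ModelSemanticError("<piece> after <otherwise>")
            if len(kids) != 2:
                raise ModelSemanticError("<piece> needs (value, condition)")
            children.append(parse_mathml(kids[0]))
            children.append(parse_mathml(kids[1]))
        elif ptag == "otherwise":
            if len(kids) != 1:
                raise ModelSemanticError("<otherwise> needs one child")
            children.append(parse_mathml(kids[0]))
            saw_otherwise = True
        else:
            raise ModelSemanticError(f"unexpected <{ptag}> inside piecewise")
    return MathNode(PIECEWISE, None, tuple(children))


def _parse_apply(elem) -> MathNode:
    kids = _children(elem)
    if not kids:
        raise ModelSemanticError("empty <apply>")
    head, *rest = kids
    htag = _local(head.tag)

    # applied user function or delay csymbol
    if htag == "ci":
        args = tuple(parse_mathml(a) for a in rest)
        return MathNode(CALL, head.text.strip(), args)
    if htag == "csymbol":
        url = head.get("definitionURL", "")
        if url.endswith("/delay"):
            if len(rest) != 2:
                raise ModelSemanticError("delay(expr, lag) takes 2 arguments")
            return MathNode(DELAY, None,
                            (parse_mathml(rest[0]), parse_mathml(rest[1])))
        raise UnsupportedFeatureError(f"applied csymbol '{url}' not supported")

    # qualifier elements (degree, logbase) are handled by the operator
    args = [parse_mathml(a) for a in rest
            if _local(a.tag) not in ("degree", "logbase")]

    if htag in _OP_TAGS:
        return _build_operator(htag, args)
    if htag in _REL_TAGS:
        if len(args) != 2:
            raise ModelSemanticError(f"<{htag}> needs 2 operands")
        return MathNode(REL, htag, tuple(args))
    if htag in _LOGIC_TAGS:
        return _build_logic(htag, args)
    if htag == "root":
        return _build_root(head, elem, args)
    if htag == "log":
        return _build_log(elem, args)
    if htag in ("power",):
        return MathNode(OP, "^", tuple(args))
    builtin = _BUILTIN_ALIASES.get(htag, htag)
    if builtin in _UNARY_FUNCS:
        if len(args) != 1:
            raise ModelSemanticError(f"<{htag}> needs 1 argument")
        return MathNode(FUNC, builtin, tuple(args))
    raise UnsupportedFeatureError(f"unsupported MathML operator <{htag}>")


_BUILTIN_ALIASES = {"ceiling": "ceiling", "exp": "exp"}


def _build_operator(htag, args):
    sym = _OP_TAGS[htag]
    if htag == "minus":
        if len(args) == 1:
            return MathNode(OP, "neg", (args[0],))
        if len(args) == 2:
            return MathNode(OP, "-", tuple(args))
        raise ModelSemanticError("<minus> takes 1 or 2 operands")
    if htag == "divide":
        if len(args) != 2:
            raise ModelSemanticError("<divide> takes 2 operands")
        return MathNode(OP, "/", tuple(args))
    if htag == "power":
        return MathNode(OP, "^", tuple(args))
    # n-ary plus / times
    if not args:
        return MathNode.num(0.0 if htag == "plus" else 1.0)
    node = args[0]
    for a in args[1:]:
        node = MathNode(OP, sym, (node, a))
    return node


def _build_logic(htag, args):
    if htag == "not":
        if len(args) != 1:
            raise ModelSemanticError("<not> takes 1 operand")
        return MathNode(LOGIC, "not", (args[0],))
    if not args:
        return MathNode.num(1.0 if htag == "and" else 0.0)
    node = args[0]
    for a in args[1:]:
        node = MathNode(LOGIC, htag, (node, a))
    return node


def _build_root(head, apply_elem, args):
    degree = _qualifier(apply_elem, "degree")
    if degree is None:
        if len(args) != 1:
            raise ModelSemanticError("<root> without degree takes 1 operand")
        return MathNode(FUNC, "sqrt", (args[0],))
    if len(args) != 1:
        raise ModelSemanticError("<root> with degree takes 1 radicand")
    return MathNode(FUNC, "root", (degree, args[0]))


def _build_log(apply_elem, args):
    base = _qualifier(apply_elem, "logbase")
    if base is None:
        if len(args) != 1:
            raise ModelSemanticError("<log> takes 1 operand")
        return MathNode(FUNC, "log10", (args[0],))
    if len(args) != 1:
        raise ModelSemanticError("<log> with logbase takes 1 operand")
    return MathNode(FUNC, "log", (base, args[0]))


def _qualifier(apply_elem, name):
    for c in _children(apply_elem):
        if _local(c.tag) == name:
            kids = _children(c)
            if len(kids) != 1:
                raise ModelSemanticError(f"<{name}> needs one child")
            return parse_mathml(kids[0])
    return None


def parse_lambda(elem):
    """Parse a FunctionDefinition ``<lambda>``: returns (arg names, body)."""
    tag = _local(elem.tag)
    if tag == "math":
        kids = _children(elem)
        if len(kids) != 1 or _local(kids[0].tag) != "lambda":
            raise ModelSemanticError("FunctionDefinition math must be a <lambda>")
        elem = kids[0]
    args = []
    body = None
    for c in _children(elem):
        if _local(c.tag) == "bvar":
            kids = _children(c)
            if len(kids) != 1 or _local(kids[0].tag) != "ci":
                raise ModelSemanticError("<bvar> must wrap a single <ci>")
            args.append(kids[0].text.strip())
        else:
            if body is not None:
                raise ModelSemanticError("<lambda> has more than one body")
            body = parse_mathml(c)
    if body is None:
        raise ModelSemanticError("<lambda> has no body")
    return args, body


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def substitute(node: MathNode, bindings: Mapping[str, MathNode]) -> MathNode:
    """Structural substitution of identifiers; capture-free because actual
    argument ASTs are spliced in as-is (SBML lambdas have no nested binders)."""
    if node.kind == NAME and node.payload in bindings:
        return bindings[node.payload]
    if not node.children:
        return node
    new = tuple(substitute(c, bindings) for c in node.children)
    if new == node.children:
        return node
    return MathNode(node.kind, node.payload, new)


def inline_function_calls(node: MathNode, defs: Mapping[str, tuple]) -> MathNode:
    """Expand every user-function-call node to the body of its
    FunctionDefinition with formal parameters replaced by the actual
    argument expressions.  Nested/chained calls are expanded transitively;
    recursion is rejected."""
    return _inline(node, defs, ())


def _inline(node: MathNode, defs, active) -> MathNode:
    children = tuple(_inline(c, defs, active) for c in node.children)
    if node.kind != CALL:
        if children == node.children:
            return node
        return MathNode(node.kind, node.payload, children)
    fid = node.payload
    if fid in active:
        raise CycleError(active + (fid,))
    if fid not in defs:
        raise ModelSemanticError(f"call to undefined function '{fid}'")
    formals, body = defs[fid]
    if len(formals) != len(children):
        raise ModelSemanticError(
            f"function '{fid}' expects {len(formals)} argument(s), "
            f"got {len(children)}")
    expanded = substitute(body, dict(zip(formals, children)))
    # the body may itself contain calls (nested definitions)
    return _inline(expanded, defs, active + (fid,))


def _negate(cond: MathNode) -> MathNode:
    return MathNode(LOGIC, "not", (cond,))


def _conj(terms) -> MathNode:
    node = terms[0]
    for t in terms[1:]:
        node = MathNode(LOGIC, "and", (node, t))
    return node


def rewrite_piecewise(node: MathNode) -> MathNode:
    """Eliminate piecewise nodes: each branch value is multiplied by its
    guard (the branch condition AND the negation of every earlier
    condition) and the guarded terms are summed; the otherwise value is
    guarded by the conjunction of all negated conditions.  First true
    condition wins.  Without an otherwise, the sum is 0 when no condition
    holds."""
    children = tuple(rewrite_piecewise(c) for c in node.children)
    if node.kind != PIECEWISE:
        if children == node.children:
            return node
        return MathNode(node.kind, node.payload, children)

    n = len(children)
    has_otherwise = n % 2 == 1
    pairs = [(children[i], children[i + 1]) for i in range(0, n - (n % 2), 2)]
    otherwise = children[-1] if has_otherwise else None
    if not has_otherwise:
        log.warning(
            "piecewise without <otherwise>: evaluates to 0 when no condition holds")

    terms = []
    prior = []
    for value, cond in pairs:
        guard = _conj([cond] + [_negate(p) for p in prior])
        terms.append(MathNode(OP, "*", (value, guard)))
        prior.append(cond)
    if otherwise is not None:
        if prior:
            guard = _conj([_negate(p) for p in prior])
            terms.append(MathNode(OP, "*", (otherwise, guard)))
        else:
            terms.append(otherwise)
    if not terms:
        return MathNode.num(0.0)
    node = terms[0]
    for t in terms[1:]:
        node = MathNode(OP, "+", (node, t))
    return node


def normalize(node: MathNode, defs: Mapping[str, tuple] | None = None) -> MathNode:
    """Standard load-time pipeline: inline function calls, then rewrite
    piecewise."""
    return rewrite_piecewise(inline_function_calls(node, defs or {}))


# ---------------------------------------------------------------------------
# RPN compilation
# ---------------------------------------------------------------------------

# opcode -> (pop count, push count); "delay" additionally consults its operand
_STACK_EFFECT = {
    "const": (0, 1), "var": (0, 1), "time": (0, 1), "avogadro": (0, 1),
    "add": (2, 1), "sub": (2, 1), "mul": (2, 1), "div": (2, 1),
    "pow": (2, 1), "neg": (1, 1),
    "func1": (1, 1), "func2": (2, 1),
    "rel": (2, 1), "and": (2, 1), "or": (2, 1), "xor": (2, 1), "not": (1, 1),
    "delay": (1, 1),  # pops lag, pushes looked-up value of its sub-program
}

_OP_OPCODE = {"+": "add", "-": "sub", "*": "mul", "/": "div", "^": "pow"}


@dataclass
class RpnProgram:
    """A compiled stack program for one expression.

    ``instructions`` is a list of ``(opcode, operand)`` pairs evaluated
    left-to-right on an operand stack; a well-formed program never
    underflows and leaves exactly one value.
    """

    instructions: list = field(default_factory=list)
    referenced_ids: set = field(default_factory=set)
    uses_delay: bool = False
    _domain_warned: bool = field(default=False, repr=False, compare=False)

    def validate(self):
        """Static stack-balance check; raises ``ModelSemanticError`` on
        underflow or a net effect other than +1."""
        depth = 0
        for opcode, _ in self.instructions:
            pop, push = _STACK_EFFECT[opcode]
            depth -= pop
            if depth < 0:
                raise ModelSemanticError("RPN program underflows the stack")
            depth += push
        if depth != 1:
            raise ModelSemanticError(
                f"RPN program leaves {depth} values on the stack (expected 1)")
        return self


def compile_to_rpn(node: MathNode) -> RpnProgram:
    """Post-order linearization of an AST into an :class:`RpnProgram`.

    The input must already be normalized (no user-function-call or
    piecewise nodes)."""
    prog = RpnProgram()
    emit = prog.instructions.append
    # explicit stack: (node, visited-flag)
    work = [(node, False)]
    while work:
        n, visited = work.pop()
        if not visited:
            work.append((n, True))
            if n.kind == DELAY:
                # the delayed expression becomes an embedded sub-program
                # (emitted in _emit_node); only the lag is evaluated on
                # the main stack
                work.append((n.children[1], False))
            else:
                for c in reversed(n.children):
                    work.append((c, False))
        else:
            _emit_node(prog, emit, n)
    return prog.validate()


def _emit_node(prog, emit, n):
    k = n.kind
    if k == NUM:
        emit(("const", n.payload))
    elif k == NAME:
        prog.referenced_ids.add(n.payload)
        emit(("var", n.payload))
    elif k == TIME:
        emit(("time", None))
    elif k == AVOGADRO:
        emit(("avogadro", None))
    elif k == OP:
        emit((_OP_OPCODE[n.payload], None) if n.payload != "neg" else ("neg", None))
    elif k == FUNC:
        if n.payload in _BINARY_FUNCS:
            emit(("func2", n.payload))
        else:
            emit(("func1", n.payload))
    elif k == REL:
        emit(("rel", n.payload))
    elif k == LOGIC:
        emit((n.payload, None))
    elif k == DELAY:
        sub = compile_to_rpn(n.children[0])
        prog.referenced_ids |= sub.referenced_ids
        prog.uses_delay = True
        emit(("delay", sub))
    else:
        raise ModelSemanticError(
            f"cannot compile node kind '{k}' (normalize first)")


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvalContext:
    """Everything a program needs at evaluation time: the current model
    time, a mapping id -> value, and (for delay expressions) a callable
    ``delay(sub_program, lag) -> value`` that evaluates ``sub_program``
    against the recorded state at ``time - lag``."""

    time: float
    values: Mapping[str, float]
    delay: Callable[[RpnProgram, float], float] | None = None


def _fact(x):
    try:
        return float(math.gamma(x + 1.0))
    except (ValueError, OverflowError):
        return math.inf


def _guard(fn):
    def wrapped(x):
        try:
            return float(fn(x))
        except ValueError:
            return math.nan
        except OverflowError:
            return math.inf
    return wrapped


_F1 = {
    "abs": abs,
    "exp": _guard(math.exp),
    "ln": _guard(math.log),
    "log10": _guard(math.log10),
    "sqrt": _guard(math.sqrt),
    "floor": math.floor,
    "ceiling": math.ceil,
    "factorial": _fact,
    "sin": math.sin, "cos": math.cos, "tan": math.tan,
    "sec": lambda x: 1.0 / math.cos(x),
    "csc": lambda x: 1.0 / math.sin(x),
    "cot": lambda x: 1.0 / math.tan(x),
    "arcsin": _guard(math.asin), "arccos": _guard(math.acos),
    "arctan": math.atan,
    "arcsec": _guard(lambda x: math.acos(1.0 / x)),
    "arccsc": _guard(lambda x: math.asin(1.0 / x)),
    "arccot": lambda x: math.atan2(1.0, x),
    "sinh": _guard(math.sinh), "cosh": _guard(math.cosh), "tanh": math.tanh,
    "sech": lambda x: 1.0 / math.cosh(x),
    "csch": _guard(lambda x: 1.0 / math.sinh(x)),
    "coth": _guard(lambda x: math.cosh(x) / math.sinh(x)),
    "arcsinh": _guard(math.asinh), "arccosh": _guard(math.acosh),
    "arctanh": _guard(math.atanh),
    "arcsech": _guard(lambda x: math.acosh(1.0 / x)),
    "arccsch": _guard(lambda x: math.asinh(1.0 / x)),
    "arccoth": _guard(lambda x: math.atanh(1.0 / x)),
}

_REL_FN = {
    "lt": lambda a, b: a < b,
    "leq": lambda a, b: a <= b,
    "gt": lambda a, b: a > b,
    "geq": lambda a, b: a >= b,
    "eq": lambda a, b: a == b,
    "neq": lambda a, b: a != b,
}


def _pow(a, b):
    try:
        r = a ** b
        if isinstance(r, complex):
            return math.nan
        return float(r)
    except (OverflowError, ZeroDivisionError):
        return math.inf
    except ValueError:
        return math.nan


def evaluate(program: RpnProgram, ctx: EvalContext) -> float:
    """Run the stack machine; returns an IEEE-754 double.  Domain errors
    (division by zero, log of a non-positive number) yield inf/NaN and a
    single logged warning per program, never an exception."""
    stack = []
    push = stack.append
    pop = stack.pop
    values = ctx.values
    for opcode, operand in program.instructions:
        if opcode == "const":
            push(operand)
        elif opcode == "var":
            try:
                push(float(values[operand]))
            except KeyError:
                raise ModelSemanticError(
                    f"identifier '{operand}' not resolvable in context") from None
        elif opcode == "time":
            push(ctx.time)
        elif opcode == "avogadro":
            push(AVOGADRO_VALUE)
        elif opcode == "add":
            b = pop(); stack[-1] += b
        elif opcode == "sub":
            b = pop(); stack[-1] -= b
        elif opcode == "mul":
            b = pop(); stack[-1] *= b
        elif opcode == "div":
            b = pop(); a = pop()
            if b == 0.0:
                if not program._domain_warned:
                    log.warning("division by zero while evaluating expression")
                    program._domain_warned = True
                push(math.nan if (a == 0.0 or math.isnan(a))
                     else math.copysign(math.inf, a) * math.copysign(1.0, b))
            else:
                push(a / b)
        elif opcode == "pow":
            b = pop(); a = pop()
            push(_pow(a, b))
        elif opcode == "neg":
            stack[-1] = -stack[-1]
        elif opcode == "func1":
            x = pop()
            try:
                r = float(_F1[operand](x))
            except ValueError:
                r = math.nan
            except (OverflowError, ZeroDivisionError):
                r = math.inf
            if (math.isnan(r) or math.isinf(r)) and not program._domain_warned:
                log.warning("domain error in %s(%g)", operand, x)
                program._domain_warned = True
            push(r)
        elif opcode == "func2":
            b = pop(); a = pop()
            if operand == "pow":
                push(_pow(a, b))
            elif operand == "root":
                push(_pow(b, 1.0 / a) if a != 0.0 else math.nan)
            else:  # log(base, x)
                try:
                    push(math.log(b) / math.log(a))
                except (ValueError, ZeroDivisionError):
                    if not program._domain_warned:
                        log.warning("domain error in log base %g of %g", a, b)
                        program._domain_warned = True
                    push(math.nan)
        elif opcode == "rel":
            b = pop(); a = pop()
            push(1.0 if _REL_FN[operand](a, b) else 0.0)
        elif opcode == "and":
            b = pop(); a = pop()
            push(1.0 if (a != 0.0 and b != 0.0) else 0.0)
        elif opcode == "or":
            b = pop(); a = pop()
            push(1.0 if (a != 0.0 or b != 0.0) else 0.0)
        elif opcode == "xor":
            b = pop(); a = pop()
            push(1.0 if ((a != 0.0) != (b != 0.0)) else 0.0)
        elif opcode == "not":
            stack[-1] = 1.0 if stack[-1] == 0.0 else 0.0
        elif opcode == "delay":
            lag = pop()
            if ctx.delay is None:
                raise ModelSemanticError(
                    "expression uses delay() but context has no delay lookup")
            push(float(ctx.delay(operand, lag)))
        else:  # pragma: no cover - compile emits only known opcodes
            raise ModelSemanticError(f"unknown opcode '{opcode}'")
    return stack[0]


def compile_math(node: MathNode, defs=None) -> RpnProgram:
    """Normalize (inline + piecewise rewrite) and compile in one call."""
    return compile_to_rpn(normalize(node, defs))
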