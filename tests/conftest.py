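"""Shared fixtures and independent oracles for the test suite.

``recursive_eval`` is a straight tree-walk evaluator for MathNode ASTs,
written independently of the RPN compilation path so the two can be
compared exactly.  ``random_ast`` builds seeded random expression trees
over a small id set for the equivalence sweep.
"""

from __future__ import annotations

import math
import random

import pytest

from sbmlsim import load_model
from sbmlsim.fixtures import make_fixture
from sbmlsim.mathml import (
    AVOGADRO_VALUE,
    CALL,
    DELAY,
    FUNC,
    LOGIC,
    NAME,
    NUM,
    OP,
    PIECEWISE,
    REL,
    TIME,
    AVOGADRO,
    MathNode,
)

# ---------------------------------------------------------------------------
# Recursive tree-walk oracle (independent of the RPN stack machine)
# ---------------------------------------------------------------------------

_REL = {
    "lt": lambda a, b: a < b, "leq": lambda a, b: a <= b,
    "gt": lambda a, b: a > b, "geq": lambda a, b: a >= b,
    "eq": lambda a, b: a == b, "neq": lambda a, b: a != b,
}


def recursive_eval(node: MathNode, time=0.0, values=None, delay=None):
    values = values or {}

    def ev(n):
        k = n.kind
        if k == NUM:
            return n.payload
        if k == NAME:
            return float(values[n.payload])
        if k == TIME:
            return time
        if k == AVOGADRO:
            return AVOGADRO_VALUE
        if k == OP:
            if n.payload == "neg":
                return -ev(n.children[0])
            a, b = ev(n.children[0]), ev(n.children[1])
            if n.payload == "+":
                return a + b
            if n.payload == "-":
                return a - b
            if n.payload == "*":
                return a * b
            if n.payload == "/":
                if b == 0.0:
                    if a == 0.0 or math.isnan(a):
                        return math.nan
                    return math.copysign(math.inf, a) * math.copysign(1.0, b)
                return a / b
            if n.payload == "^":
                try:
                    r = a ** b
                    return math.nan if isinstance(r, complex) else float(r)
                except (OverflowError, ZeroDivisionError):
                    return math.inf
                except ValueError:
                    return math.nan
        if k == REL:
            return 1.0 if _REL[n.payload](ev(n.children[0]), ev(n.children[1])) else 0.0
        if k == LOGIC:
            if n.payload == "not":
                return 1.0 if ev(n.children[0]) == 0.0 else 0.0
            a, b = ev(n.children[0]) != 0.0, ev(n.children[1]) != 0.0
            if n.payload == "and":
                return 1.0 if (a and b) else 0.0
            if n.payload == "or":
                return 1.0 if (a or b) else 0.0
            return 1.0 if (a != b) else 0.0
        if k == FUNC:
            return _func(n, ev)
        if k == PIECEWISE:
            ch = n.children
            pairs = [(ch[i], ch[i + 1]) for i in range(0, len(ch) - len(ch) % 2, 2)]
            for value, cond in pairs:
                if ev(cond) != 0.0:
                    return ev(value)
            return ev(ch[-1]) if len(ch) % 2 == 1 else 0.0
        if k == DELAY:
            return delay(n.children[0], ev(n.children[1]))
        if k == CALL:
            raise AssertionError("oracle got an un-inlined function call")
        raise AssertionError(f"unknown kind {k}")

    return ev(node)


def _func(n, ev):
    name = n.payload
    if name in ("pow", "root", "log"):
        a, b = ev(n.children[0]), ev(n.children[1])
        try:
            if name == "pow":
                return float(a ** b)
            if name == "root":
                return float(b ** (1.0 / a)) if a != 0.0 else math.nan
            return math.log(b) / math.log(a)
        except (ValueError, ZeroDivisionError):
            return math.nan
        except OverflowError:
            return math.inf
    x = ev(n.children[0])
    table = {
        "abs": abs, "exp": math.exp, "ln": math.log, "log10": math.log10,
        "sqrt": math.sqrt, "floor": math.floor, "ceiling": math.ceil,
        "sin": math.sin, "cos": math.cos, "tan": math.tan,
        "sinh": math.sinh, "cosh": math.cosh, "tanh": math.tanh,
        "arcsin": math.asin, "arccos": math.acos, "arctan": math.atan,
        "arcsinh": math.asinh, "arccosh": math.acosh, "arctanh": math.atanh,
        "factorial": lambda v: math.gamma(v + 1.0),
    }
    try:
        return float(table[name](x))
    except ValueError:
        return math.nan
    except OverflowError:
        return math.inf


# ---------------------------------------------------------------------------
# Random AST generation
# ---------------------------------------------------------------------------

AST_IDS = ["a", "b", "c", "x"]


def random_ast(rng: random.Random, depth: int = 4, boolean=False) -> MathNode:
    """Seeded random expression tree; numeric unless ``boolean``."""
    if boolean:
        if depth <= 0 or rng.random() < 0.3:
            return MathNode(REL, rng.choice(["lt", "gt", "leq", "geq"]),
                            (random_ast(rng, 0), random_ast(rng, 0)))
        op = rng.choice(["and", "or", "xor", "not"])
        if op == "not":
            return MathNode(LOGIC, "not", (random_ast(rng, depth - 1, True),))
        return MathNode(LOGIC, op, (random_ast(rng, depth - 1, True),
                                    random_ast(rng, depth - 1, True)))
    if depth <= 0 or rng.random() < 0.25:
        if rng.random() < 0.5:
            return MathNode.num(round(rng.uniform(-5, 5), 3))
        return MathNode.name(rng.choice(AST_IDS))
    roll = rng.random()
    if roll < 0.55:
        op = rng.choice(["+", "-", "*", "/"])
        return MathNode(OP, op, (random_ast(rng, depth - 1),
                                 random_ast(rng, depth - 1)))
    if roll < 0.65:
        return MathNode(OP, "neg", (random_ast(rng, depth - 1),))
    if roll < 0.85:
        f = rng.choice(["sin", "cos", "abs", "tanh", "exp"])
        return MathNode(FUNC, f, (random_ast(rng, depth - 1),))
    # numeric value of a boolean subexpression
    return random_ast(rng, depth - 1, boolean=True)


def random_context(rng: random.Random):
    return {i: round(rng.uniform(-3, 3), 3) for i in AST_IDS}


# ---------------------------------------------------------------------------
# Model fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def decay_model():
    return load_model(make_fixture("decay", k=0.5, s0=10.0))


@pytest.fixture
def chain_model():
    return load_model(make_fixture("chain"))


@pytest.fixture
def fast_model():
    return load_model(make_fixture("fast_reaction"))


@pytest.fixture
def priority_model():
    return load_model(make_fixture("event_priority"))
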