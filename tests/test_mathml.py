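"""MathML AST parsing, transforms, RPN compilation and evaluation."""

import math
import random

import pytest
from hypothesis import assume, given, seed, settings
from hypothesis import strategies as st
from lxml import etree

from sbmlsim.errors import CycleError, ModelSemanticError
from sbmlsim.mathml import (
    CALL,
    DELAY,
    FUNC,
    LOGIC,
    NAME,
    OP,
    PIECEWISE,
    REL,
    EvalContext,
    MathNode,
    compile_to_rpn,
    evaluate,
    inline_function_calls,
    normalize,
    parse_mathml,
    rewrite_piecewise,
)

from conftest import AST_IDS, random_ast, random_context, recursive_eval

MATHML_NS = "http://www.w3.org/1998/Math/MathML"


def mml(inner):
    return etree.fromstring(f'<math xmlns="{MATHML_NS}">{inner}</math>')


def run(node, time=0.0, **values):
    return evaluate(compile_to_rpn(node), EvalContext(time=time, values=values))


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("inner, time, values, expected", [
    ("<cn> 7 </cn>", 0, {}, 7.0),
    ('<cn type="e-notation"> 15 <sep/> -2 </cn>', 0, {}, 0.15),
    ('<cn type="rational"> 3 <sep/> 4 </cn>', 0, {}, 0.75),
    ("<apply><plus/><cn>1</cn><cn>2</cn><cn>3</cn></apply>", 0, {}, 6.0),
    ("<apply><minus/><cn>5</cn></apply>", 0, {}, -5.0),
    ("<apply><power/><cn>2</cn><cn>10</cn></apply>", 0, {}, 1024.0),
    ("<apply><root/><cn>9</cn></apply>", 0, {}, 3.0),
    ("<apply><root/><degree><cn>3</cn></degree><cn>8</cn></apply>", 0, {}, 2.0),
    ("<apply><log/><cn>100</cn></apply>", 0, {}, 2.0),
    ("<apply><log/><logbase><cn>2</cn></logbase><cn>8</cn></apply>", 0, {}, 3.0),
    ("<apply><ln/><exponentiale/></apply>", 0, {}, 1.0),
    ("<apply><times/><pi/><cn>2</cn></apply>", 0, {}, 2 * math.pi),
    ("<apply><geq/><ci>x</ci><cn>2</cn></apply>", 0, {"x": 2.0}, 1.0),
    ("<apply><and/><true/><false/></apply>", 0, {}, 0.0),
    ('<csymbol encoding="text" definitionURL='
     '"http://www.sbml.org/sbml/symbols/time"> t </csymbol>', 4.5, {}, 4.5),
])
def test_parse_and_evaluate(inner, time, values, expected):
    node = parse_mathml(mml(inner))
    assert run(node, time=time, **values) == pytest.approx(expected)


def test_unsupported_csymbol_rejected():
    from sbmlsim.errors import UnsupportedFeatureError
    xml = mml('<csymbol definitionURL="http://example.org/rateOf"> r </csymbol>')
    with pytest.raises(UnsupportedFeatureError):
        parse_mathml(xml)


# ---------------------------------------------------------------------------
# FunctionDefinition inlining
# ---------------------------------------------------------------------------

def test_inline_simple_call_substitutes_arguments():
    # f(x) = x + 1 applied to 3*a  ->  (3*a) + 1
    f_body = MathNode(OP, "+", (MathNode.name("x"), MathNode.num(1)))
    call = MathNode(CALL, "f", (MathNode(OP, "*", (MathNode.num(3),
                                                   MathNode.name("a"))),))
    out = inline_function_calls(call, {"f": (["x"], f_body)})
    assert all(n.kind != CALL for n in out.walk())
    assert run(out, a=2.0) == 7.0


def test_inline_nested_definitions():
    # g(y) = f(y) * 2 with f(x) = x + 1; g(a) -> (a+1)*2
    f_body = MathNode(OP, "+", (MathNode.name("x"), MathNode.num(1)))
    g_body = MathNode(OP, "*", (MathNode(CALL, "f", (MathNode.name("y"),)),
                                MathNode.num(2)))
    call = MathNode(CALL, "g", (MathNode.name("a"),))
    defs = {"f": (["x"], f_body), "g": (["y"], g_body)}
    out = inline_function_calls(call, defs)
    assert all(n.kind != CALL for n in out.walk())
    rng = random.Random(7)
    for _ in range(20):
        a = rng.uniform(-10, 10)
        assert run(out, a=a) == pytest.approx((a + 1) * 2)


def test_inline_no_calls_is_identity():
    node = MathNode(OP, "+", (MathNode.name("a"), MathNode.num(2)))
    assert inline_function_calls(node, {}) is node


def test_inline_idempotent_after_normalize():
    f_body = MathNode(OP, "+", (MathNode.name("x"), MathNode.num(1)))
    call = MathNode(CALL, "f", (MathNode.name("a"),))
    once = normalize(call, {"f": (["x"], f_body)})
    assert inline_function_calls(once, {"f": (["x"], f_body)}) == once


def test_inline_arity_mismatch():
    f_body = MathNode.name("x")
    call = MathNode(CALL, "f", (MathNode.num(1), MathNode.num(2)))
    with pytest.raises(ModelSemanticError):
        inline_function_calls(call, {"f": (["x"], f_body)})


def test_inline_recursion_rejected():
    body = MathNode(CALL, "f", (MathNode.name("x"),))
    call = MathNode(CALL, "f", (MathNode.num(1),))
    with pytest.raises(CycleError):
        inline_function_calls(call, {"f": (["x"], body)})


# ---------------------------------------------------------------------------
# Piecewise rewriting
# ---------------------------------------------------------------------------

def _pw(*children):
    return MathNode(PIECEWISE, None, children)


def _first_match(pw_children, x):
    """Direct first-true piecewise semantics (grid oracle)."""
    n = len(pw_children)
    pairs = [(pw_children[i], pw_children[i + 1])
             for i in range(0, n - n % 2, 2)]
    for value, cond in pairs:
        if recursive_eval(cond, values={"x": x}) != 0.0:
            return recursive_eval(value, values={"x": x})
    if n % 2 == 1:
        return recursive_eval(pw_children[-1], values={"x": x})
    return 0.0


def test_single_branch_with_otherwise():
    pw = _pw(MathNode.num(5),
             MathNode(REL, "gt", (MathNode.name("x"), MathNode.num(2))),
             MathNode.num(1))
    out = rewrite_piecewise(pw)
    assert all(n.kind != PIECEWISE for n in out.walk())
    assert run(out, x=3.0) == 5.0
    assert run(out, x=0.0) == 1.0


@pytest.mark.parametrize("children", [
    # overlapping conditions: first true wins
    (MathNode.num(10), MathNode(REL, "gt", (MathNode.name("x"), MathNode.num(0))),
     MathNode.num(20), MathNode(REL, "gt", (MathNode.name("x"), MathNode.num(1))),
     MathNode.num(0)),
    # no otherwise, possibly no true branch
    (MathNode.num(3), MathNode(REL, "lt", (MathNode.name("x"), MathNode.num(-1))),
     MathNode.num(8), MathNode(REL, "gt", (MathNode.name("x"), MathNode.num(4)))),
])
def test_piecewise_matches_first_match_oracle_on_grid(children):
    out = rewrite_piecewise(_pw(*children))
    assert all(n.kind != PIECEWISE for n in out.walk())
    for x in [v / 4.0 for v in range(-20, 21)]:
        assert run(out, x=x) == _first_match(children, x)


# ---------------------------------------------------------------------------
# RPN compilation and evaluation
# ---------------------------------------------------------------------------

def test_textbook_postfix_sequence():
    # (a+b)*c -> push a, push b, add, push c, mul
    node = MathNode(OP, "*", (
        MathNode(OP, "+", (MathNode.name("a"), MathNode.name("b"))),
        MathNode.name("c")))
    prog = compile_to_rpn(node)
    assert [op for op, _ in prog.instructions] == \
        ["var", "var", "add", "var", "mul"]
    assert prog.instructions[0][1] == "a"
    assert prog.referenced_ids == {"a", "b", "c"}


def test_single_literal():
    prog = compile_to_rpn(MathNode.num(7))
    assert prog.instructions == [("const", 7.0)]


def test_precedence():
    # a + b*c = 14
    node = MathNode(OP, "+", (MathNode.name("a"),
                              MathNode(OP, "*", (MathNode.name("b"),
                                                 MathNode.name("c")))))
    assert run(node, a=2, b=3, c=4) == 14.0


def test_boolean_coercion():
    node = MathNode(LOGIC, "and", (
        MathNode(REL, "gt", (MathNode.name("x"), MathNode.num(2))),
        MathNode(REL, "lt", (MathNode.name("x"), MathNode.num(5)))))
    assert run(node, x=3) == 1.0
    assert run(node, x=7) == 0.0


def test_delay_opcode_routes_through_context():
    node = MathNode(DELAY, None, (MathNode.name("S1"), MathNode.num(1.5)))
    prog = compile_to_rpn(node)
    assert prog.uses_delay
    seen = {}

    def delay_lookup(sub, lag):
        seen["lag"] = lag
        return 42.0

    ctx = EvalContext(time=10.0, values={"S1": 1.0}, delay=delay_lookup)
    assert evaluate(prog, ctx) == 42.0
    assert seen["lag"] == 1.5


def test_division_by_zero_yields_infinity_not_exception():
    node = MathNode(OP, "/", (MathNode.num(1), MathNode.name("x")))
    assert run(node, x=0.0) == math.inf
    node = MathNode(OP, "/", (MathNode.num(0), MathNode.name("x")))
    assert math.isnan(run(node, x=0.0))


def test_log_of_nonpositive_is_nan():
    node = MathNode(FUNC, "ln", (MathNode.name("x"),))
    assert math.isnan(run(node, x=-1.0))


def test_missing_identifier_raises():
    prog = compile_to_rpn(MathNode.name("ghost"))
    with pytest.raises(ModelSemanticError):
        evaluate(prog, EvalContext(time=0, values={}))


def test_stack_balance_rejects_malformed_program():
    from sbmlsim.mathml import RpnProgram
    bad = RpnProgram(instructions=[("add", None)])
    with pytest.raises(ModelSemanticError):
        bad.validate()


# ---------------------------------------------------------------------------
# Oracle equivalence sweep
# ---------------------------------------------------------------------------

def test_rpn_equals_recursive_oracle_on_1000_random_asts():
    """Stack evaluation must agree bitwise with the independent
    tree-walk evaluator on randomized expressions up to depth 8."""
    rng = random.Random(20260922)
    checked = 0
    while checked < 1000:
        node = random_ast(rng, depth=rng.randint(1, 8))
        values = random_context(rng)
        expected = recursive_eval(node, time=0.0, values=values)
        got = evaluate(compile_to_rpn(node),
                       EvalContext(time=0.0, values=values))
        if math.isnan(expected):
            assert math.isnan(got)
        else:
            assert got == expected  # bitwise
        checked += 1


@seed(20260922)
@settings(max_examples=200, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_compiled_programs_are_stack_balanced(seed_val):
    rng = random.Random(seed_val)
    node = random_ast(rng, depth=rng.randint(1, 6))
    prog = compile_to_rpn(node)
    prog.validate()  # raises on imbalance


@seed(20260923)
@settings(max_examples=100, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_piecewise_rewrite_preserves_value(seed_val):
    rng = random.Random(seed_val)
    value_a = random_ast(rng, 2)
    value_b = random_ast(rng, 2)
    cond = random_ast(rng, 2, boolean=True)
    pw = _pw(value_a, cond, value_b)
    out = rewrite_piecewise(pw)
    values = random_context(rng)
    # guarded-off branches are multiplied by 0, which only preserves the
    # first-match value when every branch is finite
    assume(all(math.isfinite(recursive_eval(v, values=values))
               for v in (value_a, value_b)))
    expected = recursive_eval(pw, values=values)
    got = evaluate(compile_to_rpn(out), EvalContext(time=0.0, values=values))
    if math.isnan(expected):
        assert math.isnan(got)
    else:
        assert got == pytest.approx(expected, rel=1e-12, abs=1e-12)
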