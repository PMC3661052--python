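"""Stepper correctness: hand-computable steps, convergence orders,
stiff stability, adaptive error control."""

import math

import numpy as np
import pytest

from sbmlsim.integrators import (
    History,
    MethodSpec,
    step_adaptive,
    step_backward_euler,
    step_explicit_euler,
    step_multistep,
    step_rk4,
)
from sbmlsim.numerics import NewtonSettings


def decay(t, y):
    return -y


def integrate_fixed(step, f, y0, t_end, h):
    t, y = 0.0, np.array([y0])
    while t < t_end - 1e-12:
        y = step(f, t, y, min(h, t_end - t)).y
        t += h
    return y[0]


# ---------------------------------------------------------------------------
# Hand-verifiable single steps
# ---------------------------------------------------------------------------

def test_euler_single_step():
    r = step_explicit_euler(decay, 0.0, np.array([1.0]), 0.1)
    assert r.y[0] == pytest.approx(0.9)


def test_euler_zero_derivative():
    r = step_explicit_euler(lambda t, y: 0.0 * y, 0.0, np.array([3.0]), 0.5)
    assert r.y[0] == 3.0


def test_backward_euler_linear_solve():
    # y' = -y: implicit update y1 = y0 / (1 + h)
    r = step_backward_euler(decay, 0.0, np.array([1.0]), 0.1)
    assert r.y[0] == pytest.approx(1.0 / 1.1, abs=1e-9)


def test_backward_vs_forward_euler_on_stiff_problem():
    stiff = lambda t, y: -1000.0 * y
    imp = step_backward_euler(stiff, 0.0, np.array([1.0]), 0.1)
    assert imp.y[0] == pytest.approx(1.0 / 101.0, abs=1e-6)
    exp = step_explicit_euler(stiff, 0.0, np.array([1.0]), 0.1)
    assert exp.y[0] == pytest.approx(-99.0)  # wild overshoot


def test_rk4_single_step_accuracy():
    r = step_rk4(decay, 0.0, np.array([1.0]), 0.1)
    assert r.y[0] == pytest.approx(0.90483750, abs=1e-8)
    assert abs(r.y[0] - math.exp(-0.1)) < 1e-7


def test_rk4_exact_for_constant_derivative():
    c = 2.5
    r = step_rk4(lambda t, y: np.array([c]), 0.0, np.array([1.0]), 0.2)
    assert r.y[0] == 1.0 + c * 0.2


# ---------------------------------------------------------------------------
# Convergence orders on y' = -y over [0, 1]
# ---------------------------------------------------------------------------

def _empirical_order(step, h=0.05):
    exact = math.exp(-1.0)
    e1 = abs(integrate_fixed(step, decay, 1.0, 1.0, h) - exact)
    e2 = abs(integrate_fixed(step, decay, 1.0, 1.0, h / 2) - exact)
    return math.log2(e1 / e2)


def _ab2_integrate(h):
    hist = History()
    t, y = 0.0, np.array([1.0])
    hist.push(t, y, decay(t, y))
    n = round(1.0 / h)
    for i in range(n):
        if len(hist) < 2:
            y = step_rk4(decay, t, y, h).y
        else:
            y = step_multistep(decay, hist, h, "adams_bashforth", 2).y
        t = (i + 1) * h
        hist.push(t, y, decay(t, y))
    return y[0]


@pytest.mark.parametrize("name, order, runner", [
    ("euler", 1, lambda h: integrate_fixed(step_explicit_euler, decay, 1.0, 1.0, h)),
    ("rk4", 4, lambda h: integrate_fixed(step_rk4, decay, 1.0, 1.0, h)),
    ("backward_euler", 1, lambda h: integrate_fixed(
        step_backward_euler, decay, 1.0, 1.0, h)),
    ("ab2", 2, _ab2_integrate),
])
def test_convergence_order(name, order, runner):
    exact = math.exp(-1.0)
    h = 0.05
    e1 = abs(runner(h) - exact)
    e2 = abs(runner(h / 2) - exact)
    measured = math.log2(e1 / e2)
    assert measured == pytest.approx(order, rel=0.3), name


def test_halving_h_halves_euler_global_error():
    exact = math.exp(-1.0)
    e1 = abs(integrate_fixed(step_explicit_euler, decay, 1.0, 1.0, 0.1) - exact)
    e2 = abs(integrate_fixed(step_explicit_euler, decay, 1.0, 1.0, 0.05) - exact)
    assert e1 / e2 == pytest.approx(2.0, rel=0.1)


def test_halving_h_cuts_rk4_error_16x():
    exact = math.exp(-1.0)
    e1 = abs(integrate_fixed(step_rk4, decay, 1.0, 1.0, 0.1) - exact)
    e2 = abs(integrate_fixed(step_rk4, decay, 1.0, 1.0, 0.05) - exact)
    assert e1 / e2 == pytest.approx(16.0, rel=0.3)


# ---------------------------------------------------------------------------
# Multistep specifics
# ---------------------------------------------------------------------------

def test_ab2_matches_hand_coefficients():
    # y_{n+1} = y_n + h (1.5 f_n - 0.5 f_{n-1})
    h = 0.1
    hist = History()
    y0, y1 = np.array([1.0]), np.array([0.9048374180359595])  # e^{-0.1}
    hist.push(0.0, y0, decay(0.0, y0))
    hist.push(h, y1, decay(h, y1))
    r = step_multistep(decay, hist, h, "adams_bashforth", 2)
    expected = y1[0] + h * (1.5 * -y1[0] - 0.5 * -y0[0])
    assert r.y[0] == pytest.approx(expected, abs=1e-15)
    assert abs(r.y[0] - math.exp(-0.2)) < 5e-4  # O(h^2) local behavior


def test_gear1_is_backward_euler_bitwise():
    h = 0.07
    hist = History()
    y = np.array([1.3])
    hist.push(0.0, y, decay(0.0, y))
    s = NewtonSettings()
    g = step_multistep(decay, hist, h, "gear", 1, s)
    b = step_backward_euler(decay, 0.0, y, h, s)
    assert g.y[0] == b.y[0]  # identical Newton problem, identical result


def test_am2_matches_trapezoid_closed_form():
    # trapezoid on y' = -y: y1 = y0 (1 - h/2) / (1 + h/2)
    h = 0.1
    hist = History()
    y = np.array([1.0])
    hist.push(0.0, y, decay(0.0, y))
    r = step_multistep(decay, hist, h, "adams_moulton", 2,
                       NewtonSettings(tolerance=1e-13))
    assert r.y[0] == pytest.approx((1 - h / 2) / (1 + h / 2), abs=1e-10)


def test_multistep_requires_history():
    with pytest.raises(RuntimeError):
        step_multistep(decay, History(), 0.1, "adams_bashforth", 2)


# ---------------------------------------------------------------------------
# Stiff stability probe
# ---------------------------------------------------------------------------

def test_a_stability_on_fast_decay():
    """On y' = -1000 y at h = 0.1, backward Euler and Gear-2 shrink |y|
    every step while explicit Euler diverges."""
    stiff = lambda t, y: -1000.0 * y
    h = 0.1

    y = np.array([1.0])
    for _ in range(6):
        y2 = step_backward_euler(stiff, 0.0, y, h).y
        assert abs(y2[0]) < abs(y[0])
        y = y2

    hist = History()
    y = np.array([1.0])
    hist.push(0.0, y, stiff(0.0, y))
    y = step_backward_euler(stiff, 0.0, y, h).y  # A-stable startup
    hist.push(h, y, stiff(h, y))
    prev = abs(y[0])
    for i in range(2, 7):
        y = step_multistep(stiff, hist, h, "gear", 2).y
        assert abs(y[0]) < prev
        prev = abs(y[0])
        hist.push(i * h, y, stiff(i * h, y))

    y = np.array([1.0])
    for _ in range(10):
        y = step_explicit_euler(stiff, 0.0, y, h).y
    assert abs(y[0]) > 1e10  # divergence is the expected behavior


# ---------------------------------------------------------------------------
# Adaptive methods
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("method", ["rkf45", "cash_karp"])
def test_adaptive_accuracy_and_step_growth(method):
    atol = rtol = 1e-8
    t, y, h = 0.0, np.array([1.0]), 1e-3
    steps = 0
    sizes = []
    while t < 1.0 - 1e-12:
        h = min(h, 1.0 - t)
        r = step_adaptive(decay, t, y, h, method, atol, rtol)
        steps += 1
        if r.accepted:
            sizes.append(h)
            t += h
            y = r.y
        h = min(r.h_next, 1.0 - t) if t < 1.0 else r.h_next
    assert abs(y[0] - math.exp(-1.0)) < 1e-7
    assert steps < 10_000  # far fewer evaluations than fixed h = 1e-4
    # smooth problem: step sizes grow from the cautious start until the
    # controller cap / end-of-interval clamp takes over
    assert sizes[1] > sizes[0]
    assert sizes[2] >= sizes[1]


def test_error_at_tolerance_boundary_is_accepted():
    r = step_adaptive(decay, 0.0, np.array([1.0]), 1e-6, "rkf45", 1e-9, 1e-6)
    assert r.error_estimate <= 1.0
    assert r.accepted


def test_method_spec_validates_order():
    with pytest.raises(ValueError):
        MethodSpec(family="gear", order=5)
    with pytest.raises(ValueError):
        MethodSpec(family="nope")
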