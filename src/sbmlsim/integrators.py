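"""Numerical integration steppers, written from scratch.

Fixed-step: explicit Euler, classical RK4, Adams-Bashforth (orders 1-4);
implicit backward Euler, Adams-Moulton (orders 1-4, order 1 being
backward Euler and order 2 the trapezoid rule) and Gear/BDF (orders 1-4).
Adaptive: the embedded Runge-Kutta-Fehlberg 4(5) and Cash-Karp 4(5)
pairs with the conventional step controller (safety 0.9, growth capped
at 5x, shrinkage floored at 0.1x).

Biochemical networks mix reactions on widely separated time scales, so a
step y_{n+1} = y_n + h f(t_n, y_n) (explicit Euler) can be unstable at
any practical h; the implicit methods instead solve
y_{n+1} - y_n - h f(t_{n+1}, y_{n+1}) = 0 with the Newton machinery in
:mod:`sbmlsim.numerics`, trading function solves for A-stability.

Implicit and multistep methods need previous derivative values; the
caller maintains the history and must restart it (via RK4) whenever an
event assignment or fast-reaction equilibration moves the state
discontinuously, since multistep formulas assume a smooth trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import StepError
from .numerics import NewtonSettings, newton_solve

EXPLICIT_FAMILIES = ("euler", "rk4", "adams_bashforth")
IMPLICIT_FAMILIES = ("backward_euler", "adams_moulton", "gear")
ADAPTIVE_FAMILIES = ("rkf45", "cash_karp")
ALL_FAMILIES = EXPLICIT_FAMILIES + IMPLICIT_FAMILIES + ADAPTIVE_FAMILIES


@dataclass
class MethodSpec:
    """Which stepper to use and with what knobs."""

    family: str = "rk4"
    order: int = 2            # multistep/Gear only, 1..4
    atol: float = 1e-9        # adaptive only
    rtol: float = 1e-6        # adaptive only

    def __post_init__(self):
        if self.family not in ALL_FAMILIES:
            raise ValueError(f"unknown method family '{self.family}'")
        if self.family in ("adams_bashforth", "adams_moulton", "gear"):
            if not 1 <= self.order <= 4:
                raise ValueError(
                    f"{self.family} supports orders 1-4, got {self.order}")

    @property
    def is_implicit(self) -> bool:
        return self.family in IMPLICIT_FAMILIES

    @property
    def is_adaptive(self) -> bool:
        return self.family in ADAPTIVE_FAMILIES

    @property
    def is_multistep(self) -> bool:
        return self.family in ("adams_bashforth", "adams_moulton", "gear")

    @property
    def history_needed(self) -> int:
        """(t, y, f) records required, including the current point.

        Adams-Bashforth order k combines f at the k most recent points;
        Adams-Moulton order k uses f_{n+1} implicitly plus k-1 recorded
        values (so the trapezoid rule starts from a single point); Gear
        order k combines the k most recent states."""
        if self.family == "adams_moulton":
            return max(1, self.order - 1)
        if self.family in ("adams_bashforth", "gear"):
            return self.order
        return 0


@dataclass
class StepResult:
    y: np.ndarray
    accepted: bool = True
    error_estimate: float | None = None   # max scaled component (adaptive)
    h_next: float | None = None           # suggested next step (adaptive)
    f_new: np.ndarray | None = None       # derivative at the new point, if known


def _check_finite(v, what):
    if not np.all(np.isfinite(v)):
        raise StepError(f"non-finite {what} during integration step")


# ---------------------------------------------------------------------------
# One-step methods
# ---------------------------------------------------------------------------

def step_explicit_euler(f, t, y, h) -> StepResult:
    """y_{n+1} = y_n + h f(t_n, y_n)."""
    k = np.asarray(f(t, y))
    _check_finite(k, "derivative")
    return StepResult(y=y + h * k)


def step_rk4(f, t, y, h) -> StepResult:
    """Classical four-stage fourth-order Runge-Kutta."""
    k1 = np.asarray(f(t, y))
    k2 = np.asarray(f(t + h / 2, y + h / 2 * k1))
    k3 = np.asarray(f(t + h / 2, y + h / 2 * k2))
    k4 = np.asarray(f(t + h, y + h * k3))
    _check_finite(k4, "derivative")
    return StepResult(y=y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4))


def step_backward_euler(f, t, y, h, newton: NewtonSettings | None = None) -> StepResult:
    """Solve y_{n+1} - y_n - h f(t+h, y_{n+1}) = 0, seeded at y_n."""
    newton = newton or NewtonSettings()
    y = np.asarray(y, dtype=float)

    def residual(z):
        return z - y - h * np.asarray(f(t + h, z))

    z = newton_solve(residual, y, newton)
    return StepResult(y=z)


# ---------------------------------------------------------------------------
# Embedded adaptive pairs
# ---------------------------------------------------------------------------

# Fehlberg 4(5): (c, a-rows, b4, b5)
_RKF45 = {
    "c": [0.0, 1 / 4, 3 / 8, 12 / 13, 1.0, 1 / 2],
    "a": [
        [],
        [1 / 4],
        [3 / 32, 9 / 32],
        [1932 / 2197, -7200 / 2197, 7296 / 2197],
        [439 / 216, -8.0, 3680 / 513, -845 / 4104],
        [-8 / 27, 2.0, -3544 / 2565, 1859 / 4104, -11 / 40],
    ],
    "b_low": [25 / 216, 0.0, 1408 / 2565, 2197 / 4104, -1 / 5, 0.0],
    "b_high": [16 / 135, 0.0, 6656 / 12825, 28561 / 56430, -9 / 50, 2 / 55],
}

# Cash-Karp 4(5)
_CASH_KARP = {
    "c": [0.0, 1 / 5, 3 / 10, 3 / 5, 1.0, 7 / 8],
    "a": [
        [],
        [1 / 5],
        [3 / 40, 9 / 40],
        [3 / 10, -9 / 10, 6 / 5],
        [-11 / 54, 5 / 2, -70 / 27, 35 / 27],
        [1631 / 55296, 175 / 512, 575 / 13824, 44275 / 110592, 253 / 4096],
    ],
    "b_low": [2825 / 27648, 0.0, 18575 / 48384, 13525 / 55296, 277 / 14336, 1 / 4],
    "b_high": [37 / 378, 0.0, 250 / 621, 125 / 594, 0.0, 512 / 1771],
}

_TABLEAUX = {"rkf45": _RKF45, "cash_karp": _CASH_KARP}

_SAFETY = 0.9
_GROW_CAP = 5.0
_SHRINK_FLOOR = 0.1


def step_adaptive(f, t, y, h, method="rkf45", atol=1e-9, rtol=1e-6) -> StepResult:
    """One embedded 4(5) attempt.  The error estimate is
    max_i |y5_i - y4_i| / (atol + rtol |y_i|); the step is accepted when
    it is <= 1 and the suggested next step is
    h * min(5, max(0.1, 0.9 error^(-1/5)))."""
    tab = _TABLEAUX[method]
    y = np.asarray(y, dtype=float)
    ks = []
    for i, (ci, row) in enumerate(zip(tab["c"], tab["a"])):
        yi = y.copy()
        for aij, kj in zip(row, ks):
            yi += h * aij * kj
        ks.append(np.asarray(f(t + ci * h, yi)))
    _check_finite(ks[-1], "derivative")
    y_low = y + h * sum(b * k for b, k in zip(tab["b_low"], ks))
    y_high = y + h * sum(b * k for b, k in zip(tab["b_high"], ks))
    scale = atol + rtol * np.abs(y)
    diff = np.abs(y_high - y_low)
    err = float(np.max(diff / scale)) if y.size else 0.0
    accepted = err <= 1.0
    if err == 0.0:
        factor = _GROW_CAP
    else:
        factor = min(_GROW_CAP, max(_SHRINK_FLOOR, _SAFETY * err ** -0.2))
    return StepResult(y=y_high, accepted=accepted,
                      error_estimate=err, h_next=h * factor)


# ---------------------------------------------------------------------------
# Multistep methods
# ---------------------------------------------------------------------------

# Adams-Bashforth: y_{n+1} = y_n + h sum b_j f_{n-j}
_AB = {
    1: [1.0],
    2: [3 / 2, -1 / 2],
    3: [23 / 12, -16 / 12, 5 / 12],
    4: [55 / 24, -59 / 24, 37 / 24, -9 / 24],
}

# Adams-Moulton: y_{n+1} = y_n + h (b_imp f_{n+1} + sum b_j f_{n-j})
_AM = {
    1: (1.0, []),                                   # backward Euler
    2: (1 / 2, [1 / 2]),                            # trapezoid
    3: (5 / 12, [8 / 12, -1 / 12]),
    4: (9 / 24, [19 / 24, -5 / 24, 1 / 24]),
}

# Gear/BDF: y_{n+1} = sum a_j y_{n-j} + h b f_{n+1}
_GEAR = {
    1: ([1.0], 1.0),
    2: ([4 / 3, -1 / 3], 2 / 3),
    3: ([18 / 11, -9 / 11, 2 / 11], 6 / 11),
    4: ([48 / 25, -36 / 25, 16 / 25, -3 / 25], 12 / 25),
}


@dataclass
class History:
    """Most-recent-first record of (t, y, f) at accepted uniform steps."""

    points: list = field(default_factory=list)  # [(t, y, f)] newest first
    max_len: int = 5

    def push(self, t, y, f):
        self.points.insert(0, (t, np.asarray(y, dtype=float),
                               np.asarray(f, dtype=float)))
        del self.points[self.max_len:]

    def clear(self):
        self.points.clear()

    def __len__(self):
        return len(self.points)


def step_multistep(f, history: History, h, method="adams_bashforth",
                   order=2, newton: NewtonSettings | None = None) -> StepResult:
    """Advance one step with a fixed-coefficient multistep formula.

    ``history`` must hold enough points at uniform spacing ``h``, newest
    first (history[0] is the current point): ``order`` of them for
    Adams-Bashforth and Gear, ``order - 1`` (at least one) for
    Adams-Moulton.  The implicit variants solve the corrector with
    Newton, seeded at the current state.
    """
    needed = max(1, order - 1) if method == "adams_moulton" else order
    if len(history) < needed:
        raise RuntimeError(
            f"{method} order {order} needs {needed} history points, "
            f"have {len(history)}")
    t0, y0, f0 = history.points[0]

    if method == "adams_bashforth":
        coeffs = _AB[order]
        y = y0.copy()
        for bj, (_, _, fj) in zip(coeffs, history.points):
            y += h * bj * fj
        _check_finite(y, "state")
        return StepResult(y=y)

    newton = newton or NewtonSettings()

    if method == "adams_moulton":
        b_imp, b_exp = _AM[order]
        expl = y0.copy()
        for bj, (_, _, fj) in zip(b_exp, history.points):
            expl += h * bj * fj

        def residual(z):
            return z - expl - h * b_imp * np.asarray(f(t0 + h, z))

        return StepResult(y=newton_solve(residual, y0, newton))

    if method == "gear":
        a, b = _GEAR[order]
        base = np.zeros_like(y0)
        for aj, (_, yj, _) in zip(a, history.points):
            base += aj * yj

        def residual(z):
            return z - base - h * b * np.asarray(f(t0 + h, z))

        return StepResult(y=newton_solve(residual, y0, newton))

    raise ValueError(f"unknown multistep method '{method}'")
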