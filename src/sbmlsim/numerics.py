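"""Dense linear algebra and root finding written from scratch.

Implicit integrators, AlgebraicRule constraints and fast-reaction
equilibration all reduce to solving a small square nonlinear system
F(x) = 0.  This module provides the whole chain: LU decomposition with
partial pivoting, triangular solves (forward elimination / backward
substitution), a forward-difference Jacobian, and plain k-dimensional
Newton iteration x <- x - J^{-1} F(x).

numpy arrays are used as containers only; every algorithm is explicit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConvergenceError, SingularMatrixError

_PIVOT_MIN = 1e-14


@dataclass
class NewtonSettings:
    """Knobs for Newton iteration.

    tolerance: infinity-norm residual threshold for convergence.
    max_iterations: hard cap on Newton steps.
    jacobian_epsilon: base finite-difference step; the per-component step
      is ``jacobian_epsilon * max(|x_j|, 1)``.
    """

    tolerance: float = 1e-10
    max_iterations: int = 100
    jacobian_epsilon: float = float(np.sqrt(np.finfo(float).eps))

    def __post_init__(self):
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


def lu_decompose(A):
    """Factor P A = L U with unit-diagonal L and partial pivoting.

    Returns ``(lu, perm)`` where ``lu`` stores L below and U on/above the
    diagonal in one k x k array and ``perm[i]`` is the original row index
    now in row i.  Raises :class:`SingularMatrixError` when the best
    available pivot is below 1e-14 in magnitude.
    """
    lu = np.array(A, dtype=float, copy=True)
    k = lu.shape[0]
    if lu.shape != (k, k):
        raise ValueError("matrix must be square")
    perm = list(range(k))
    for col in range(k):
        # pick the largest magnitude in this column at/below the diagonal
        p = col
        best = abs(lu[col, col])
        for r in range(col + 1, k):
            m = abs(lu[r, col])
            if m > best:
                best = m
                p = r
        if best < _PIVOT_MIN:
            raise SingularMatrixError(
                f"pivot {best:.3e} below threshold at column {col}")
        if p != col:
            lu[[col, p]] = lu[[p, col]]
            perm[col], perm[p] = perm[p], perm[col]
        pivot = lu[col, col]
        for r in range(col + 1, k):
            factor = lu[r, col] / pivot
            lu[r, col] = factor
            for c in range(col + 1, k):
                lu[r, c] -= factor * lu[col, c]
    return lu, perm


def lu_solve(lu, perm, b):
    """Solve A x = b given the factorization from :func:`lu_decompose`."""
    k = lu.shape[0]
    b = np.asarray(b, dtype=float)
    x = np.empty(k)
    # forward elimination: L y = P b
    for i in range(k):
        s = b[perm[i]]
        for j in range(i):
            s -= lu[i, j] * x[j]
        x[i] = s
    # backward substitution: U x = y
    for i in range(k - 1, -1, -1):
        s = x[i]
        for j in range(i + 1, k):
            s -= lu[i, j] * x[j]
        x[i] = s / lu[i, i]
    return x


def solve_linear(A, b):
    """Convenience: one-shot A x = b via LU."""
    lu, perm = lu_decompose(A)
    return lu_solve(lu, perm, b)


def numerical_jacobian(F, x, settings: NewtonSettings | None = None):
    """Forward-difference Jacobian J[i][j] = (F_i(x + eps_j e_j) - F_i(x)) / eps_j."""
    settings = settings or NewtonSettings()
    x = np.asarray(x, dtype=float)
    f0 = np.asarray(F(x), dtype=float)
    if not np.all(np.isfinite(f0)):
        bad = int(np.flatnonzero(~np.isfinite(f0))[0])
        raise ValueError(f"F returned a non-finite value at component {bad}")
    k = x.size
    J = np.empty((f0.size, k))
    for j in range(k):
        eps = settings.jacobian_epsilon * max(abs(x[j]), 1.0)
        xp = x.copy()
        xp[j] += eps
        fj = np.asarray(F(xp), dtype=float)
        if not np.all(np.isfinite(fj)):
            bad = int(np.flatnonzero(~np.isfinite(fj))[0])
            raise ValueError(
                f"F returned a non-finite value at component {bad} "
                f"while perturbing x[{j}]")
        J[:, j] = (fj - f0) / eps
    return J


def newton_solve(F, x0, settings: NewtonSettings | None = None):
    """Plain Newton iteration for square F(x) = 0, seeded at ``x0``.

    No damping or line search: non-convergence raises
    :class:`ConvergenceError` carrying the last residual, leaving the
    caller (typically an implicit integrator) free to retry with a
    smaller step.
    """
    settings = settings or NewtonSettings()
    x = np.array(x0, dtype=float, copy=True)
    residual = None
    for it in range(settings.max_iterations):
        f = np.asarray(F(x), dtype=float)
        if f.size != x.size:
            raise ValueError("newton_solve requires a square system")
        residual = float(np.max(np.abs(f))) if f.size else 0.0
        if residual < settings.tolerance:
            return x
        J = numerical_jacobian(F, x, settings)
        lu, perm = lu_decompose(J)
        x -= lu_solve(lu, perm, f)
    # final check after the last update
    f = np.asarray(F(x), dtype=float)
    residual = float(np.max(np.abs(f))) if f.size else 0.0
    if residual < settings.tolerance:
        return x
    raise ConvergenceError(
        f"Newton failed to converge in {settings.max_iterations} iterations "
        f"(residual {residual:.3e})",
        residual=residual, iterations=settings.max_iterations)


def left_null_space(N, tol=1e-10):
    """Basis (rows) for {y : y^T N = 0} via Gauss-Jordan on N^T.

    Used to derive conservation relations from a stoichiometric matrix.
    Returned vectors are the standard free-variable basis of the null
    space of N^T.
    """
    M = np.array(N, dtype=float, copy=True).T
    rows, cols = M.shape
    pivots = []
    r = 0
    for c in range(cols):
        # find pivot
        p = None
        best = tol
        for rr in range(r, rows):
            if abs(M[rr, c]) > best:
                best = abs(M[rr, c])
                p = rr
        if p is None:
            continue
        M[[r, p]] = M[[p, r]]
        M[r] /= M[r, c]
        for rr in range(rows):
            if rr != r and M[rr, c] != 0.0:
                M[rr] -= M[rr, c] * M[r]
        pivots.append(c)
        r += 1
        if r == rows:
            break
    free = [c for c in range(cols) if c not in pivots]
    basis = []
    for fc in free:
        v = np.zeros(cols)
        v[fc] = 1.0
        for i, pc in enumerate(pivots):
            v[pc] = -M[i, fc]
        basis.append(v)
    return basis
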