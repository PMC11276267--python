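"""Exact vertex enumeration for polytopes given by equalities and x >= 0.

The feasible sets that arise here are bounded polytopes of the form
``{x >= 0 : A x = b}``.  The enumeration proceeds by

1. eliminating the equality constraints (particular solution via an LP
   feasibility solve, null-space basis via SVD),
2. detecting *implicit* equalities among the remaining inequalities (an
   inequality whose slack cannot be made positive anywhere on the feasible
   set) and recursing on the corresponding affine subspace, and
3. enumerating the vertices of the resulting full-dimensional polytope with
   Qhull (``scipy.spatial.HalfspaceIntersection``) seeded at a Chebyshev
   center found by linear programming.

Degenerate low dimensions (a point, a segment) are handled directly.  The
reduced dimension is guarded: vertex counts can grow exponentially, so the
caller sets a ceiling on the dimension after equality elimination.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import null_space
from scipy.optimize import linprog
from scipy.spatial import HalfspaceIntersection, QhullError

from .errors import NumericalError, ValidationError

__all__ = ["enumerate_vertices", "DimensionGuardError"]

_SLACK_TOL = 1e-9


class DimensionGuardError(ValidationError):
    """The reduced polytope dimension exceeds the enumeration guard."""


def _lp(c, A_ub=None, b_ub=None, A_eq=None, b_eq=None, bounds=(None, None)):
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                  bounds=bounds, method="highs")
    if res.status != 0:
        raise NumericalError(f"LP failed (status {res.status}): {res.message}")
    return res


def enumerate_vertices(A_eq: np.ndarray, b_eq: np.ndarray, n_vars: int,
                       max_reduced_dim: int = 24) -> np.ndarray:
    """All vertices of ``{x >= 0 : A_eq x = b_eq}`` as an ``(n_v, n_vars)`` array."""
    A_eq = np.asarray(A_eq, float)
    b_eq = np.asarray(b_eq, float)
    x0 = _lp(np.zeros(n_vars), A_eq=A_eq, b_eq=b_eq, bounds=(0, None)).x
    N = null_space(A_eq)
    k = N.shape[1]
    if k > max_reduced_dim:
        raise DimensionGuardError(
            f"reduced polytope dimension {k} exceeds the guard "
            f"({max_reduced_dim}); for larger systems use the iterative "
            f"bottleneck solver at small beta instead of exact enumeration"
        )
    if k == 0:
        return x0[None, :]
    # x = x0 + N u >= 0   <=>   (-N) u <= x0
    V = _halfspace_vertices(-N, x0.copy())
    X = x0[None, :] + V @ N.T
    return _dedupe(np.clip(X, 0.0, None))


def _halfspace_vertices(A: np.ndarray, b: np.ndarray, depth: int = 0) -> np.ndarray:
    """Vertices of the bounded polytope ``{u : A u <= b}``."""
    if depth > 8:
        raise NumericalError("implicit-equality reduction did not terminate")
    k = A.shape[1]
    # drop duplicate rows for Qhull's benefit
    norms = np.linalg.norm(A, axis=1)
    keep = norms > 1e-14
    A, b, norms = A[keep], b[keep], norms[keep]
    scaled = np.column_stack([A / norms[:, None], b / norms])
    _, idx = np.unique(np.round(scaled, 12), axis=0, return_index=True)
    A, b, norms = A[sorted(idx)], b[sorted(idx)], norms[sorted(idx)]

    eq_rows = [i for i in range(A.shape[0])
               if b[i] - _lp(A[i], A_ub=A, b_ub=b).fun < _SLACK_TOL]
    if eq_rows:
        E, d = A[eq_rows], b[eq_rows]
        u0 = np.linalg.lstsq(E, d, rcond=None)[0]
        N = null_space(E)
        if N.shape[1] == 0:
            return u0[None, :]
        rest = [i for i in range(A.shape[0]) if i not in set(eq_rows)]
        sub = _halfspace_vertices(A[rest] @ N, b[rest] - A[rest] @ u0, depth + 1)
        return u0[None, :] + sub @ N.T
    if k == 1:
        lo = _lp(np.ones(1), A_ub=A, b_ub=b).x
        hi = _lp(-np.ones(1), A_ub=A, b_ub=b).x
        return np.vstack([lo, hi])
    # Chebyshev center as a strictly interior seed for Qhull
    c = np.zeros(k + 1)
    c[-1] = -1.0
    res = _lp(c, A_ub=np.column_stack([A, norms]), b_ub=b,
              bounds=[(None, None)] * k + [(0, None)])
    center, radius = res.x[:k], res.x[-1]
    if radius <= 10 * _SLACK_TOL:
        raise NumericalError(f"degenerate interior (Chebyshev radius {radius:.2e})")
    halfspaces = np.column_stack([A, -b])
    try:
        hs = HalfspaceIntersection(halfspaces, center)
    except QhullError:
        hs = HalfspaceIntersection(halfspaces, center, qhull_options="QJ")
    pts = hs.intersections
    return pts[np.all(np.isfinite(pts), axis=1)]


def _dedupe(X: np.ndarray, decimals: int = 9) -> np.ndarray:
    _, idx = np.unique(np.round(X, decimals), axis=0, return_index=True)
    return X[sorted(idx)]
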