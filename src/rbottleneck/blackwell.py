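"""Exact Blackwell redundancy, the Blackwell order, and channel deficiency.

Blackwell redundancy is the largest mutual information ``I(Q; Y)`` carried by
a random variable ``Q`` that is a garbling of *every* source: for each source
``s`` there must exist a post-processing channel ``kappa_s`` with
``q_{Q|Y} = kappa_s ∘ p_{X_s|Y}``.  For fixed bottleneck cardinality the
feasible garblings form a polytope (row-stochasticity and the agreement
constraints are linear, entries are nonnegative) and ``I(Q; Y)`` is convex in
the channel, so the maximum sits at a vertex — enumerating all vertices and
keeping the best is exact.  A cardinality of ``sum_s |X_s| - n + 1`` suffices.

Deficiency quantifies *how far* one channel is from being a garbling of
another: the minimum target-weighted KL divergence between any garbled
version of ``c`` and the channel ``b``.  It vanishes exactly when
``b`` is Blackwell-below ``c``, and lower-bounds the per-source compression
leak of any bottleneck variable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

from .discrete import Channel, DiscreteDistribution, SourceSystem
from .errors import NumericalError, ValidationError
from .polytope import enumerate_vertices

__all__ = [
    "BlackwellPolytope",
    "BlackwellResult",
    "build_blackwell_polytope",
    "blackwell_redundancy_exact",
    "is_blackwell_leq",
    "deficiency",
]

LN2 = np.log(2.0)


@dataclass(frozen=True, eq=False)
class BlackwellPolytope:
    """Halfspace description of the joint garbling polytope.

    Variables are the entries of the per-source garblings ``kappa_s`` (input
    alphabet X_s, output alphabet Q), flattened source by source.  Equalities
    are row-stochasticity of each ``kappa_s`` plus the agreement constraints
    ``kappa_1 ∘ p_{X_1|Y} = kappa_s ∘ p_{X_s|Y}``; the inequalities are
    ``kappa >= 0``.  The polytope is never empty: constant garblings (every
    row equal) always satisfy the constraints.
    """

    A_eq: np.ndarray
    b_eq: np.ndarray
    n_vars: int
    n_q: int
    offsets: tuple[int, ...]
    x_cards: tuple[int, ...]


@dataclass(frozen=True, eq=False)
class BlackwellResult:
    """Exact redundancy with its witness channel and enumeration diagnostics."""

    redundancy: float
    channel: Channel
    vertex_values: np.ndarray
    n_vertices: int

    def __iter__(self):  # allow `value, channel = result`
        return iter((self.redundancy, self.channel))


def build_blackwell_polytope(system: SourceSystem, n_q: int) -> BlackwellPolytope:
    channels = system.channels
    ny = len(system.p_y)
    x_cards = tuple(len(ch.output_outcomes) for ch in channels)
    offsets = tuple(int(o) for o in np.cumsum([0] + [nx * n_q for nx in x_cards]))
    n_vars = offsets[-1]
    rows, rhs = [], []
    for s, nx in enumerate(x_cards):
        for x in range(nx):
            row = np.zeros(n_vars)
            row[offsets[s] + x * n_q: offsets[s] + (x + 1) * n_q] = 1.0
            rows.append(row)
            rhs.append(1.0)
    p1 = channels[0].probs
    for s in range(1, len(channels)):
        ps = channels[s].probs
        for y in range(ny):
            for q in range(n_q):
                row = np.zeros(n_vars)
                row[offsets[0] + q: offsets[1]: n_q] += p1[y]
                row[offsets[s] + q: offsets[s + 1]: n_q] -= ps[y]
                rows.append(row)
                rhs.append(0.0)
    return BlackwellPolytope(np.array(rows), np.array(rhs), n_vars, n_q,
                             offsets, x_cards)


def _mi_target_channel(p_y: np.ndarray, q_probs: np.ndarray) -> float:
    """I(Q;Y) in bits for channel table p(q|y) under target marginal p_y."""
    pq = p_y @ q_probs
    with np.errstate(divide="ignore", invalid="ignore"):
        t = q_probs * np.log2(q_probs / pq[None, :])
    t = np.where(q_probs > 0, t, 0.0)
    return max(float(p_y @ t.sum(axis=1)), 0.0)


def blackwell_redundancy_exact(system: SourceSystem, n_q: int | None = None,
                               max_reduced_dim: int = 24) -> BlackwellResult:
    """Exact redundancy by vertex enumeration of the garbling polytope.

    Independent of the source weights by construction (``nu_s`` never enters
    the constraints or the objective).  Intended for small systems; the
    enumeration refuses to run when the polytope dimension after equality
    elimination exceeds ``max_reduced_dim``.
    """
    if n_q is None:
        n_q = sum(len(ch.output_outcomes) for ch in system.channels) \
            - system.n_sources + 1
    if n_q < 1:
        raise ValidationError("bottleneck cardinality must be at least 1")
    poly = build_blackwell_polytope(system, n_q)
    vertices = enumerate_vertices(poly.A_eq, poly.b_eq, poly.n_vars,
                                  max_reduced_dim=max_reduced_dim)
    p_y = system.p_y.probs
    p1 = system.channels[0].probs
    best_val, best_q = -1.0, None
    values = np.empty(len(vertices))
    for i, v in enumerate(vertices):
        kappa1 = v[poly.offsets[0]:poly.offsets[1]].reshape(poly.x_cards[0], n_q)
        q_probs = p1 @ kappa1
        values[i] = _mi_target_channel(p_y, q_probs)
        if values[i] > best_val:
            best_val, best_q = values[i], q_probs
    # clean the witness: renormalize away enumeration round-off
    best_q = np.clip(best_q, 0.0, None)
    best_q /= best_q.sum(axis=1, keepdims=True)
    channel = Channel(system.p_y.outcomes,
                      [f"q{i}" for i in range(n_q)], best_q)
    return BlackwellResult(float(best_val), channel, values, len(vertices))


def is_blackwell_leq(b: Channel, c: Channel, tol: float = 1e-9) -> bool:
    """Is ``b`` a garbling of ``c``?  Decided by an LP on the residual.

    Minimizes the largest absolute entry of ``kappa ∘ c - b`` over
    row-stochastic ``kappa``; ``b`` is Blackwell-below ``c`` when the optimum
    is zero (within ``tol``).
    """
    if b.input_outcomes != c.input_outcomes:
        raise ValidationError("channels must share the target alphabet")
    ny = len(b.input_outcomes)
    nc, nb = len(c.output_outcomes), len(b.output_outcomes)
    nk = nc * nb  # kappa[x_c, x_b] flattened, plus one slack variable t
    rows_ub, rhs_ub = [], []
    for y in range(ny):
        for j in range(nb):
            row = np.zeros(nk + 1)
            row[j:nk:nb] = c.probs[y]      # (kappa ∘ c)(j|y)
            row[-1] = -1.0
            rows_ub.append(row.copy())
            rhs_ub.append(b.probs[y, j])   # residual <= t
            row[:nk] *= -1.0
            rows_ub.append(row)
            rhs_ub.append(-b.probs[y, j])  # -residual <= t
    rows_eq = []
    for i in range(nc):
        row = np.zeros(nk + 1)
        row[i * nb:(i + 1) * nb] = 1.0
        rows_eq.append(row)
    res = linprog(np.eye(nk + 1)[-1], A_ub=np.array(rows_ub), b_ub=np.array(rhs_ub),
                  A_eq=np.array(rows_eq), b_eq=np.ones(nc),
                  bounds=[(0, 1)] * nk + [(0, None)], method="highs")
    if res.status != 0:
        raise NumericalError(f"degradation LP failed: {res.message}")
    return bool(res.fun <= tol)


def deficiency(c: Channel, b: Channel, p_y: DiscreteDistribution,
               tol: float = 1e-10, max_iter: int = 20000) -> float:
    """Weighted KL deficiency ``min_kappa D(kappa ∘ c || b)`` in bits.

    The divergence is averaged over the target marginal ``p_y``.  The problem
    is convex in ``kappa``; it is solved by exponentiated-gradient (mirror
    descent) steps on the rows of ``kappa`` with backtracking line search.
    Returns ``inf`` when no garbling of ``c`` is absolutely continuous with
    respect to ``b``.
    """
    if c.input_outcomes != b.input_outcomes or c.input_outcomes != p_y.outcomes:
        raise ValidationError("channels and target marginal must share alphabets")
    w = p_y.probs
    C = c.probs                      # (ny, nc)
    B = b.probs                      # (ny, nb)
    nc, nb = C.shape[1], B.shape[1]

    # absolute continuity: wherever b(j|y) = 0, the garbled mass must vanish,
    # which forbids kappa[i, j] for every i with c(i|y) > 0
    allowed = np.ones((nc, nb), dtype=bool)
    for y in range(len(w)):
        zero_j = B[y] <= 0
        pos_i = C[y] > 0
        if zero_j.any() and pos_i.any():
            allowed[np.ix_(pos_i, zero_j)] = False
    if np.any(~allowed.any(axis=1)):
        return float("inf")

    kappa = allowed / allowed.sum(axis=1, keepdims=True)

    def objective(k: np.ndarray) -> float:
        m = C @ k                        # (ny, nb)
        mask = m > 0
        t = np.zeros_like(m)
        t[mask] = m[mask] * np.log(m[mask] / np.maximum(B, 1e-300)[mask])
        return float(w @ t.sum(axis=1))  # nats

    def gradient(k: np.ndarray) -> np.ndarray:
        m = C @ k
        lnr = np.log(np.maximum(m, 1e-30) / np.maximum(B, 1e-300))
        return (w[:, None] * C).T @ (lnr + 1.0)

    obj = objective(kappa)
    eta = 1.0
    improved = np.inf
    for _ in range(max_iter):
        g = gradient(kappa)
        g = g - g.min(axis=1, keepdims=True)  # row shift: invariant on the simplex
        step_taken = False
        while eta >= 1e-14:
            knew = np.where(allowed, kappa * np.exp(-np.clip(eta * g, -700, 700)), 0.0)
            norm = knew.sum(axis=1, keepdims=True)
            if np.all(norm > 0):
                knew = knew / norm
                new_obj = objective(knew)
                if new_obj <= obj + 1e-15:
                    step_taken = True
                    break
            eta *= 0.5
        if not step_taken:  # no descent direction left: numerically optimal
            return max(obj / LN2, 0.0)
        improved = obj - new_obj
        kappa, obj = knew, new_obj
        if improved < tol * LN2:
            return max(obj / LN2, 0.0)
        eta = min(eta * 1.3, 1e4)
    raise NumericalError(
        f"deficiency solver did not converge: last improvement {improved:.3e} nats"
    )
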