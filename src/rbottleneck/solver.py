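"""Alternating ascent solver for the redundancy bottleneck Lagrangians.

The optimization variable is a bottleneck channel ``r(q | s, z)`` attached to
the augmented joint ``p(y, s, z)``.  The solved tradeoff is between

* prediction  ``I(Q; Y | S)`` — target information carried by Q, and
* compression ``I(Q; S | Y)`` — how much Q leaks about which source spoke,

combined either linearly, ``I(Q;Y|S) - I(Q;S|Y) / beta``, or through the
exponential penalty ``I(Q;Y|S) - exp(I(Q;S|Y)) / beta``.  The exponential form
is the default because it resolves tradeoff curves that are not strictly
concave, where the linear Lagrangian only ever lands on the curve's endpoints.

The solver alternates a variational step (the auxiliary joint ``omega`` is set
to the joint induced by the current ``r``) with a closed-form multiplicative
update of ``r`` obtained from the stationarity condition of the variational
objective.  Both steps increase the objective, which is bounded above by
``I(Z; Y | S)``, so the iteration converges.  The objective is not jointly
concave, so random restarts guard against poor local optima.

Internally everything is computed in nats — the exponential penalty and the
effective inverse temperature ``beta * exp(-I(Q;S|Y))`` are natural-log
expressions — and converted to bits at the reporting boundary.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .discrete import JointSystem
from .errors import NumericalError, ValidationError

__all__ = [
    "BottleneckChannel",
    "SolverConfig",
    "SolverState",
    "SourceDecomposition",
    "RBPoint",
    "init_bottleneck",
    "update_variational",
    "update_bottleneck",
    "evaluate_channel",
    "evaluate_point",
    "solve",
    "batch_pred_comp",
    "induced_target_channel",
]

LN2 = math.log(2.0)
#: probability floor applied inside logarithms of the multiplicative update
LOG_FLOOR = 1e-300


@dataclass(frozen=True, eq=False)
class BottleneckChannel:
    """The channel ``r(q | s, z)`` defined on the (s, z) support.

    Stored densely as an ``(n_s, n_z, n_q)`` table; rows off the support mask
    carry no probability mass in any induced quantity and are kept uniform.
    """

    probs: np.ndarray
    support: np.ndarray

    def __init__(self, probs, support):
        p = np.asarray(probs, dtype=float)
        sup = np.asarray(support, dtype=bool)
        object.__setattr__(self, "probs", p)
        object.__setattr__(self, "support", sup)
        if p.ndim != 3 or p.shape[:2] != sup.shape:
            raise ValidationError("bottleneck table must be (n_s, n_z, n_q)")
        rows = p[sup]
        if np.any(rows < -1e-12):
            raise ValidationError("negative bottleneck probability")
        if np.any(np.abs(rows.sum(axis=1) - 1.0) > max(1e-12, 1e-12 * p.shape[2])):
            raise ValidationError("supported bottleneck rows must sum to 1")

    @property
    def n_q(self) -> int:
        return self.probs.shape[2]

    @property
    def rows(self) -> np.ndarray:
        """The supported rows, one per (s, z) pair with z in the source alphabet."""
        return self.probs[self.support]

    def permute_labels(self, perm) -> "BottleneckChannel":
        """Relabel the bottleneck outcomes; all induced quantities are invariant."""
        perm = np.asarray(perm, dtype=int)
        return BottleneckChannel(self.probs[:, :, perm], self.support)


@dataclass(frozen=True)
class SolverConfig:
    """Solver settings.

    beta
        Positive tradeoff parameter; small beta favors compression (the
        redundancy limit), large beta favors prediction.
    objective
        ``"exponential"`` (default) or ``"linear"``.
    n_q
        Bottleneck cardinality; ``None`` selects the provably sufficient
        ``sum_s |X_s| + 1``.
    tol
        Convergence threshold on the objective change per iteration, in bits.
    """

    beta: float = 1.0
    objective: str = "exponential"
    n_q: int | None = None
    max_iter: int = 5000
    tol: float = 1e-10
    n_restarts: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.beta <= 0:
            raise ValidationError("beta must be positive")
        if self.objective not in ("linear", "exponential"):
            raise ValidationError("objective must be 'linear' or 'exponential'")
        if self.n_q is not None and self.n_q < 1:
            raise ValidationError("n_q must be at least 1")
        if self.tol <= 0:
            raise ValidationError("tol must be positive")

    def resolve_n_q(self, joint: JointSystem) -> int:
        return self.n_q if self.n_q is not None else joint.n_support + 1


@dataclass(eq=False)
class SolverState:
    """One run's internal state: current channel, variational joint, trace."""

    r: BottleneckChannel
    omega: np.ndarray
    beta_eff: float
    objective_trace: list = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False


@dataclass(frozen=True, eq=False)
class SourceDecomposition:
    """Per-source split of prediction and compression (bits).

    ``prediction[s] = I(Q; Y | S=s)`` and ``compression[s] = I(Q; S=s | Y)``
    are specific conditional mutual informations; their nu-weighted averages
    recover the totals exactly.
    """

    source_names: tuple[str, ...]
    weights: np.ndarray
    prediction: np.ndarray
    compression: np.ndarray

    def total_prediction(self) -> float:
        return float(self.weights @ self.prediction)

    def total_compression(self) -> float:
        return float(self.weights @ self.compression)


@dataclass(frozen=True, eq=False)
class RBPoint:
    """One solved tradeoff point (all information quantities in bits)."""

    beta: float
    prediction: float
    compression: float
    objective: float
    per_source: SourceDecomposition
    converged: bool
    n_iter: int
    channel: BottleneckChannel
    objective_kind: str = "exponential"


# ---------------------------------------------------------------------------
# elementary steps
# ---------------------------------------------------------------------------

def init_bottleneck(joint: JointSystem, n_q: int, rng: np.random.Generator
                    ) -> BottleneckChannel:
    """Random start: supported rows drawn from a symmetric Dirichlet(1)."""
    ns, nz = joint.support.shape
    probs = np.full((ns, nz, n_q), 1.0 / n_q)
    probs[joint.support] = rng.dirichlet(np.ones(n_q), size=int(joint.support.sum()))
    return BottleneckChannel(probs, joint.support)


def update_variational(joint: JointSystem, r: BottleneckChannel) -> np.ndarray:
    """The optimal variational joint: ``omega(y,s,z,q) = p(y,s,z) r(q|s,z)``."""
    return joint.p_ysz[:, :, :, None] * r.probs[None, :, :, :]


def _pred_comp_nats(joint: JointSystem, r_probs: np.ndarray) -> tuple[float, float]:
    """(I(Q;Y|S), I(Q;S|Y)) in nats for the induced joint over (Y, S, Q)."""
    j = np.einsum("ysz,szq->ysq", joint.p_ysz, r_probs)
    return _cmi_last(j, cond=1), _cmi_last(j.transpose(1, 0, 2), cond=1)


#: joint-mass threshold below which cells are treated as zero in MI sums;
#: prevents sub-normal underflow of marginal products (contribution < 1e-110)
MASS_EPS = 1e-120


def _cmi_last(j: np.ndarray, cond: int) -> float:
    """I(A;B|C) in nats for 3-d joint (a, c, b) with the conditioner on axis 1."""
    j = np.moveaxis(j, cond, 0)
    pa = j.sum(axis=2, keepdims=True)
    pb = j.sum(axis=1, keepdims=True)
    pc = pa.sum(axis=1, keepdims=True)
    mask = j > MASS_EPS
    out = np.zeros_like(j)
    out[mask] = j[mask] * np.log((j * pc)[mask] / (pa * pb)[mask])
    return max(float(out.sum()), 0.0)


def update_bottleneck(joint: JointSystem, omega: np.ndarray, beta_eff: float
                      ) -> BottleneckChannel:
    """Closed-form multiplicative update of ``r`` at fixed variational joint.

    Stationarity of the variational objective in ``r`` gives

        r(q|s,z)  ∝  exp sum_y p(y|s,z) [ beta_eff ln omega(y|q,s)
                                          + ln omega(q|y)
                                          + ln omega(z|s,y,q) ]

    (terms independent of q are absorbed by the row normalization).  Rows are
    renormalized after a max-subtraction in the exponent for stability.
    """
    p_ysz = joint.p_ysz
    p_sz = p_ysz.sum(axis=0)
    with np.errstate(invalid="ignore"):
        p_y_sz = np.where(p_sz > 0, p_ysz / np.where(p_sz > 0, p_sz, 1.0), 0.0)

    w_ysq = omega.sum(axis=2)                     # (y, s, q)
    w_sq = w_ysq.sum(axis=0)                      # (s, q)
    w_yq = omega.sum(axis=(1, 2))                 # (y, q)
    p_y = p_ysz.sum(axis=(1, 2))                  # (y,)

    ln_w_y_qs = np.log(np.maximum(w_ysq / np.maximum(w_sq, LOG_FLOOR)[None], LOG_FLOOR))
    ln_w_q_y = np.log(np.maximum(w_yq / p_y[:, None], LOG_FLOOR))
    ln_w_z_syq = np.log(
        np.maximum(omega / np.maximum(w_ysq, LOG_FLOOR)[:, :, None, :], LOG_FLOOR)
    )

    expo = np.einsum("ysz,ysq->szq", p_y_sz, beta_eff * ln_w_y_qs + ln_w_q_y[:, None, :])
    expo += np.einsum("ysz,yszq->szq", p_y_sz, ln_w_z_syq)
    if not np.all(np.isfinite(expo[joint.support])):
        raise NumericalError("non-finite exponent in bottleneck update")
    expo -= expo.max(axis=2, keepdims=True)
    r = np.exp(expo)
    norm = r.sum(axis=2, keepdims=True)
    if np.any(norm[joint.support] <= 0):
        raise NumericalError(
            "bottleneck row vanished after exponentiation; "
            "smallest exponent %.3g" % expo.min()
        )
    r /= norm
    r[~joint.support] = 1.0 / r.shape[2]
    return BottleneckChannel(r, joint.support)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def evaluate_channel(joint: JointSystem, r: BottleneckChannel
                     ) -> tuple[float, float, SourceDecomposition]:
    """Exact prediction, compression and per-source decomposition (bits)."""
    j_ysq = np.einsum("ysz,szq->ysq", joint.p_ysz, r.probs)
    p_y = joint.p_y
    nu = joint.nu
    p_ys = p_y[:, None] * nu[None, :]

    with np.errstate(invalid="ignore", divide="ignore"):
        q_given_ys = j_ysq / p_ys[:, :, None]                 # p(q | y, s)
    q_given_s = j_ysq.sum(axis=0) / nu[:, None]               # p(q | s)
    q_given_y = j_ysq.sum(axis=1) / p_y[:, None]              # p(q | y)

    def _avg_kl(cond_ref: np.ndarray) -> np.ndarray:
        # sum_y p(y) D(p(q|y,s) || ref) per source, in bits
        mask = q_given_ys > MASS_EPS
        ratio = np.zeros_like(q_given_ys)
        ratio[mask] = np.log2(q_given_ys[mask] / np.maximum(cond_ref, LOG_FLOOR)[mask])
        return np.einsum("y,ysq->s", p_y, q_given_ys * ratio)

    pred_s = np.maximum(_avg_kl(np.broadcast_to(q_given_s[None], j_ysq.shape)), 0.0)
    comp_s = np.maximum(_avg_kl(np.broadcast_to(q_given_y[:, None], j_ysq.shape)), 0.0)
    decomp = SourceDecomposition(joint.s_outcomes, nu, pred_s, comp_s)
    return decomp.total_prediction(), decomp.total_compression(), decomp


def evaluate_point(joint: JointSystem, r: BottleneckChannel, beta: float = 1.0,
                   objective: str = "exponential") -> RBPoint:
    """Wrap a channel as an :class:`RBPoint` with its Lagrangian objective."""
    pred, comp, decomp = evaluate_channel(joint, r)
    obj = _objective_bits(pred, comp, beta, objective)
    return RBPoint(beta, pred, comp, obj, decomp, True, 0, r, objective)


def _objective_bits(pred_bits: float, comp_bits: float, beta: float,
                    objective: str) -> float:
    if objective == "linear":
        return pred_bits - comp_bits / beta
    return pred_bits - math.exp(comp_bits * LN2) / (beta * LN2)


def induced_target_channel(joint: JointSystem, r: BottleneckChannel):
    """The bottleneck seen from the target: ``p(q | y)`` as a :class:`Channel`."""
    from .discrete import Channel

    j_ysq = np.einsum("ysz,szq->ysq", joint.p_ysz, r.probs)
    probs = j_ysq.sum(axis=1) / joint.p_y[:, None]
    return Channel(joint.y_outcomes, [f"q{i}" for i in range(r.n_q)], probs)


def batch_pred_comp(joint: JointSystem, r_batch: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized (prediction, compression) in bits for a batch of channels.

    ``r_batch`` has shape ``(B, n_s, n_z, n_q)``; used by the dense random
    search that cross-checks the iterative solver.
    """
    j = np.einsum("ysz,bszq->bysq", joint.p_ysz, r_batch)

    def _cmi(jj):  # I(A;B|C) for (B, a, c, b), conditioner axis 2
        pa = jj.sum(axis=3, keepdims=True)
        pb = jj.sum(axis=1, keepdims=True)
        pc = pa.sum(axis=1, keepdims=True)
        mask = jj > MASS_EPS
        out = np.zeros_like(jj)
        out[mask] = jj[mask] * np.log2((jj * pc)[mask] / (pa * pb)[mask])
        return np.maximum(out.sum(axis=(1, 2, 3)), 0.0)

    return _cmi(j), _cmi(j.transpose(0, 2, 1, 3))


# ---------------------------------------------------------------------------
# full solve
# ---------------------------------------------------------------------------

def _run_once(joint: JointSystem, config: SolverConfig, r0: BottleneckChannel
              ) -> SolverState:
    beta = config.beta
    exponential = config.objective == "exponential"
    tol_nats = config.tol * LN2
    r = r0
    state = SolverState(r, update_variational(joint, r), beta)
    f_prev = -np.inf
    beta_eff = beta
    for it in range(config.max_iter):
        omega = update_variational(joint, r)
        if exponential:
            _, comp_nats = _pred_comp_nats(joint, r.probs)
            beta_eff = beta * math.exp(-comp_nats)
        else:
            beta_eff = beta
        r = update_bottleneck(joint, omega, beta_eff)
        pred_nats, comp_nats = _pred_comp_nats(joint, r.probs)
        penalty = math.exp(comp_nats) if exponential else comp_nats
        f = pred_nats - penalty / beta
        state.objective_trace.append(f / LN2)
        state.n_iter = it + 1
        if abs(f - f_prev) < tol_nats:
            state.converged = True
            break
        f_prev = f
    state.r = r
    state.omega = update_variational(joint, r)
    state.beta_eff = beta_eff
    return state


def solve(joint: JointSystem, config: SolverConfig,
          warm_start: BottleneckChannel | None = None,
          rng: np.random.Generator | None = None) -> RBPoint:
    """Solve one Lagrangian: best of a warm start plus random restarts.

    Returns the point with the largest objective; near-ties (within 1e-12
    bits) are broken in favor of lower compression.  Non-convergence of every
    restart is reported through ``converged=False`` and a warning, not an
    exception.
    """
    n_q = config.resolve_n_q(joint)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    starts: list[BottleneckChannel] = []
    if warm_start is not None:
        if warm_start.n_q != n_q or warm_start.probs.shape[:2] != joint.support.shape:
            raise ValidationError("warm start shape does not match joint/config")
        starts.append(warm_start)
    starts.extend(init_bottleneck(joint, n_q, rng) for _ in range(config.n_restarts))
    if not starts:
        raise ValidationError("no starting point: n_restarts=0 and no warm start")

    best: RBPoint | None = None
    for r0 in starts:
        state = _run_once(joint, config, r0)
        pred, comp, decomp = evaluate_channel(joint, state.r)
        obj = _objective_bits(pred, comp, config.beta, config.objective)
        point = RBPoint(config.beta, pred, comp, obj, decomp, state.converged,
                        state.n_iter, state.r, config.objective)
        if (best is None or point.objective > best.objective + 1e-12
                or (abs(point.objective - best.objective) <= 1e-12
                    and point.compression < best.compression)):
            best = point
    if not best.converged:
        warnings.warn(
            f"RB solver did not converge at beta={config.beta:g} "
            f"within {config.max_iter} iterations", RuntimeWarning)
    return best


def joint_fingerprint(joint: JointSystem) -> str:
    """Short stable identifier of the augmented joint (used in curve records)."""
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(joint.p_ysz).tobytes())
    h.update(np.ascontiguousarray(joint.support).tobytes())
    h.update("|".join(joint.z_outcomes).encode())
    return h.hexdigest()[:12]


def config_with_beta(config: SolverConfig, beta: float) -> SolverConfig:
    return replace(config, beta=beta)
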