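"""Tradeoff-curve assembly: beta annealing, envelopes and interpolation.

A full redundancy-bottleneck analysis sweeps the tradeoff parameter beta over
a grid, warm-starting each solve from the previous optimum (annealing) while
still trying fresh random restarts.  The achieved (compression, prediction)
pairs are summarized by their upper concave envelope — the optimal tradeoff
is provably non-decreasing and concave in the rate, so the envelope is the
honest estimator of the curve and linear interpolation on it evaluates the
bottleneck value at any fixed rate R.

Per-source traces are also exposed.  No monotonicity or concavity is imposed
on those: individual sources can, and in interesting systems do, trace
non-concave and non-monotonic paths even though the total curve is concave.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .discrete import JointSystem
from .errors import ValidationError
from .solver import RBPoint, SolverConfig, config_with_beta, joint_fingerprint, solve

__all__ = [
    "RBCurve",
    "default_beta_grid",
    "anneal_curve",
    "concave_envelope",
    "rb_at_rate",
    "per_source_curves",
]


@dataclass(frozen=True, eq=False)
class RBCurve:
    """An ordered sequence of solved tradeoff points (increasing beta)."""

    points: tuple[RBPoint, ...]
    fingerprint: str
    config: SolverConfig

    @property
    def betas(self) -> np.ndarray:
        return np.array([p.beta for p in self.points])

    @property
    def predictions(self) -> np.ndarray:
        return np.array([p.prediction for p in self.points])

    @property
    def compressions(self) -> np.ndarray:
        return np.array([p.compression for p in self.points])


def default_beta_grid(n: int = 50, lo: float = 1e-2, hi: float = 1e3) -> np.ndarray:
    """Logarithmic beta grid covering both tradeoff limits for all fixtures."""
    return np.geomspace(lo, hi, n)


def anneal_curve(joint: JointSystem, beta_grid=None,
                 config: SolverConfig | None = None) -> RBCurve:
    """Solve the Lagrangian along an increasing beta grid with warm starts.

    At each beta the previous optimum seeds the solver alongside
    ``config.n_restarts`` fresh random starts; the best point is kept.
    """
    if config is None:
        config = SolverConfig()
    betas = default_beta_grid() if beta_grid is None else np.asarray(beta_grid, float)
    if betas.size == 0:
        raise ValidationError("beta grid must be non-empty")
    if np.any(betas <= 0) or np.any(np.diff(betas) <= 0):
        raise ValidationError("beta grid must be strictly increasing and positive")
    rng = np.random.default_rng(config.seed)
    points = []
    warm = None
    for beta in betas:
        point = solve(joint, config_with_beta(config, float(beta)),
                      warm_start=warm, rng=rng)
        warm = point.channel
        points.append(point)
    return RBCurve(tuple(points), joint_fingerprint(joint), config)


def concave_envelope(compression, prediction) -> tuple[np.ndarray, np.ndarray]:
    """Upper concave envelope of achieved (compression, prediction) pairs.

    Points are sorted by compression, dominated points (no better prediction
    than a cheaper point) are dropped, and the upper concave hull of the rest
    is returned.  Restart noise can produce dominated points; concavity of
    the true curve licenses the hull.
    """
    x = np.asarray(compression, float)
    y = np.asarray(prediction, float)
    if x.size == 0:
        raise ValidationError("envelope of an empty point set")
    order = np.argsort(x, kind="stable")
    hull: list[tuple[float, float]] = []
    best = -np.inf
    for xi, yi in zip(x[order], y[order]):
        if yi <= best + 1e-15:
            continue  # dominated
        best = yi
        if hull and xi <= hull[-1][0] + 1e-15:
            hull.pop()  # same rate, strictly better prediction
        while len(hull) >= 2:
            (x1, y1), (x2, y2) = hull[-2], hull[-1]
            # drop the middle point if it lies on or below the chord
            if (y2 - y1) * (xi - x1) <= (yi - y1) * (x2 - x1) + 1e-15:
                hull.pop()
            else:
                break
        hull.append((float(xi), float(yi)))
    hx, hy = np.array([p[0] for p in hull]), np.array([p[1] for p in hull])
    return hx, hy


def rb_at_rate(curve: RBCurve, rate: float) -> float:
    """Bottleneck value at a fixed compression rate R, in bits.

    Linear interpolation on the concave envelope of the achieved points.
    Beyond the largest achieved compression the value is clamped to the
    largest achieved prediction; the result is non-decreasing and concave in
    R by construction.
    """
    if rate < 0:
        raise ValidationError("rate must be nonnegative")
    if len(curve.points) < 1:
        raise ValidationError("curve has no points")
    hx, hy = concave_envelope(curve.compressions, curve.predictions)
    if rate >= hx[-1]:
        return float(hy[-1])
    if rate <= hx[0]:
        return float(hy[0])
    return float(np.interp(rate, hx, hy))


def per_source_curves(curve: RBCurve) -> dict[str, np.ndarray]:
    """Per-source (compression, prediction) traces, one ``(n_beta, 2)`` array each."""
    if not curve.points:
        raise ValidationError("curve has no points")
    names = curve.points[0].per_source.source_names
    out = {}
    for i, name in enumerate(names):
        out[name] = np.array([
            (p.per_source.compression[i], p.per_source.prediction[i])
            for p in curve.points
        ])
    return out
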