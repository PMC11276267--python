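"""Benchmark systems from the partial-information-decomposition literature.

Five named gates exercise qualitatively different redundancy structure:

* ``unique``  — one source copies the target, the other is pure noise; all
  information is unique, redundancy is zero.
* ``and``     — both sources see the same channel to ``Y = X1 AND X2``; all
  information is redundant.
* ``bsc``     — four binary symmetric channels of differing noise levels;
  exposes a graded redundant group (the two cleanest sources).
* ``spin_overlap`` — a three-bit target observed through three two-bit windows
  that share the first bit; redundancy equals the shared bit.
* ``copy``    — ``Y = (X1, X2)`` with tunable correlation ``eps`` between the
  sources; the classic example of a discontinuous Blackwell redundancy.

``random_system`` produces Dirichlet-random systems for property testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .discrete import Channel, DiscreteDistribution, SourceSystem
from .errors import ValidationError

__all__ = [
    "GateSpec",
    "make_gate",
    "unique_gate",
    "and_gate",
    "bsc_gate",
    "spin_overlap_gate",
    "copy_gate",
    "random_system",
    "GATE_NAMES",
]

logger = logging.getLogger(__name__)

GATE_NAMES = ("unique", "and", "bsc", "spin_overlap", "copy", "random")


@dataclass(frozen=True)
class GateSpec:
    """A named gate plus gate-specific parameters and optional source weights."""

    name: str
    parameters: dict = field(default_factory=dict)
    nu_s: tuple[float, ...] | None = None


def _bsc(eps: float) -> Channel:
    return Channel("01", "01", [[1 - eps, eps], [eps, 1 - eps]])


def unique_gate(nu_s=None) -> SourceSystem:
    """Uniform binary target; X1 a copy of Y, X2 an independent uniform bit."""
    p_y = DiscreteDistribution.uniform("01")
    x1 = Channel.identity("01")
    x2 = Channel("01", "01", np.full((2, 2), 0.5))
    return SourceSystem(p_y, [("X1", x1), ("X2", x2)], _nu(nu_s, 2))


def and_gate(nu_s=None) -> SourceSystem:
    """Y = X1 AND X2 for independent uniform source bits.

    Conditioned on the target, both sources see the same channel
    (2/3, 1/3 given y=0; 0, 1 given y=1), so all information is redundant.
    """
    p_y = DiscreteDistribution("01", [0.75, 0.25])
    ch = Channel("01", "01", [[2 / 3, 1 / 3], [0.0, 1.0]])
    return SourceSystem(p_y, [("X1", ch), ("X2", ch)], _nu(nu_s, 2))


def bsc_gate(eps=(0.1, 0.1, 0.2, 0.5), nu_s=None) -> SourceSystem:
    """Uniform binary target observed through binary symmetric channels."""
    eps = tuple(float(e) for e in np.atleast_1d(eps))
    if any(e < 0 or e > 1 for e in eps):
        raise ValidationError("bsc error probabilities must lie in [0, 1]")
    p_y = DiscreteDistribution.uniform("01")
    sources = [(f"X{i + 1}", _bsc(e)) for i, e in enumerate(eps)]
    return SourceSystem(p_y, sources, _nu(nu_s, len(eps)))


def spin_overlap_gate(nu_s=None) -> SourceSystem:
    """Three uniform binary spins; X1 = X2 = (Y1, Y2) and X3 = (Y1, Y3).

    Source outcomes are labelled by the observed bit pair, so the pooled
    alphabet is shared across sources and a pooled outcome does not by itself
    reveal which window produced it.
    """
    y_outcomes = [f"{a}{b}{c}" for a in "01" for b in "01" for c in "01"]
    pair_outcomes = [f"{a}{b}" for a in "01" for b in "01"]
    p_y = DiscreteDistribution.uniform(y_outcomes)

    def window(select) -> Channel:
        t = np.zeros((8, 4))
        for i, y in enumerate(y_outcomes):
            t[i, pair_outcomes.index(select(y))] = 1.0
        return Channel(y_outcomes, pair_outcomes, t)

    x12 = window(lambda y: y[0] + y[1])
    x3 = window(lambda y: y[0] + y[2])
    return SourceSystem(p_y, [("X1", x12), ("X2", x12), ("X3", x3)], _nu(nu_s, 3))


def copy_gate(eps: float = 0.0, nu_s=None) -> SourceSystem:
    """Y = (X1, X2) for binary sources with correlation parameter ``eps``.

    ``p(x1 = x2) = 1/2 - eps/4`` per agreeing pair: perfect correlation at
    eps = 0, independence at eps = 1.  Target outcomes of zero probability
    (the discordant pairs at eps = 0) are pruned so that the target marginal
    keeps full support; the pruning is logged.
    """
    if eps < 0 or eps > 1:
        raise ValidationError("copy gate correlation eps must lie in [0, 1]")
    outcomes = ["00", "01", "10", "11"]
    probs = np.array([0.5 - eps / 4, eps / 4, eps / 4, 0.5 - eps / 4])
    keep = probs > 0
    if not keep.all():
        dropped = [o for o, k in zip(outcomes, keep) if not k]
        logger.info("copy gate: pruning zero-probability target outcomes %s", dropped)
    outcomes = [o for o, k in zip(outcomes, keep) if k]
    probs = probs[keep]
    p_y = DiscreteDistribution(outcomes, probs)

    def project(pos: int) -> Channel:
        t = np.zeros((len(outcomes), 2))
        for i, y in enumerate(outcomes):
            t[i, int(y[pos])] = 1.0
        return Channel(outcomes, "01", t)

    return SourceSystem(p_y, [("X1", project(0)), ("X2", project(1))], _nu(nu_s, 2))


def random_system(n_sources: int, y_card: int, x_cards, seed: int) -> SourceSystem:
    """A Dirichlet(1)-random system with uniform source weights; reproducible."""
    x_cards = list(np.broadcast_to(x_cards, (n_sources,)).astype(int))
    rng = np.random.default_rng(seed)
    y_outcomes = [f"y{i}" for i in range(y_card)]
    p_y = DiscreteDistribution(y_outcomes, rng.dirichlet(np.ones(y_card)))
    sources = []
    for s, nx in enumerate(x_cards):
        probs = rng.dirichlet(np.ones(nx), size=y_card) if nx > 1 else np.ones((y_card, 1))
        ch = Channel(y_outcomes, [f"x{j}" for j in range(nx)], probs)
        sources.append((f"X{s + 1}", ch))
    return SourceSystem(p_y, sources)


def _nu(nu_s, n: int) -> DiscreteDistribution | None:
    if nu_s is None:
        return None
    probs = np.asarray(nu_s, dtype=float)
    if len(probs) != n:
        raise ValidationError(f"nu_s must have {n} entries")
    return DiscreteDistribution([f"X{i + 1}" for i in range(n)], probs)


_BUILDERS = {
    "unique": unique_gate,
    "and": and_gate,
    "bsc": bsc_gate,
    "spin_overlap": spin_overlap_gate,
    "copy": copy_gate,
}


def make_gate(spec: GateSpec | str, **parameters) -> SourceSystem:
    """Build the system named by a :class:`GateSpec` (or name + keyword args)."""
    if isinstance(spec, str):
        spec = GateSpec(spec, parameters)
    elif parameters:
        raise ValidationError("pass parameters either in the spec or as keywords")
    if spec.name == "random":
        try:
            return random_system(**spec.parameters)
        except TypeError as exc:
            raise ValidationError(f"invalid random-system parameters: {exc}") from exc
    if spec.name not in _BUILDERS:
        raise ValidationError(
            f"unknown gate {spec.name!r}; expected one of {GATE_NAMES}"
        )
    try:
        return _BUILDERS[spec.name](nu_s=spec.nu_s, **spec.parameters)
    except TypeError as exc:
        raise ValidationError(f"invalid parameters for {spec.name!r}: {exc}") from exc
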