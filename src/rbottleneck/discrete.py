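"""Discrete probability containers and information measures.

This module provides the problem data for a redundancy analysis — a target
marginal ``p(y)``, a set of source channels ``p(x_s | y)`` and source weights
``nu(s)`` — together with the augmented joint distribution over ``(Y, S, Z)``
in which ``S`` is the (random) identity of the source and ``Z`` is the pooled
source outcome.  All information measures are reported in bits.

The augmented joint is

    p(y, s, z) = p(y) * nu(s) * p_{X_s|Y}(z | y)   for z in the alphabet of X_s

and zero otherwise.  Because the source index is drawn independently of the
target, the construction always satisfies ``I(Y; S) = 0``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

__all__ = [
    "DiscreteDistribution",
    "Channel",
    "SourceSystem",
    "JointSystem",
    "build_joint",
    "compose",
    "entropy",
    "kl",
    "mutual_information",
    "conditional_mi",
    "source_mutual_information",
    "prediction_bound",
    "rate_bound",
]

#: absolute tolerance for normalization / stochasticity checks at construction
ATOL = 1e-12


def _as_labels(outcomes) -> tuple[str, ...]:
    """Outcome labels are opaque strings; arbitrary label types are serialized."""
    return tuple(str(o) for o in outcomes)


@dataclass(frozen=True, eq=False)
class DiscreteDistribution:
    """A probability distribution over an ordered, finite set of outcomes."""

    outcomes: tuple[str, ...]
    probs: np.ndarray

    def __init__(self, outcomes, probs):
        object.__setattr__(self, "outcomes", _as_labels(outcomes))
        p = np.asarray(probs, dtype=float)
        object.__setattr__(self, "probs", p)
        if p.ndim != 1 or len(p) != len(self.outcomes):
            raise ValidationError("probs must be a vector matching outcomes")
        if len(set(self.outcomes)) != len(self.outcomes):
            raise ValidationError("duplicate outcome labels")
        if np.any(p < -ATOL):
            raise ValidationError("negative probability")
        if abs(p.sum() - 1.0) > max(ATOL, 1e-12 * len(p)):
            raise ValidationError(f"probabilities sum to {p.sum()!r}, not 1")

    def __len__(self) -> int:
        return len(self.outcomes)

    @classmethod
    def uniform(cls, outcomes) -> "DiscreteDistribution":
        outcomes = _as_labels(outcomes)
        return cls(outcomes, np.full(len(outcomes), 1.0 / len(outcomes)))


@dataclass(frozen=True, eq=False)
class Channel:
    """A conditional distribution ``p(output | input)``.

    ``probs[i, j]`` is the probability of ``output_outcomes[j]`` given
    ``input_outcomes[i]``; every row is a distribution.
    """

    input_outcomes: tuple[str, ...]
    output_outcomes: tuple[str, ...]
    probs: np.ndarray

    def __init__(self, input_outcomes, output_outcomes, probs):
        object.__setattr__(self, "input_outcomes", _as_labels(input_outcomes))
        object.__setattr__(self, "output_outcomes", _as_labels(output_outcomes))
        p = np.asarray(probs, dtype=float)
        object.__setattr__(self, "probs", p)
        if p.shape != (len(self.input_outcomes), len(self.output_outcomes)):
            raise ValidationError(
                f"channel table shape {p.shape} does not match alphabets"
            )
        if len(set(self.output_outcomes)) != len(self.output_outcomes):
            raise ValidationError("duplicate output labels")
        if np.any(p < -ATOL):
            raise ValidationError("negative conditional probability")
        if np.any(np.abs(p.sum(axis=1) - 1.0) > max(ATOL, 1e-12 * p.shape[1])):
            raise ValidationError("channel rows must each sum to 1")

    @classmethod
    def identity(cls, outcomes) -> "Channel":
        outcomes = _as_labels(outcomes)
        return cls(outcomes, outcomes, np.eye(len(outcomes)))


def compose(kappa: Channel, base: Channel) -> Channel:
    """Channel composition ``kappa ∘ base``: downstream processing of ``base``.

    ``(kappa ∘ base)(b | y) = sum_c kappa(b | c) base(c | y)``.
    """
    if kappa.input_outcomes != base.output_outcomes:
        raise ValidationError(
            "composition alphabet mismatch: kappa input must equal base output"
        )
    return Channel(base.input_outcomes, kappa.output_outcomes, base.probs @ kappa.probs)


@dataclass(frozen=True, eq=False)
class SourceSystem:
    """The user-facing problem definition.

    A target marginal ``p_y`` (full support), an ordered list of named source
    channels with input alphabet equal to the target alphabet, and a
    full-support weight distribution ``nu_s`` over the sources.
    """

    p_y: DiscreteDistribution
    sources: tuple[tuple[str, Channel], ...]
    nu_s: DiscreteDistribution

    def __init__(self, p_y, sources, nu_s=None):
        sources = tuple((str(name), ch) for name, ch in sources)
        if not sources:
            raise ValidationError("at least one source is required")
        names = [name for name, _ in sources]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate source names")
        if nu_s is None:
            nu_s = DiscreteDistribution.uniform(names)
        object.__setattr__(self, "p_y", p_y)
        object.__setattr__(self, "sources", sources)
        object.__setattr__(self, "nu_s", nu_s)
        if np.any(p_y.probs <= 0):
            raise ValidationError("target marginal must have full support")
        if np.any(nu_s.probs <= 0):
            raise ValidationError("source weights must have full support")
        if len(nu_s) != len(sources):
            raise ValidationError("nu_s length must equal the number of sources")
        for name, ch in sources:
            if ch.input_outcomes != p_y.outcomes:
                raise ValidationError(
                    f"source {name!r}: channel input alphabet differs from target"
                )

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.sources)

    @property
    def channels(self) -> tuple[Channel, ...]:
        return tuple(ch for _, ch in self.sources)

    @property
    def n_sources(self) -> int:
        return len(self.sources)


@dataclass(frozen=True, eq=False)
class JointSystem:
    """The augmented joint distribution ``p(y, s, z)`` with merged Z alphabet.

    ``support[s, z]`` marks whether the pooled outcome ``z`` belongs to the
    alphabet of source ``s``; ``p_ysz`` vanishes off the support.
    """

    y_outcomes: tuple[str, ...]
    s_outcomes: tuple[str, ...]
    z_outcomes: tuple[str, ...]
    p_ysz: np.ndarray
    support: np.ndarray
    source_alphabet_sizes: tuple[int, ...] = field(compare=False)

    def __init__(self, y_outcomes, s_outcomes, z_outcomes, p_ysz, support,
                 source_alphabet_sizes=None):
        object.__setattr__(self, "y_outcomes", _as_labels(y_outcomes))
        object.__setattr__(self, "s_outcomes", _as_labels(s_outcomes))
        object.__setattr__(self, "z_outcomes", _as_labels(z_outcomes))
        p = np.asarray(p_ysz, dtype=float)
        sup = np.asarray(support, dtype=bool)
        object.__setattr__(self, "p_ysz", p)
        object.__setattr__(self, "support", sup)
        if source_alphabet_sizes is None:
            source_alphabet_sizes = tuple(int(c) for c in sup.sum(axis=1))
        object.__setattr__(self, "source_alphabet_sizes", tuple(source_alphabet_sizes))
        ny = len(self.y_outcomes)
        ns = len(self.s_outcomes)
        nz = len(self.z_outcomes)
        if p.shape != (ny, ns, nz) or sup.shape != (ns, nz):
            raise ValidationError("joint table / support shape mismatch")
        if abs(p.sum() - 1.0) > 1e-10:
            raise ValidationError("joint distribution must sum to 1")
        if np.any(p[:, ~sup] > 0):
            raise ValidationError("probability mass outside the (s, z) support")
        j_ys = p.sum(axis=2)
        if mutual_information(j_ys) > 1e-10:
            raise ValidationError("target and source index must be independent")

    @property
    def p_y(self) -> np.ndarray:
        """Target marginal recovered from the joint."""
        return self.p_ysz.sum(axis=(1, 2))

    @property
    def nu(self) -> np.ndarray:
        """Source-weight marginal recovered from the joint."""
        return self.p_ysz.sum(axis=(0, 2))

    @property
    def n_support(self) -> int:
        """Number of (s, z) pairs with z in the alphabet of source s."""
        return int(self.support.sum())


def build_joint(system: SourceSystem) -> JointSystem:
    """Construct the augmented joint ``p(y,s,z) = p(y) nu(s) p_{X_s|Y}(z|y)``.

    The Z alphabet is the sorted union of the source output alphabets; shared
    labels are merged, so overlapping alphabets make ``Z`` genuinely ambiguous
    about which source produced it.
    """
    z_outcomes = sorted(set().union(*(ch.output_outcomes for ch in system.channels)))
    z_index = {z: i for i, z in enumerate(z_outcomes)}
    ny = len(system.p_y)
    ns = system.n_sources
    nz = len(z_outcomes)
    p = np.zeros((ny, ns, nz))
    support = np.zeros((ns, nz), dtype=bool)
    for s, (name, ch) in enumerate(system.sources):
        cols = [z_index[z] for z in ch.output_outcomes]
        support[s, cols] = True
        p[:, s, cols] = system.p_y.probs[:, None] * system.nu_s.probs[s] * ch.probs
    return JointSystem(
        system.p_y.outcomes, system.names, z_outcomes, p, support,
        tuple(len(ch.output_outcomes) for ch in system.channels),
    )


# ---------------------------------------------------------------------------
# information measures (bits)
# ---------------------------------------------------------------------------

def entropy(d: DiscreteDistribution) -> float:
    """Shannon entropy in bits, with the 0·log 0 = 0 convention."""
    p = d.probs
    nz = p > 0
    return float(-(p[nz] * np.log2(p[nz])).sum())


def kl(p: DiscreteDistribution, q: DiscreteDistribution) -> float:
    """Kullback–Leibler divergence ``D(p || q)`` in bits.

    Returns ``inf`` when ``p`` puts mass where ``q`` has none.
    """
    if p.outcomes != q.outcomes:
        raise ValidationError("kl requires a shared outcome ordering")
    pp, qq = p.probs, q.probs
    mask = pp > 0
    if np.any(qq[mask] <= 0):
        return math.inf
    return float((pp[mask] * np.log2(pp[mask] / qq[mask])).sum())


def _check_normalized(table: np.ndarray) -> np.ndarray:
    t = np.asarray(table, dtype=float)
    if np.any(t < -ATOL):
        raise ValidationError("joint table has negative entries")
    if abs(t.sum() - 1.0) > 1e-8:
        raise ValidationError(f"joint table sums to {t.sum()!r}, not 1")
    return t


def mutual_information(joint: np.ndarray) -> float:
    """``I(A; B)`` in bits for a 2-d joint probability table."""
    j = _check_normalized(joint)
    pa = j.sum(axis=1, keepdims=True)
    pb = j.sum(axis=0, keepdims=True)
    mask = j > 0
    out = np.zeros_like(j)
    out[mask] = j[mask] * np.log2(j[mask] / (pa * pb)[mask])
    return max(float(out.sum()), 0.0)


def conditional_mi(joint: np.ndarray, cond_axis: int) -> float:
    """``I(A; B | C)`` in bits for a 3-d joint table, conditioning on one axis.

    Computed as the conditional-marginal-weighted average of the per-condition
    mutual information between the remaining two axes.
    """
    j = _check_normalized(joint)
    if j.ndim != 3:
        raise ValidationError("conditional_mi expects a 3-d joint table")
    j = np.moveaxis(j, cond_axis, 0)
    total = 0.0
    for c in range(j.shape[0]):
        pc = j[c].sum()
        if pc > 0:
            total += pc * mutual_information(j[c] / pc)
    return total


def source_mutual_information(system: SourceSystem) -> dict[str, float]:
    """Per-source mutual information ``I(X_s; Y)`` in bits."""
    out = {}
    for name, ch in system.sources:
        joint = system.p_y.probs[:, None] * ch.probs
        out[name] = mutual_information(joint)
    return out


def prediction_bound(system: SourceSystem) -> float:
    """Upper bound on RB prediction: ``I(Z;Y|S) = sum_s nu(s) I(X_s;Y)`` (bits)."""
    mis = source_mutual_information(system)
    return float(sum(system.nu_s.probs[i] * mis[n] for i, n in enumerate(system.names)))


def rate_bound(system: SourceSystem) -> float:
    """Largest useful compression rate: ``I(Z; S | Y)`` on the augmented joint."""
    joint = build_joint(system)
    # I(Z;S|Y): move axes to (z, s, y) and condition on the last
    return conditional_mi(joint.p_ysz.transpose(2, 1, 0), 2)
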