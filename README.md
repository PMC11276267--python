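# rbottleneck

Redundancy analysis for discrete multivariate systems, formulated as an
information bottleneck.

## The problem

In the partial information decomposition (PID), several source variables
X₁, …, Xₙ carry information about a target Y — in neuroscience the sources
might be brain regions and the target a stimulus; in systems biology,
regulators and a phenotype.  *Redundancy* is the part of that information
present in **every** source individually.  A principled redundancy measure is
Blackwell redundancy,

    I∩ = max_Q I(Q; Y)   subject to   Q ⪯_Y X_s for all s,

the most target information any variable Q can carry while being a stochastic
post-processing (garbling) of each single source channel p(x_s | y).

This package implements the *redundancy bottleneck* (RB) view of that
quantity.  Pool the sources into one augmented system: draw the source index
S ~ ν(s) independently of Y and let Z be the pooled outcome, so
p(y, s, z) = p(y) ν(s) p_{X_s|Y}(z | y).  A bottleneck variable Q with Markov
structure Q − (S, Z) − Y then trades off

* **prediction** I(Q; Y | S) — target information extracted from the sources,
* **compression** I(Q; S | Y) — how much Q leaks about *which* source spoke:

    I_RB(R) = max_Q I(Q; Y | S)   subject to   I(Q; S | Y) ≤ R.

At R = 0 this recovers Blackwell redundancy exactly; as R → ∞ it climbs to
Σ_s ν(s) I(X_s; Y).  The curve R ↦ I_RB(R) is non-decreasing and concave,
continuous in the underlying probabilities for R > 0 (unlike I∩ itself), and
decomposes source-by-source — which identifies groups of redundant sources
without any combinatorial search.

## What the package provides

* `discrete` — distributions, channels, source systems, the augmented joint,
  and all information measures (bits).
* `solver` — an alternating-ascent (Blahut–Arimoto-style) solver for the
  linear and exponential RB Lagrangians with multiplicative closed-form
  updates, random restarts and monotone objective traces.
* `curve` — β-annealing, concave envelopes, interpolation of I_RB(R), and
  per-source tradeoff traces.
* `blackwell` — exact Blackwell redundancy for small systems by vertex
  enumeration of the garbling polytope, the Blackwell order decision
  (`is_blackwell_leq`), and weighted KL deficiency between channels.
* `gates` — the standard PID benchmark systems (UNIQUE, AND, a four-channel
  noisy family, a 3-spin overlap target, the COPY gate) plus random systems.
* `io` / `cli` — JSON system files, CSV curves, and an `rbottleneck` command
  with `gate`, `info`, `blackwell`, `curve` and `at-rate` subcommands.

## Worked example

```python
import numpy as np
from rbottleneck import (SolverConfig, anneal_curve, blackwell_redundancy_exact,
                         build_joint, rb_at_rate, unique_gate)

system = unique_gate()          # X1 copies the target bit, X2 is noise
print(round(blackwell_redundancy_exact(system).redundancy, 4))   # 0.0

curve = anneal_curve(build_joint(system), np.geomspace(1e-2, 1e3, 12),
                     SolverConfig(n_restarts=3, seed=0))
last = curve.points[-1]
print(round(last.compression, 4), round(last.prediction, 4))
print(round(rb_at_rate(curve, 0.0), 4))
```

prints

```
0.0
0.3113 0.5
0.0
```

Zero redundancy: nothing can be predicted without revealing that the
information came from X1.  Paying the full identity leak of
I(Z; S | Y) ≈ 0.311 bits buys the maximum average prediction of 0.5 bits
(one full bit from X1, nothing from X2), and the zero-rate end of the curve
agrees with the exact vertex-enumeration value.

The scripts in `examples/` walk through one capability each: the UNIQUE-gate
curve, exact redundancy on three gates, finding the redundant pair among four
noisy channels, and the continuity contrast on the COPY gate.

The same analyses from a shell:

```bash
rbottleneck gate and --out and.json
rbottleneck blackwell --system and.json     # blackwell_redundancy = 0.311278 bits
rbottleneck at-rate --system and.json -R 0.05
```

## Scope and limitations

Discrete (finite-alphabet) systems only; the exact Blackwell solver is for
small systems (the enumeration refuses once the reduced polytope dimension
grows) — at scale, use the iterative solver at small β instead.  See
`docs/methods.md` for the algorithmic details and numerical choices.
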