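# Methods

This note documents the models, algorithms and numerical choices behind
`rbottleneck`, in the order a reader would meet them: the augmented system,
the bottleneck optimization, the exact zero-rate solver, deficiency, the
benchmark generators, and known limitations.

## The augmented system

The problem data are a full-support target marginal p(y), n source channels
p(x_s | y), and a full-support weight distribution ν(s) over sources (uniform
unless the application dictates otherwise — e.g. sampling frequencies of
mutually exclusive conditions).  The augmented joint is

    p(y, s, z) = p(y) ν(s) p_{X_s|Y}(z | y),   z ∈ X_s,

with Z living on the *union* of the source alphabets (sorted string labels).
Overlapping labels are merged deliberately: a pooled outcome shared by two
sources does not by itself reveal which source produced it, and quantities
such as I(Z; S | Y) depend on that overlap.  Because S is drawn independently
of Y, the construction guarantees I(Y; S) = 0; this is validated at build
time (tolerance 1e-10) along with row-stochasticity and normalization
(1e-12).  Zero-probability target outcomes are rejected rather than silently
pruned — pruning changes alphabet indices — except in the COPY-gate builder,
which prunes its own structurally impossible outcomes and logs the fact.
All reported information quantities are in bits.

## The bottleneck optimization

The object of interest is the tradeoff

    I_RB(R) = max_{r(q|s,z)} I(Q; Y | S)  s.t.  I(Q; S | Y) ≤ R,

explored through Lagrangians: linear, pred − comp/β, and exponential,
pred − e^{comp}/β.  The exponential form is the default.  Rationale: the
optimal curve is concave but not always *strictly* concave (the AND and COPY
gates have entirely linear curves), and for linear segments the linear
Lagrangian is degenerate — every β maps to a segment endpoint.  The
exponential penalty breaks that degeneracy while preserving the optimum set.

The solver alternates two closed-form steps on a variational objective
L(r, ω) whose exact maximizer over the auxiliary joint ω is the joint induced
by the current r.  The r-step solves the stationarity condition of L in r at
fixed ω:

    r(q|s,z) ∝ exp Σ_y p(y|s,z) [ β_eff ln ω(y|q,s) + ln ω(q|y)
                                  + ln ω(z|s,y,q) ]

with the row normalizer absorbing all q-independent terms.  This grouping —
the whole bracket inside the Σ_y — is the one derived from the stationarity
condition; L is concave in r at fixed ω (the penalty is a composition of a
convex KL with the convex exponential), so the step is a global inner
maximization and each full alternation increases L.  The monotone-ascent
property is asserted in the test suite on random systems for both objective
forms.  For the exponential objective the update uses the effective inverse
temperature β_eff = β·e^{−I_r(Q;S|Y)} recomputed each iteration; for the
linear objective β_eff = β.

Numerical choices:

* computation in nats internally (the exponential penalty and β_eff are
  natural-log expressions); bits at the reporting boundary;
* log-domain update with a 1e-300 floor inside logarithms and max-subtraction
  before exponentiation;
* joint-mass cells below 1e-120 are treated as zero in information sums —
  sub-normal underflow of marginal products would otherwise produce NaNs
  while such cells contribute < 1e-110 bits;
* initialization from symmetric Dirichlet(1) rows, one seeded generator
  threaded through all stochastic code;
* convergence when the objective changes by < 1e-10 bits (default), capped
  at 5000 iterations (the AND gate at β = 1e-2 needs ≈ 2700); non-convergence
  is reported on the returned point and warned, not raised;
* 5 random restarts by default; the best objective wins, ties (within 1e-12
  bits) broken toward lower compression;
* bottleneck cardinality defaults to the provably sufficient Σ_s|X_s| + 1.

## Curves, envelopes, interpolation

A curve is traced by annealing: β runs over a logarithmic grid (default 50
points, 1e-2…1e3 — wide enough to reach both limits on every benchmark),
each solve warm-started from the previous optimum alongside fresh restarts.
β = 0 itself is never used; the update degenerates there, and the smallest
grid value already pins the zero-rate regime.

I_RB(R) is evaluated by linear interpolation on the *upper concave envelope*
of the achieved (compression, prediction) pairs: dominated points (restart
noise) are dropped and the concave hull taken — concavity of the true curve
licenses this.  Beyond the largest achieved compression the value is clamped
to the largest achieved prediction; when the solver undershoots the
theoretical rate bound this clamping is the conservative choice.  The result
is non-decreasing and concave in R by construction.

Per-source traces expose the specific conditional mutual informations
I(Q; Y | S=s) and I(Q; S=s | Y), whose ν-weighted averages reproduce the
totals exactly (asserted at 1e-10).  No shape constraints are imposed on
per-source traces: they can be non-concave and non-monotonic, and the
four-channel benchmark shows exactly that.

## Exact Blackwell redundancy

The zero-rate limit is computed exactly for small systems.  Fixing the
bottleneck cardinality at Σ_s|X_s| − n + 1 (which suffices), the feasible
garblings (κ_1, …, κ_n) — row-stochastic, κ_1∘p_{X_1|Y} = κ_s∘p_{X_s|Y} —
form a bounded polytope, and I(Q; Y) is convex in the induced channel, so the
maximum sits at a vertex.  The enumeration backend:

1. eliminate the equality constraints (LP feasibility for a particular
   solution, SVD null space for the basis);
2. detect implicit equalities among the κ ≥ 0 inequalities by per-row slack
   maximization LPs and recurse on the affine subspace they define;
3. enumerate vertices of the resulting full-dimensional polytope with Qhull,
   seeded at a Chebyshev center (0- and 1-dimensional cases handled
   directly); duplicate vertices and duplicate induced channels are merged at
   1e-9.

The guard is placed on the polytope dimension *after* equality elimination
(default 24) rather than on the raw variable count: the agreement
constraints collapse most of the raw dimensions (the 3-spin benchmark has
120 raw variables but an 18-dimensional feasible set with 100 vertices), and
the reduced dimension is what actually controls enumeration cost.  Oversized
problems are refused with a pointer to the iterative solver at small β.
The result is independent of ν by construction, and the returned maximum is
checked against every enumerated vertex in the tests.

The Blackwell order itself is decided by a small LP (minimize the largest
residual entry of κ∘c − b over stochastic κ; the order holds iff the optimum
is 0 within 1e-9).  The order is applied verbatim to channels with zero
entries, although its classical definition assumes full support; the
benchmark systems' deterministic channels make this extension necessary.

## Deficiency

The weighted KL deficiency δ_D(c, b) = min_κ Σ_y p(y) D((κ∘c)(·|y) ‖ b(·|y))
quantifies how far b is from being a garbling of c; it vanishes exactly in
the degradable direction and lower-bounds each source's compression leak
I(Q; S=s | Y) relative to the induced channel p(q|y).  Only this argument
order is implemented (minimizing KL in its first argument over a convex set);
the reversed-order variant found elsewhere in the literature is out of scope.
The minimization is convex and solved by exponentiated-gradient steps on the
rows of κ with backtracking (objective tolerance 1e-10, step growth 1.3,
halving on failure); entries forbidden by zeros of b are removed up front,
and if a whole row is forbidden the deficiency is infinite.  The solver is
cross-checked against an exhaustive 1e-3-step grid in the tests.

## Benchmark generators

The gate builders reproduce their defining distributions exactly (rational
entries at double precision): UNIQUE (copy + independent noise), AND
(p_Y = (3/4, 1/4), both channels (2/3, 1/3; 0, 1)), the four binary
symmetric channels (defaults ε = 0.1, 0.1, 0.2, 0.5), the 3-spin overlap
target (three uniform bits, windows (Y1,Y2), (Y1,Y2), (Y1,Y3) sharing the
bit-pair alphabet), and COPY(ε) (agreeing pairs carry mass 1/2 − ε/4 each).
Source weights default to uniform.  `random_system` draws Dirichlet(1)
marginals and channel rows, seeded, and is the fodder for property tests.
These generators emulate idealized textbook systems — exact symmetries,
deterministic channels, tiny alphabets.  Passing tests therefore demonstrate
correctness of the computations, not robustness to features of empirical
data such as sampling noise in estimated channels or large alphabets; for
estimated systems the exact enumeration is also quickly out of reach and
only the iterative solver applies.

## Known limitations and observed behavior

* Only the independent-S construction is implemented; correlated (S, Y)
  generalizations are out of scope, as are continuous variables and
  stochastic/neural solvers.
* At large β the exponential penalty on compression becomes weak, and a
  single cold-started solve can return the maximal prediction at *more*
  than the minimal compression; annealing across the β grid is what carries
  the minimal-compression solution to the large-β end (the 3-spin benchmark
  reaches (0.459, 2.0) annealed but not reliably cold-started).
* On the COPY gate the optimal curve is exactly the chord from (0, 0) to
  (ε/2, 1), so the rate-limited value at R behaves as min(1, 2R/ε): it is a
  continuous function of ε — in contrast to the exact redundancy, which
  jumps from 1 to 0 at ε = 0⁺ — but its decay near ε = 0 is steep
  (1 → 0.4 → 0.2 across ε = 0, 0.05, 0.1 at R = 0.01).  Continuity does not
  come with a gentle modulus.
* Restart noise can leave dominated points on a traced curve; envelopes, not
  raw traces, are the quantity with guarantees.  Phase transitions along β
  are visible in the raw traces; no changepoint detection is attempted.
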