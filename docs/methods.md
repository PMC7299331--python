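# Methods

## Threshold dynamics

Expression levels follow a discrete-time, continuous-state map with
Boolean interaction logic (the strong-cooperativity limit of Hill input
functions). Each step a gene's product decays by the factor (1 − α) and
gains a production term combining its regulators' Heaviside factors
γ_r θ(s_r − k_r) (activators) or γ_r θ(k_r − s_r) (repressors) under an
AND gate (product of the γθ factors) or an OR gate (their maximum). The
AND product reproduces the printed two- and three-gene circuit equations
exactly; the OR rule is our choice of the natural saturating alternative,
since only the AND form is written out in full in the source model
family. Parameters are keyed by *regulator*: γ_r is that regulator's
maximum expression rate and k_r its dissociation constant, in expression
(abundance) units; α is dimensionless per step.

Conventions that make the map fully deterministic:

- **θ at exact threshold**: θ(0) = 1 (production active at equality),
  configurable via `theta_at_zero`. The analytic switch-time formulas
  (ceil rule) are consistent with this choice.
- **Genes with no regulators and no drive** decay geometrically
  (`undriven="hold"` selectable). Driven genes are clamped to the drive
  signal — they are inputs, not dynamical variables.
- **Unknown-sign edges** are rejected by the simulator: there is no
  defensible production rule for an uncharacterised interaction. They
  remain first-class citizens of all structural analyses.

One caption in the source material quotes α = 2.0 for the feed-forward
loop figure; the map is only stable for α < 1 and the printed fixed
points (0.6 = 0.12/0.2 and 0.42 = 0.084/0.2) require α = 0.2, which is
what the accompanying text uses and what we adopt.

## The frustrated fiber: map, closed form, phase diagram

For the UNSAT feed-forward fiber (activator X; repressor autoregulation
on Y repressing Y and Z) the rescaled variable ψ = y/k_y follows
ψ_{t+1} = βψ_t + αλ θ(1 − ψ_t) with β = 1 − α and gain
λ = γ_x γ_y/(k_y α), for drive above the X threshold. (The unscaled
writing of this map thresholds y at k_y; after rescaling the threshold is
1.) Because e^{−1/τ} = β exactly (τ⁻¹ = −log β), the piecewise
closed form — geometric decay segments of length ⌈τ log ψ_s⌉ alternating
with rise segments of length ⌈τ log((λ−ψ_s)/(λ−1))⌉ toward λ — agrees
with the iterated map to rounding error (≤ 1e−9 over 500 steps in the
tests, typically ~1e−13). For λ < 1 there is a single monotone segment
converging to ψ∞ = λ; λ > 1 gives sustained oscillation; the phase
boundary λ = 1 is equivalently γ_y/k_y = (γ_x/α)⁻¹.

The oscillation detector is a state-recurrence test on a deterministic
trajectory: after a burn-in, the tail must have amplitude above an
absolute tolerance (default 1e−9) and repeat with a fixed integer period
within that tolerance. Constant and still-converging monotone tails are
classified as non-oscillating. Near the boundary the transient grows like
τ log(1/(λ−1)), so boundary-location runs use 2000 steps with a 1000-step
burn-in, which resolves the transition to better than 1e−3 in λ.

## Fibers, input trees, branching ratios

Fibers are computed as the coarsest balanced coloring: start with all
genes in one class and repeatedly split classes by the multiset of
(in-neighbor class, edge sign) until stable (at most |genes| rounds).
Edge signs — including "unknown" — are part of the balance condition,
because the dynamics differ by sign. The verification oracle is
independent: depth-|V| input trees canonized bottom-up by hash-consing
sign-labelled rooted trees; the tests check class-for-class agreement
exhaustively on all 3-node digraphs with self-loops and all loop-free
4-node digraphs over {absent, activator, repressor}, plus sampled 5–6
node graphs with all three signs. (Full enumeration of 4-node graphs
*with* self-loops — 4^16 graphs — is computationally out of reach; the
3-node family covers the self-loop interactions exhaustively.)

Input-tree layer sizes Q_t are computed exactly, at any depth, from the
integer recurrence c_{t+1} = A_in c_t on per-gene occurrence counts;
explicit node-level layers are materialized only up to a node cap, since
Q_t grows geometrically (the Fibonacci fiber's 40th layer has ~1.6e8
nodes). The branching ratio is reported as Q_depth/Q_{depth−1} at depth
40, which separates the canonical values 1, φ = 1.6180… and 2 far beyond
the 4-decimal reporting precision. Fiber classes carry the |n, ℓ⟩ label:
ℓ counts distinct regulator *fibers* outside the fiber's
strongly-connected loop core; the generalized recurrence
Q_t = nQ_{t−1} + mQ_{t−d} is fitted exactly over small integers when one
exists (AR: (1, 0, ·); Fibonacci: (1, 1, 2); n = 2: (2, 0, ·)).

A property worth knowing: two structurally identical circuits in disjoint
components genuinely share one fiber (their input trees are isomorphic,
and with identical parameters their dynamics synchronize across
components). The block finder therefore reports them as one match; any
distinguishing regulation of their inputs splits them.

## Circuit finding and grouping

Symmetric blocks are found by running the coloring, keeping non-trivial
fibers (size ≥ 2, or self-looped singletons), classifying each by
branching ratio, and grouping fibers generated by the same loop core (the
union of non-trivial strongly connected components in the fiber's
regulatory ancestry) into a single match — one loop can synchronize
several balanced classes, e.g. the Fibonacci circuit synchronizes {X, Z}
while {Y} carries the loop, and the two are one circuit, not two.

Flip-flop finders are constrained searches anchored on mutually
repressing pairs (rare in sparse networks), then extended role-by-role.
Sign constraints follow what the figures fix: the toggle pair must be
mutually repressing; input and stage edges are accepted with any sign,
exposed as the place to tighten if stricter conventions are wanted. The
JK search defaults to the parity (cross-feedback) wiring, the variant
realized in biological networks; the chiral variant is available on
request. Matches are de-duplicated by the unordered replica pair plus
input assignment, and overlapping matches are all reported (counts are
instances). Each finder is validated against an independent brute-force
role-enumeration matcher on random small networks.

## Null model

Randomization does repeated double-edge swaps within each sign class
(default 10× the edge count of attempts, a standard mixing heuristic),
rejecting proposals that would create duplicate ordered pairs or
self-loops; per-gene in/out degrees per sign are preserved exactly.
Self-loops are frozen as their own invariant class, because
autoregulation status defines the AR fiber and a null that creates or
destroys autoregulation would not be comparing like with like. The SD in
the Z-score uses the population (divide-by-n) convention. Reported
conventions: "N/A" when the observed count is zero, "Inf" when the null
counts have zero spread below the observed count, with the conservative
bound form "> 3" available when the circuit never occurs in the ensemble.

## Synthetic data

`embed_circuits` plants canonical circuits node-disjointly in a random
background: background genes receive directed edges with a 2:1
activator:repressor ratio (typical of curated transcriptional networks;
the ratio is configurable) and density of about 1.5 edges per gene,
drawn uniformly with sources anywhere and targets restricted to
background genes. That restriction is the load-bearing guarantee: planted
genes keep their exact signed in-edge structure, so planted fibers and
flip-flop patterns can never be destroyed by embedding — the background
can only add further true instances, which the brute-force oracle
confirms are real. What this generator does *not* emulate: the heavy-
tailed out-degree distributions, autoregulation density and cross-talk of
real species networks. Passing the planted-recovery tests therefore shows
correctness of the finders, not that real-network counts or Z-scores will
match any particular species table — reproducing those requires the
curated species databases themselves, which are deliberately out of
scope.

## Problem sizes and numerical choices

Test and validation runs use: 500–2000 dynamics steps (transients decay
like β^t, so 500 steps reach fixed points to ~1e−10 for the α used);
depth 40 input trees; 200-gene planted networks over 20 seeds; 200 random
≤ 8-node networks for finder/oracle agreement; and 10–100 null replicates
in tests (the library default is 1000). All randomness is seeded;
hypothesis runs derandomized. Floating-point tolerances: 1e−9 for
closed-form/map agreement and synchronization (observed ~1e−13), 1e−6
for fixed-point convergence, 1e−3 for branching-ratio class assignment.

## Known limitations

- Continuous-time (delay-ODE) and stochastic dynamics are not modelled.
- The dynamics module rejects unknown-sign edges rather than guessing.
- `sat_classify` is exhaustive over ≤ 20 genes by design (circuit scale).
- Fiber-block grouping can, on dense random backgrounds, merge many
  weakly-related background fibers into one "other"-class match; planted
  and curated circuits are unaffected because their ancestry is confined.
- Species-network counts require external curated databases and are not
  shipped or reproduced.
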