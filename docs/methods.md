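# Methods

## Model

`elnet` simulates a conserved population of `N = 2^n` bit-string
individuals adapting toward a fixed n-bit target under incomplete
information, and measures the weighted directed network formed by their
state transitions.  The model's assumptions:

* **Conserved resource.** The number of individuals never changes; nodes of
  the transition network are *occupied states*, so node and edge counts can
  both grow and shrink over time.  Total edge weight in a window of `w`
  steps is exactly `w·N`.
* **Partial observability.** One target digit (`k`, redrawn uniformly each
  step and shared by the population) is hidden; its fitness bit is a fair
  coin per individual.  This is the model's only noise source at
  stationarity.
* **Global overestimation.** Before updating, every individual's local
  fitness word is replaced through a quotient-lattice construction: the
  step's fitness words generate a lattice `L` (bitwise OR/AND closure), a
  uniformly drawn element `x ∈ L` defines the principal ideal `↓x`, and
  each word is replaced by the join of its class under the smallest
  congruence collapsing `↓x`.  Since bit-string lattices are distributive,
  that congruence has the closed form `a ≡ b ⟺ a∨x = b∨x`, and the class
  join of `b` is simply `b ∨ x` — the replacement is an overestimate (more
  frozen digits), never an underestimate.  The closed form is validated in
  the test suite against a brute-force smallest-congruence closure on all
  tested lattices with ≤ 32 elements.
* **Synchrony.** All individuals update at once from the same pre-step
  state matrix (two-buffer update); no individual sees another's new state.

The control model replaces the lattice step with independent erosion of
fitness 1-bits at probability μ, leaving everything else unchanged.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `n` | — | bit length; population size is `2^n` (dimensionless) |
| `steps` | — | synchronous time steps per trial |
| `burn_in` | 200 | steps discarded before any window is measured |
| `mu` | 0.0 | control-model erosion probability per fitness 1-bit, in [0,1] |
| `target` | random | fixed n-bit target word of the trial |
| `lattice_mode` | `generated` | `generated` closes the step's fitness set; `full-boolean` uses all of {0,1}^n (sensitivity option) |
| `ideal_rule` | `uniform-L` | ideal generator drawn uniformly over the lattice; `uniform-B` draws over the step's distinct fitness words |
| `control_flip` | `mu` | direction of μ; the `one-minus-mu` variant is kept selectable |
| window length | 200 | steps per transition-network window (20-step windows for the short-interval comparison) |

Headline ensembles use `n = 8` (256 individuals), 100 trials of 400 steps
(burn-in 200 + one 200-step window); the sliding-window ensembles use 16
trials of 1600 steps, i.e. ~1200 overlapping windows per trial at stride 1.
These sizes were chosen so a full reproduction completes in minutes on one
CPU while keeping ensemble standard errors well below the published spreads
being compared against.

All randomness comes from one `numpy` generator per trial with a documented
draw order (hidden position → hidden-bit guesses → ideal draw → update
words, each update consuming one full-width word per individual regardless
of its fitness pattern), so trials are byte-reproducible from `(config,
seed)` and insensitive to how many digits happen to be free.

## Measurement conventions

Two standard conventions exist for each of the headline statistics and the
sources being reproduced do not state theirs; both are implemented:

* **Clustering**: average local clustering vs transitivity (triangle
  ratio), both on the undirected simple projection with self-loops removed.
* **Mean degree**: undirected `2E/|V|` vs directed `E/|V|`, self-loops
  excluded.  Library defaults are average-local and undirected.
* **μ direction**: a fitness 1-bit flips to 0 with probability μ (error
  grows with μ) or `1−μ`.

The reproduction and acceptance paths fix one combination — *transitivity,
directed, flip-with-μ* — calibrated once against the published control-model
reference values (control at μ = 0.005: measured C ≈ 0.43 vs reference
0.474; MD ≈ 9.2 vs 9.25; the `1−μ` variant yields MD ≈ 200 and is clearly
wrong under the stated monotonicity of error in μ).  The chosen conventions
are recorded in every report.

Weight statistics (weight distribution, renormalized weight variance,
Hamming profile) always include self-loops: a self-transition carries
conserved resource, and excluding it would break the `Σw = w·N` identity.
The Hamming weight profile attributes an edge's weight to the distance of
its *destination* state from the target, since in-flow concentration near
the target is the phenomenon of interest.

## Distribution fits

Degree and weight distributions are fitted by maximum likelihood on the
discrete supports `k ≥ xmin` with `xmin = 1` (no xmin optimization, since
single global exponents are reported):

* discrete exponential `p(k) ∝ e^{−λk}`: closed form
  `λ̂ = ln(1 + 1/(mean − xmin))`, verified against numeric likelihood
  maximization;
* discrete power law `p(k) ∝ k^{−α}`: numeric maximization of the
  Hurwitz-zeta likelihood (bounded scalar optimization on α ∈ (1, 25]);
* model evidence: Akaike weights across the two one-parameter families;
* standard errors from the numerical curvature of the log-likelihood at
  the MLE.

Synthetic draws for the recovery tests use exact inversion: shifted
geometric for the exponential and vectorized bisection on the zeta CCDF for
the power law (no continuous approximation), chi-square-checked against the
exact pmf.  Parameter recovery is verified within 3 SE at 10⁴ samples over
λ ∈ {0.1, 0.226, 0.5} and α ∈ {1.4, 1.55, 2.5}, and AIC family selection is
≥ 95% correct at that size.

## Series analyses

Sliding windows advance by removing the leaving steps' transition counts
and adding the entering steps' (dense count table over transition codes),
and are exactly equal to from-scratch builds — an identity the tests check
edge map by edge map.  Recurrence of a windowed statistic to its long-run
mean is operationalized as sign changes of the centered series, with exact
hits counted as events; recurrence times are the gaps between consecutive
events in window-shift units.  This is the simplest mean-crossing rule; it
is recorded in output metadata because other operationalizations (e.g.
ε-bands) would lengthen the times systematically.  Phase-plane trajectories
of (MD, weight variance) report the shoelace signed area (orientation), the
path length, and the first-to-last closure distance.

## What the generator does and does not emulate

The simulation *is* the study system — there is no external data.  What
passing tests demonstrate is therefore internal: algebraic identities
(closure, congruence, conservation), estimator correctness on synthetic
draws, and the reproducibility of ensemble statistics under the documented
conventions.  They do not demonstrate that this implementation matches the
unpublished details of the reference implementation; the supplementary
algorithm text those details live in was not available, and two of its
choices (how the per-step lattice is constructed, how the ideal generator
is drawn) are exposed as options rather than asserted.

## Known limitations

* **Concentration statistics of the EL model.**  With the algorithm as
  implemented, new mismatches (created at the hidden digit) and corrections
  of existing ones are both gated by the same probability that the drawn
  ideal element has a 0 at the relevant digit.  A mean-field balance then
  pins the stationary mean Hamming distance to the target near 0.5 — for
  *any* ideal-draw distribution — and the population concentrates tightly
  around the target.  The acceptance checks show the consequences: measured
  C ≈ 0.33, MD ≈ 6.1, max in-degree ≈ 40 and ≈ 100% of edge weight within
  Hamming distance 3, versus published reference values of 0.133, 5.00,
  24.9 and 70% that imply a broader stationary spread (mean distance ≈ 2–3)
  with predominantly single-digit moves.  Sensitivity variants
  (`full-boolean` lattice, `uniform-B` ideal draw, guess-after-quotient
  ordering) do not close the gap.  The control model, the edge-weight
  power law (α ≈ 1.52/1.55 at 200-step windows, ≈ 1.55/1.48 at 20-step),
  and the mean-degree recurrence law (α ≈ 1.42/1.40) reproduce well.
* **Growth–decay cycle amplitude.**  The windowed MD/variance series do
  anticorrelate (pooled r ≈ −0.64 to −0.80 depending on snapshot spacing),
  but the cycle is weaker than the reference values suggest: the
  weight-variance series crosses its mean about half as often as the
  published exponential rate (0.017 vs 0.031 per window step) implies.
* Asynchronous updates, variable population sizes, multiple or moving
  targets, weighted clustering, and node-removal robustness experiments are
  out of scope.
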