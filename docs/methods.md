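# Methods

This note records the model, the numerical choices, and what the synthetic
experiments do and do not establish. It documents the package's own design;
every number quoted here is computed by the test suite or the acceptance
script.

## Model and assumptions

The learner is a multilayer perceptron with `L` fully connected ReLU hidden
layers of equal width `N`, inputs `x ∈ R^{N0}`, pre-activations scaled by
`1/√fan_in`, readout scaled by `1/√N`, and i.i.d. Gaussian weights
`W ~ N(0, σ²)`. Learning is modeled as the zero-temperature limit of a Gibbs
posterior over weights with an L2 ridge and a quadratic *perturbation
penalty* `λ‖Θ_t − Θ_{t−1}‖²` coupling consecutive tasks: at `β → ∞` the
network interpolates each task's training data, and the penalties select
*which* interpolator — `λ = 0` forgets everything between tasks, `λ → ∞`
makes the minimum change that fits the new data. We work exclusively with
deterministic point solutions of this limit; finite-temperature sampling is
out of scope.

Two regimes are treated by separate components:

**Single head** (`clforget.singlehead`). One readout shared by all tasks,
hidden weights held fixed at their random draw (the wide-network
approximation: training barely moves hidden weights). Sequential learning is
then minimum-change interpolation of the readout, with closed-form updates.
Forgetting of task 1 at step `t` is the normalized training MSE `F_{t,1}`.
In this regime the order parameters of `clforget.order_params` predict
`F_{2,1} = 2(γ_RF − γ_rule)` for task pairs with statistically symmetric
relations; the relation is verified on a synthetic grid to an aggregate
relative RMS deviation of a few percent.

**Multihead** (`clforget.multihead`). A dedicated readout per task, a single
hidden layer (`L = 1`), two tasks, and finite load `α = P/N`, where hidden
weights *can* move. The phase structure in `(α, γ_sim)` — FR / OF / G with
`α_c = γ_sim⁻²` — is implemented as theory (`critical_load`,
`classify_regime`) and validated by direct simulation.

Both feature routes are exposed everywhere: explicit finite-width features
(seeded, stochastic) and the depth-`L` arc-cosine (NNGP) ReLU kernel as the
infinite-width Gram limit. The kernel path is deterministic and is the
default for order parameters and single-head grids. The dual-path agreement
(to 1e-8 against a brute-force projector oracle at small width, and within
0.02 between width-20000 Grams and the kernel) is the module's core oracle
test.

## Synthetic data

All experiments run on synthetic stimulus pools: i.i.d. standard-normal
vectors, row-normalized to `‖x‖ = √N0` so kernel angles are well defined and
`σ` is interpretable. Three protocols control task relations:

* **target-distractor** — `ρ_shared` (fraction of stimuli reused across
  tasks), `ρ_target` (fraction of ±1-labelled stimuli on the shared set),
  `ρ_flip` (probability of flipping a shared target label relative to task
  1), `target_fraction` (±1 vs. 0 labels; default 0.5). Fractional counts
  round half away from zero and are recorded in task metadata. When the
  requested `ρ_target` is inconsistent with the shared count, the
  shared-target count is clamped to the feasible interval by default (the
  knob saturates); a strict mode raises instead. Flips are applied relative
  to task 1, not chained, so all pairs `(1, t)` share one statistical
  relation.
* **permutation** — each task permutes a fresh random subset of
  `round(ratio·N0)` input coordinates (at least 2 when the ratio is
  positive); per-example norms are exactly preserved.
* **split** — disjoint class groups per task, binarized by per-task balanced
  random dichotomies; `split_ratio_pair` replaces a controlled fraction of
  task 1's examples to interpolate between identical and disjoint tasks.

What the Gaussian pools emulate: controllable subspace overlap, rule
agreement, and load. What they do not: the covariance structure, sparsity,
and label-geometry alignment of natural images; heavy-tailed norms; any
within-task correlation between stimuli. Passing tests therefore establish
the *mechanics* of the theory (OP algebra, interpolation dynamics, phase
boundaries) under clean conditions, not performance claims on real datasets.
Loaders for NPY/CSV/IDX matrices let users point every analysis at their own
data.

Test sets are perturbed training inputs: `X' = normalize(X + ηZ)` with `Z`
standard normal, so the expected perturbation is a fraction `η` of the input
norm. Default `η = 0.1`.

## Numerical choices

* **Gram inversions** add relative jitter `ε = 1e-10 · Tr(G)/P` to the
  diagonal (configurable); Cholesky factorization with a conditioning error
  that reports the condition number when a block is not positive definite
  beyond the jitter.
* **Kernel recursion** clips cosines to `[−1, 1]` before `arccos` rather than
  raising; a negative self-kernel raises, since it signals broken input
  normalization.
* **P12 is never materialized.** All bilinear forms reduce to `P×P` Gram
  algebra through the dual coefficients `u_i = G_ii⁻¹ Y_i/‖Y_i‖`; the
  explicit `N×N` path exists only as the validation oracle.
* **Finite-width order parameters** average over 40 feature seeds by default
  and report the across-seed spread, since single-draw values fluctuate at
  O(1/√N). Note that finite-width OPs are systematically biased relative to
  the kernel limit at practical widths (e.g. `γ_sim` at `N = 300` sits
  noticeably below its kernel value); comparisons against the multihead
  trainer therefore use the finite-width OP at the trainer's width.
* **Exponential fits** exclude `t = 1` (identically zero), seed a 200-point
  log grid of time constants in `[0.1, 10T]` with the exact linear solution
  for `F_max` per candidate, then refine by bounded least squares. An
  all-zero curve returns a degenerate marker; a relaxation-free curve pins
  `τ_F` at the lower bound with a warning.
* **Multihead trainer.** The head is eliminated analytically at every
  optimizer step (exact ridge solve; by the envelope theorem its gradient
  contribution vanishes), and L-BFGS runs on the hidden weights alone — this
  removes the stiff head direction from the quasi-Newton problem. `λ → ∞` is
  realized as: head-only least squares if it already interpolates (the exact
  minimum-perturbation solution, used for `α < 1`); otherwise a vanishing-
  regularizer continuation, minimizing
  `½‖r‖² + ½ε(‖W − W₁‖² + κ‖a₂‖²)` over a geometric ladder of `ε` with warm
  starts until the fit interpolates (normalized loss ≤ 1e-8) and `‖ΔW‖`
  stabilizes within 1%. The head tie-break weight `κ = 1e-6` keeps the head
  norm infinitely cheaper than weight changes, as the `λ ≫ σ⁻²` limit
  requires; it is what lets the overfitting regime express its diverging
  `‖a₂‖²/N`. Task 1 uses the same solver with reference `W₀` and equal
  weights, stopping at the first interpolating stage (its cost has no
  perturbation penalty to minimize). `λ = 0` re-learns from the original
  initialization, matching fresh training exactly.
* **Problem sizes.** The phase-transition validation runs at width `N = 300`
  with `N0 = 150` and loads up to 3.4 (single seed per load, six grid loads);
  the λ-sweep at `N = 150`, `α = 3`, eight penalties. Larger sizes sharpen
  the transitions but change nothing qualitatively.

## Design choices where the design was open

* The infinite-width limit is the standard depth-composed arc-cosine (NNGP)
  ReLU kernel, bias-free, matching the bias-free network definition.
* The variance decomposition of forgetting statistics over the three OPs
  uses LMG relative importance (incremental R² averaged over all predictor
  orderings, normalized to sum to one) — chosen for ordering invariance.
* The empirical phase boundary is the first load at which seed-averaged
  `F_{2,1}` exceeds 0.01, linearly interpolated between grid points.
* `G_{2,2}` is normalized by the solo-learning baseline `G₂⁰` (≥ 5 fresh
  seeds); `G_{2,1}` is normalized by the analogous task-1 baseline when one
  is supplied, else reported raw.
* The learned component of the representation-similarity matrix subtracts
  the kernel under the random initialization `W₀`; the block score is mean
  within-class minus mean between-class similarity of that component.

## Known limitations

* The full finite-`λ`, finite-`α` posterior theory is not implemented; all
  simulations are point estimates. Quantities that are Gibbs averages in the
  theory are approximated by single minimizers, which smooths the sharp
  theoretical transitions at finite size.
* The continuation solver finds a local minimum-perturbation interpolator
  near the previous weights. Forgetting magnitudes just above `α_c` are small
  and grow smoothly, so threshold-based estimates of `α_c` carry ~10–20%
  uncertainty at `N = 300`.
* **Depth effects are regime dependent.** In this fixed-feature kernel model,
  two-task forgetting on permutation pairs *decreases* with depth only when
  examples greatly outnumber input dimensions (`P ≫ N0`, the analog of image
  benchmarks whose effective input rank is far below the sample count); for
  `P ≲ N0` deeper kernels amplify conflict instead, and at very small
  permutation ratios the depth profile is U-shaped. The depth-trend tests
  therefore run at `P/N0 = 5` and assert rank correlations, and conclusions
  about depth should not be extrapolated outside that regime.
* Multihead theory and trainer cover `T = 2` tasks and one hidden layer
  only; longer sequences and task-identity embeddings are out of scope.
* Single-head anterograde effects are not analyzed (they vanish in the
  infinite-width limit this package works in).
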