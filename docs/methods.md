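# Methods

## Model

The network is a strict generative hierarchy of rate neurons. Membrane
potentials `u_0 … u_n` (level 0 is the observation) emit rates
`r_ℓ = φ(u_ℓ)`; level `ℓ+1` predicts level `ℓ` with a diagonal Gaussian
whose mean `μ_ℓ = W_ℓ r_{ℓ+1}` and confidence (inverse variance)
`π_ℓ = A_ℓ r_{ℓ+1}` are both linear functions of the higher-level rates.
Confidence is therefore context-dependent: it changes with the higher-level
representation on the timescale of inference, while the weights `A_ℓ` learn
the statistics of the environment on the slow timescale.

The single scalar objective is

    E = Σ_{ℓ=0}^{n−1} [ ½ e_ℓᵀ diag(π_ℓ) e_ℓ − ½ Σ_i log π_{ℓ,i} ],
    e_ℓ = u_ℓ − μ_ℓ,

the negative log-joint of the hierarchy (up to `Σ_ℓ d_ℓ/2·log 2π`) with a
uniform prior on the top level. The first term measures errors in predicted
standard deviations (diagonal Mahalanobis distance); the second penalises
vanishing confidence and is what makes the confidence estimate
error-correcting rather than collapsing. Only diagonal covariances are
modelled; the state is a point estimate (MAP), never a sample.

Assumptions worth stating: a strict chain (each level predicted only by the
level above), rates and confidences non-negative (guaranteed by the
rectifier/softplus activations together with positive `A`), and Gaussian
predictive distributions.

## Inference dynamics

Representations relax by explicit Euler integration of confidence-
preconditioned gradient descent,

    τ u̇_ℓ = −π_ℓ⁻¹ ∘ ∂E/∂u_ℓ = −u_ℓ + μ_ℓ + π_ℓ⁻¹ ∘ a_ℓ,
    a_ℓ = φ′(u_ℓ) ∘ (W_{ℓ−1}ᵀ(π_{ℓ−1}∘e_{ℓ−1}) + A_{ℓ−1}ᵀδ_{ℓ−1}),
    δ_ℓ = (π_ℓ⁻¹ − e_ℓ²)/2.

The metric `π_ℓ⁻¹` makes the confidence of incoming predictions divide a
neuron's integration of bottom-up errors (prior confidence, divisive), while
the confidence of outgoing predictions multiplies the errors they entail
(data confidence, multiplicative). The two published forms of the dynamics
(metric-scaled gradient vs. leak + prediction + modulated error) are
algebraically identical; a test asserts the implementation satisfies both to
1e-10.

Level conventions: the top level has a uniform prior, hence no local error
term and no leak — it integrates the pure bottom-up gradient `τu̇_n = a_n`.
An unclamped observation level relaxes toward its top-down mean. Clamped
levels never move.

### Numerical choices

* **Integration**: explicit Euler, default `dt/τ = 0.05`, `max_steps = 2000`.
  Stability requires `dt/τ` small relative to the largest curvature of the
  preconditioned flow (roughly `π‖W‖²` for strong weights); the default is
  conservative for the weight scales used here, and a divergence guard
  aborts with the offending step and level on any non-finite state — no
  silent clipping.
* **Stopping**: largest componentwise potential change below `tol = 1e-6`;
  the residual descent-direction norm is reported for diagnostics. The
  continuous-time theory has no stopping rule, so this is an artifact
  choice.
* **Confidence floor** `ε = 1e-6`, applied inside the prediction step:
  `log π` and `π⁻¹` are undefined at zero, and positivity is only
  guaranteed while rates stay positive. Floored components are treated as
  constants in all gradients (subgradient 0 through the floor), keeping the
  computed gradients consistent with the computed energy.
* **Degenerate inputs**: with every level clamped, relaxation returns
  immediately (converged, zero steps). Ties in classification readouts
  resolve to the lowest index.
* **Batching**: every state array may carry a leading batch axis; the
  integrator then relaxes all problems in lock-step (used to classify
  evaluation sets and to evaluate energies on dense grids). The recorded
  energy of a batched state is the sum over the batch.

With positive rates (softplus, or rectifier states away from zero) the
dynamics provably descend `E`; the suite checks non-increase per step to
1e-9 on random clamped-data problems. With confidences held fixed
(diagnostic mode, second-order pathway off) the scalar-chain equilibrium is
the precision-weighted mean of data and prior — the Bayes-optimal
combination — verified to 1e-4 over a grid of confidence ratios.

## Learning

At (approximate) equilibrium both pathways take one gradient step on the
same energy:

    ΔW_ℓ = lr_W (π_ℓ∘e_ℓ) r_{ℓ+1}ᵀ,
    ΔA_ℓ = lr_A δ_ℓ r_{ℓ+1}ᵀ               (plain), or
    ΔA_ℓ = lr_A A_ℓ ∘ (δ_ℓ r_{ℓ+1}ᵀ)       (multiplicative, default).

The multiplicative rule scales the step by the current weight, so weights
cannot cross zero in continuous time; in discrete time the per-entry step
factor is additionally clipped to [0.5, 1.5], which makes positivity
unconditional. The plain rule is kept because it is the exact negative
gradient (used in the finite-difference audits); if it undershoots, entries
clip at the confidence floor with a logged warning. Confidence weights are
capped at `π_max = 1e4` so degenerate zero-variance data cannot push the
estimate to infinity (logged when hit).

Defaults: `lr_W = 0.01`, `lr_A = 0.005`, 30 epochs, online updates (one per
presented sample, shuffled per epoch). `A` initialises uniform on
[0.5, 1.5] (positive, as the multiplicative rule requires), `W` as
Normal(0, 0.1²). Training clamps the observation to the data vector and the
top level to the one-hot target; hidden levels (absent in the two-level
networks used by the experiments) relax to equilibrium first, initialised
at 0.5 so rectifier gradients can flow.

Because the stochastic updates never stop, `W` fluctuates around the class
mean with equilibrium standard deviation ≈ `sqrt(lr_W·π·σ²/2)`. Where a
clean parameter estimate matters (the confidence-recovery demo and the
classification experiment), the harnesses therefore use a smaller
`lr_W = 0.002` with 40 epochs: at the spec-level defaults the jitter is of
the same order as the quantity being estimated for tight-variance contexts.

## Synthetic tasks

All data are generated internally from labelled diagonal-Gaussian class
specifications (exact class balance, deterministic in the seed).

* **Built-in classification tasks** (2-D, two classes, 1000 samples per
  class): `crossed_ellipses` — equal means, variances (1, 0.04) vs.
  (0.04, 1); `same_mean_nested` — equal means, variances (1, 1) vs.
  (0.04, 0.04). Both share class means exactly, so any decision rule
  reading only first-order (mean) structure is at chance by construction;
  the 3σ ("99.7%") ellipses of the two classes cross or nest. The precise
  variances are canonical choices; what matters is the defining equal-means
  property.
* **Maximum-likelihood oracle**: argmax of the true class log-densities —
  the perfect-knowledge upper bound for every learned mode.
* **Cue integration**: a fixed-confidence chain with one clamped
  observation component per cue and a clamped context unit providing the
  prior; the free latent settles at the precision-weighted mean. The Euler
  step is chosen as `dt = τ·π_prior / (2(π_prior + Σπ_cues))` so the linear
  dynamics stay contractive for arbitrarily confident cues.
* **Confidence learning**: scalar observations drawn per clamped one-hot
  context; after training, column `k` of `W` and `A` hold the learned mean
  and confidence of context `k`, reported against the ground truth
  `(m, 1/σ²)` together with the post-convergence calibration of `δ`
  (evaluated on the training set, whose empirical statistics are what the
  weights can converge to).

What the generator does *not* emulate: non-Gaussian or correlated noise,
covariate shift between train and test (evaluation uses fresh draws from
the same distributions), temporal structure, and input dimensionalities
beyond desk scale. Passing tests therefore demonstrate correctness of the
mechanism on matched-model data, not robustness on natural stimuli.

## Classification experiment

A fresh 2×2 network is trained on a built-in task (observation and class
levels clamped; learning reduces to the two local rules) and evaluated on
1000 held-out draws in three modes: full confidence dynamics, the classical
predictive-coding baseline (unit confidence, no second-order pathway, same
trained `W`), and the maximum-likelihood oracle. At test time the class
level starts at (0.5, 0.5) — an unbiased positive start — and the most
active class neuron is read out at convergence.

A structural finding from this implementation: on `same_mean_nested` the
calibrated confidence map is rank-1 (both classes are isotropic, so the two
columns of `A` are proportional), which leaves the top-level energy with an
exactly flat valley. The infinite-time equilibrium then drifts to a corner
of that valley under the force of the `W` pathway — which on an equal-means
task carries no class signal, only the finite-sample error of the class-mean
estimate (σ/√N ≈ 0.03 at N = 1000, amplified ~25× along the soft mode).
Typical held-out accuracy is therefore ≈ 0.80–0.86 against an oracle at
≈ 0.92, while the classical baseline stays near chance (0.47–0.56); the
qualitative ordering (confidence ≫ classical, both bounded by the oracle)
is robust, but the residual oracle gap is noise-limited, not a convergence
failure. On `crossed_ellipses` the confidence map is full-rank, the
equilibrium is well-posed, and the gap to the oracle shrinks to ≈ 0.02.

## Known limitations

* Diagonal (per-neuron) confidence only; no full inverse-covariance metric
  and no scalar/global confidence variants.
* The preconditioner treats predictions as fixed; it is an approximate
  second-order scheme, not the exact Hessian.
* Gradient-based relaxation can in principle settle in a local minimum of
  `E`; the brute-force equivalence checks use weight scales for which the
  free-latent energy is well-behaved.
* Weight transport (the transposes in `a_ℓ`) and one-to-one error wiring
  are assumed, as in classical predictive coding.
* The identity activation violates rate positivity and exists only for
  closed-form tests; it warns once on use.
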