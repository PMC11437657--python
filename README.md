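# confpc — predictive coding with learned confidence and second-order errors

`confpc` is a simulator and library for hierarchical Gaussian
predictive-coding networks in which every level of the hierarchy predicts
not only the *mean* activity of the level below but also the *confidence*
(inverse variance) of that prediction, and in which mismatches between
predicted confidence and realised error — *second-order errors* — are
propagated and learned just like ordinary prediction errors. It is aimed at
computational neuroscientists who want a small, fully tested rate-based
model to study confidence weighting, Bayesian cue integration, and
variance-driven (nonlinear) classification without any external data.

## Model

Representations `u_0 … u_n` (with `u_0` the observation) form a strict
generative hierarchy. Level `ℓ+1` sends rates `r_{ℓ+1} = φ(u_{ℓ+1})` through
two top-down pathways:

    μ_ℓ = W_ℓ r_{ℓ+1}        (predicted mean)
    π_ℓ = A_ℓ r_{ℓ+1}        (predicted confidence = inverse variance)

Inference and learning both descend one energy, the negative log-joint of
the implied hierarchical Gaussian model with a uniform top-level prior:

    E = Σ_ℓ [ ½ ‖e_ℓ‖²_{π_ℓ} − ½ Σ_i log π_{ℓ,i} ],     e_ℓ = u_ℓ − μ_ℓ

The first term is a diagonal Mahalanobis distance — errors measured in
predicted standard deviations; the second rewards confident prediction.
Inference follows confidence-preconditioned gradient descent

    τ u̇_ℓ = −π_ℓ⁻¹ ∘ ∂E/∂u_ℓ = −u_ℓ + μ_ℓ + π_ℓ⁻¹ ∘ a_ℓ

with the total propagated error combining confidence-weighted first-order
errors and second-order errors `δ_ℓ = (π_ℓ⁻¹ − e_ℓ²)/2`:

    a_ℓ = φ′(u_ℓ) ∘ ( W_{ℓ−1}ᵀ (π_{ℓ−1} ∘ e_{ℓ−1}) + A_{ℓ−1}ᵀ δ_{ℓ−1} )

At equilibrium, both weight pathways learn through local Hebbian-style
rules: `ΔW_ℓ ∝ (π_ℓ ∘ e_ℓ) r_{ℓ+1}ᵀ` and `ΔA_ℓ ∝ δ_ℓ r_{ℓ+1}ᵀ` (by default
in a multiplicative variant, `ΔA_ℓ ∝ A_ℓ ∘ (δ_ℓ r_{ℓ+1}ᵀ)`, which keeps
confidence weights positive). `δ` has zero mean exactly when confidence is
calibrated to the true inverse variance, so the `A` pathway is an
error-correcting estimator of uncertainty.

A classical predictive-coding baseline (unit confidence, no second-order
pathway) and a fixed-confidence diagnostic mode (constant `π`, exposing the
closed-form precision-weighted Bayesian equilibria) share the same
integrator.

## Worked example

The flagship experiment is a 2-D binary classification task whose two
classes share the same mean and differ only in variance (a broad isotropic
class with a tight one nested inside), so first-order prediction errors
carry no class information. A 2×2 network (two observation neurons, two
class neurons) is trained by clamping the observation to the data and the
class level to the one-hot label; at test time the class level relaxes
freely and the most active neuron is read out.

```
$ confpc make-data --task same_mean_nested --n 1000 --seed 0 --out demo/data
INFO confpc: wrote 2000 samples to demo/data/dataset.csv

$ confpc train --data demo/data/dataset.csv --out demo/run \
      --epochs 40 --lr-w 0.002 --seed 0
INFO confpc: epoch 39: mean energy -0.59955
INFO confpc: checkpoint written to demo/run/checkpoint.json

$ confpc evaluate --checkpoint demo/run/checkpoint.json \
      --data demo/data/dataset.csv --spec demo/data/dataset.json \
      --out demo/eval --seed 0
INFO confpc: confidence accuracy: 0.8430
INFO confpc: classical accuracy: 0.5285
INFO confpc: ml_oracle accuracy: 0.9265
```

The full confidence dynamics solve the task (0.84, in-sample here), the
classical predictive-coding baseline is at chance (0.53 — both classes have
the same mean, so minimising Euclidean distance to the point prediction is
uninformative), and the maximum-likelihood rule with perfect knowledge of
the generating means and variances (0.93) upper-bounds both learned modes.

Cue integration in fixed-confidence mode reproduces the precision-weighted
Bayesian combination of a prior with noisy cues at equilibrium:

```
$ confpc demo-cue-integration --prior-mean 0 --prior-conf 1 --cue 2,3 --cue -1,0.5
network equilibrium estimate: 1.222219
precision-weighted closed form: 1.222222
```

Other subcommands: `infer` (relax one observation and print the top-level
estimate), `gradcheck` (finite-difference audit of the analytic gradients),
`demo-confidence-learning` (recover context-conditional means and inverse
variances), all with YAML config files and flat flag overrides.

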