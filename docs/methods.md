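# Methods

## Model

The predictor is a one-hidden-layer autoencoder with a regression branch.
For an input `x ∈ R^m` (robust-scaled morphometric features):

- encoder: `z = act(W_φ x + b_φ)`, `z ∈ R^n`, activation ReLU by default
  (tanh available);
- decoder: `x' = W_θ z + b_θ` (linear output);
- regression head: `y' = w_ψ·z + b_ψ` (linear; a config option inserts one
  hidden layer into the head).

Both heads share the encoder, so the code `z` is shaped by two tasks at
once. The training objective over a batch is

```
L = w_r · mean_i ‖x_i − x'_i‖²  +  w_y · mean_i (y_i − y'_i)²
  + λ_θ‖θ‖² + λ_φ‖φ‖² + λ_ψ‖ψ‖²
```

with `w_r = w_y = 1` and `λ = 0.1` per parameter group by default. The MLP
ablation drops the decoder and its two terms; everything else is identical.

This is the smallest architecture consistent with the method: depth,
activation, optimizer and batch size are genuinely open choices and are all
exposed in `TrainConfig`.

### Reconstruction-error convention

The reconstruction distance is the squared L2 norm of the residual vector —
a **sum over features**, averaged over the batch. The alternative
convention (additionally averaging over features) makes the data terms an
order of magnitude smaller than the `λ = 0.1` penalties whenever the scaled
features have sub-unit variance (robust scaling by the 5–95 percentile range
leaves variance ≈ 0.09 for near-Gaussian features). Under that convention
both AE and MLP converge within a few epochs to essentially the same
ridge-limited solution — train and test error coincide, nothing overfits,
and the multi-task mechanism has nothing to improve. With the sum
convention the data terms dominate, the networks genuinely fit, and the
reconstruction task demonstrably improves test MSE over the matched MLP.
Both conventions are implemented (`TrainConfig.recon_convention`).

### Squared-L2 penalties

"All parameters" is taken literally: biases are included in the penalties
by default (`penalize_biases=False` excludes them).

## Training protocol

- Full-batch gradient descent by default (`batch_size=None`); any minibatch
  size can be configured. Rationale: deterministic descent produces a
  smooth per-epoch validation curve, so the early-stopping rule below
  responds to actual overfitting. With small minibatches the validation MSE
  fluctuates epoch to epoch and the first-increase rule halts training
  almost immediately on noise.
- Learning rate `0.1 · 0.99^floor(epoch/5)`.
- Early stopping: training stops the first (1-based) epoch whose validation
  regression MSE exceeds the previous epoch's, and the previous epoch's
  parameters are returned. A `patience` parameter (default 1) generalizes
  this to `patience` consecutive increases.
- Hidden-size grid search ({50, 100, 200, 400} by default) selects the size
  whose returned parameters have the lowest validation MSE; ties go to the
  smaller size. Grid points that diverge are recorded as +inf and skipped.
- Gradients are analytic (plain backprop); the test suite checks them
  against central differences at 1e-5 relative tolerance. All randomness
  (initialization, shuffling) flows from one seed; identical config + data
  gives bit-identical training histories.

## Preprocessing

- Robust scaling per feature: `(x − median) / (p95 − p5)`, percentiles by
  linear interpolation between order statistics, fitted on **training
  subjects only** (a `scaler_scope="all"` switch reproduces pooled fitting
  for comparison with pipelines that normalize before splitting; the
  train-only default avoids test-set leakage). Features with `p95 == p5`
  are flagged constant and mapped to 0.
- Outcome standardized to zero mean / unit sample SD (ddof = 1) with
  training-set statistics; validation and test outcomes are transformed with
  the same parameters. Model predictions are mapped back to the raw scale
  before computing reported MSE/PCC.
- Split: train/val/test at overall ratios 0.56/0.14/0.30 — a 7:3
  train:test split with a validation fifth carved from the training share
  (the protocol needs a validation set for early stopping and grid search
  but its size is an open choice). Rounding: the pooled training share gets
  `floor(0.7·n)` subjects, the remainder is the test set, so 11534 subjects
  split 8073/3461; the validation set takes `floor(0.14·n)` of the share.

## Synthetic cohorts

The generator emulates the statistical regime the method assumes, not
neuroanatomy:

- **Features**: `X = Z W + ε` with `Z ~ N(0, I_k)` latent factors, `W`
  block-sparse (contiguous feature blocks assigned round-robin to factors,
  loading `loading_scale`, default 1), `ε ~ N(0, feature_noise_sd²)`
  (default 1). Within a factor group the pairwise correlation is
  `loading²/(loading² + σ²)` = 0.5 at defaults. The default full-scale
  structure (604 features in 8 near-equal single-factor blocks) puts
  ~12.4% of feature pairs above correlation 0.3, matching the regime
  reported for real morphometry tables.
- **Outcome**: an affine rescaling of `g(Z·β)` plus Gaussian noise, with
  `g` identity or tanh, calibrated by *analytic* population moments (tanh
  second moment via Gauss–Hermite quadrature) so that the population mean
  and SD equal `outcome_mean = 91.60` and `outcome_sd = 10.62` and the
  population R² of the latent signal equals `signal_r2` (default 0.2, a
  weak-signal regime). Because sample moments are never used, the
  calibration is a testable statistical property (±0.5 at n = 5000), not an
  identity.
- **Sex modulation**: subjects are male with probability 0.523 (the
  published cohort's composition); the standardized signal amplitude for
  females is `sex_effect_ratio` times the male amplitude, with per-subject
  noise absorbing the difference so outcome variance stays calibrated in
  both groups. Ratio > 1 raises the female subgroup's attainable
  prediction correlation.
- **Ground truth**: the latent factors and the planted signal-feature set
  (features loading on the first `n_signal_latent` factors) are recorded for
  recovery tests.

What the generator does **not** emulate: spatial smoothness, site/scanner
effects, non-Gaussian marginals, heteroscedastic noise, age effects.
Passing tests demonstrate that the machinery behaves as specified under the
stated statistical regime — not that the method attains any particular
performance on real neuroimaging data, which is access-restricted.

## Evaluation

- MSE `(1/N)Σ(y−ŷ)²` and Pearson correlation, both computed on the raw
  outcome scale.
- Uncertainty: subjects resampled with replacement (default 100 resamples);
  reports carry the bootstrap mean ± SD and the percentile 95% CI.
  Resamples with constant truth (PCC undefined) are skipped and counted.
- Subgroup comparison: `t = (r1 − r2)/√(s1²/n1 + s2²/n2)` with a two-sided
  normal p-value. When groups come from bootstrap evaluation, `s_i` is the
  subject-level dispersion `√n_i · bootSD(r_i)`, so `s_i²/n_i` is the
  squared standard error of `r_i` — the reading under which the two-sample
  formula is a calibrated z-test (measured type-I error ≈ 5–8% at nominal
  5%). Substituting the bootstrap SD directly would divide a standard
  error by √n a second time and reject nearly always under the null.
  A Fisher-z two-sample comparison (`method="fisher_z"`) is also provided.

## Shapley attribution

- Value function: marginal-expectation convention — absent features are
  replaced by values from a fixed background sample (default: 100
  training subjects drawn by seed), present features come from the
  instance; the coalition value is the background-averaged prediction.
- `exact_enumeration` averages marginal contributions over all coalitions
  (≤ 12 features); local accuracy, symmetry and the dummy axiom hold to
  machine precision, and for linear models attributions equal
  `w_i (x_i − mean_background(x_i))` exactly.
- `sampling` averages contributions along random feature permutations
  (default 20 per subject for population rankings); the telescoping sum
  keeps local accuracy exact, and per-feature error shrinks as 1/√P.
- Attributions are computed on the standardized-outcome scale. Population
  importance is the mean of |φ_i| over subjects; rankings sort descending
  with lexicographic tie-breaks. Subgroup rankings recompute the statistic
  per covariate level and report the top-k overlap.

## Numerical and design notes

- Percentiles: numpy's linear interpolation; SDs: sample convention
  (ddof = 1). Constant outcome columns are rejected (tolerance
  1e-12·|mean| for float residue).
- Weight init: seeded Gaussian with He fan-in scaling, zero biases.
- Divergence (non-finite objective) raises with the partial history
  attached; grid search treats a diverged point as +inf.
- The "LR" baseline is ordinary least squares — a logistic model cannot
  target a continuous score. Baselines consume the same scaled features and
  standardized outcomes as the networks and use library-default
  hyperparameters with pinned seeds; no tuning.
- Problem sizes in the test suite and acceptance script (2000-subject,
  60-feature cohorts; 10 seed replicates; 20 permutations × 200 subjects
  for SHAP) are chosen so the full suite runs in about a minute on one CPU
  while keeping every property comfortably measurable.

## Known limitations

- Exact Shapley enumeration is exponential; above 12 features only the
  sampling estimator is available.
- The first-increase early-stopping rule is sensitive to validation-curve
  noise if minibatch training is configured; use `patience > 1` there.
- Checkpoints serialize parameters to JSON (human-readable, diffable);
  fitted baselines are pickled and are not portable across library
  versions.
- With `sex_effect_ratio` far from 1 and large `signal_r2`, the implied
  female signal amplitude can exceed 1 (unit outcome variance); the
  generator rejects such configs rather than silently clipping.
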