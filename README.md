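# morphae

Predicting a continuous cognitive phenotype — a fluid-intelligence-like
score — from ROI-level brain-morphometry feature tables, using an
autoencoder whose reconstruction loss regularizes a shared regression
branch.

## The problem and the model

Morphometric feature tables (per-region volume, surface area, sulcal depth
and cortical thickness, e.g. 604 FreeSurfer measurements over the 148
Destrieux ROIs) are strongly redundant: a large fraction of feature pairs
are highly correlated, and the outcome signal is weak. A plain MLP
regressor extracts whatever directions fit the training outcomes, including
noise directions; a network that must *also* reconstruct its input is forced
to encode the correlation structure of the features, which improves
generalization of the regression head.

Concretely, an encoder `z = E_φ(x)` feeds both a linear decoder
`x' = D_θ(z)` and a regression head `y' = f_ψ(z)`, trained jointly on

```
L(θ, φ, ψ) =  E‖x − D_θ(E_φ(x))‖²  +  E(y − f_ψ(E_φ(x)))²
            + λ_θ‖θ‖² + λ_φ‖φ‖² + λ_ψ‖ψ‖²
```

with λ = 0.1 on each parameter group, learning rate 0.1 decaying by 0.99
every 5 epochs, hidden sizes chosen from {50, 100, 200, 400} by validation
grid search, and early stopping at the first epoch where validation MSE
rises. The MLP ablation is the identical encoder + head without the
decoder. Performance is measured by test-set MSE and the Pearson
correlation (PCC) between predicted and true scores, with bootstrap
uncertainty (100 resamples), evaluated overall and per sex subgroup (the
two subgroup PCCs are compared by a two-sample z statistic). Feature
importance is the population mean of absolute Shapley values per feature,
computed by exact coalition enumeration (≤ 12 features) or permutation
sampling.

Because the motivating cohort data are access-restricted, the package ships
a synthetic cohort generator (block-structured latent-factor features, an
outcome calibrated to mean 91.60 / SD 10.62, and a sex-modulated signal) so
the entire pipeline is testable end to end.

## Worked example

```
morphae simulate   --config configs/demo.yaml
morphae preprocess --config configs/demo.yaml
morphae train      --config configs/demo.yaml
morphae evaluate   --config configs/demo.yaml
morphae explain    --config configs/demo.yaml
morphae report     --config configs/demo.yaml
```

The demo config simulates 2000 subjects × 60 features (10 correlated
blocks over 5 latent factors) with the outcome signal planted in the 12
features loading on the first factor, splits 56/14/30, trains the AE, the
MLP ablation and four classical baselines, and prints:

```
Performance (point estimate ± bootstrap SD)
model                      train PCC           train MSE   ...      test PCC            test MSE
ae                   0.524 ±0.024     86.866 ± 3.563  ...  0.549 ±0.033     85.098 ± 4.774
linear_regression    0.538 ±0.025     83.758 ± 3.645  ...  0.523 ±0.033     86.253 ± 5.159
mlp                  0.533 ±0.023     89.302 ± 3.671  ...  0.546 ±0.032     88.894 ± 4.854
random_forest        0.974 ±0.002     12.663 ± 0.513  ...  0.519 ±0.032     86.815 ± 5.071
svr                  0.833 ±0.012     40.339 ± 2.544  ...  0.472 ±0.031     92.642 ± 5.348
xgboost              1.000 ±0.000      0.005 ± 0.000  ...  0.414 ±0.038    103.120 ± 6.230

Top features by population mean |SHAP| (AE)
feature                                    mean |SHAP|
volume.lh.roi004                                0.0456
area.lh.roi004                                  0.0453
volume.rh.roi000                                0.0424
...
top-k overlap between subgroups: 9
```

Reading it: the AE posts the lowest test MSE (85.1 vs 88.9 for the
matched MLP — the reconstruction-regularization benefit), tree models
overfit the training set (xgboost train MSE ≈ 0) without generalizing
better, and all ten top-ranked mean-|SHAP| features belong to the planted
signal set (features of `roi000`/`roi003`/`roi004`, the regions loading on
the outcome factor). MSE is on the raw score scale (outcome SD ≈ 10.6, so
variance ≈ 113); SHAP magnitudes are on the standardized-outcome scale.

`configs/paper_mode.yaml` runs the same protocol at the full published
scale (11534 subjects × 604 features, grid search, 100 bootstraps).

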