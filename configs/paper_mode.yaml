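# Full-protocol run on a synthetic cohort at the published study scale:
# 11534 subjects x 604 features, 7:3 train:test split (validation carved
# from the training share), robust percentile scaling, hidden-size grid
# search over {50, 100, 200, 400}, lambda = 0.1 on all three parameter
# groups, lr 0.1 decaying to 0.99x every 5 epochs, first-increase early
# stopping, 100 bootstrap resamples, SHAP rankings overall and per sex.
seed: 0
outdir: runs/paper_mode
datagen:
  n_subjects: 11534
  n_features: 604
  n_latent: 8
  signal_r2: 0.05          # weak signal, in line with reported PCC ~ 0.2
  sex_effect_ratio: 1.4
split:
  ratios: [0.56, 0.14, 0.30]
scaler_scope: train
grid_search: true
train:
  hidden_grid: [50, 100, 200, 400]
  lambda_theta: 0.1
  lambda_phi: 0.1
  lambda_psi: 0.1
  lr_init: 0.1
  lr_decay: 0.99
  lr_step: 5
  max_epochs: 100
baselines: [linear_regression, random_forest, svr, xgboost]
evaluation:
  n_boot: 100
interpret:
  estimator: sampling
  n_permutations: 20
  background_size: 100
  n_subjects: 200
  top_k: 10
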