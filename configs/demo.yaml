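# Small cohort that runs the whole pipeline in under a minute.
seed: 7
outdir: runs/demo
datagen:
  n_subjects: 2000
  n_features: 60
  n_latent: 5
  block_sizes: [6, 6, 6, 6, 6, 6, 6, 6, 6, 6]
  signal_r2: 0.3
  n_signal_latent: 1       # plants the outcome signal in 12 of 60 features
  sex_effect_ratio: 1.5
split:
  ratios: [0.56, 0.14, 0.30]
train:
  hidden_size: 100
  max_epochs: 100
baselines: [linear_regression, random_forest, svr, xgboost]
evaluation:
  n_boot: 100
interpret:
  estimator: sampling
  n_permutations: 20
  background_size: 100
  n_subjects: 100
  top_k: 10
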