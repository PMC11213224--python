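import numpy as np
import pytest

import morphae as m
from morphae.datagen import default_block_sizes


def reference_gen_config(seed: int = 0, **overrides) -> m.GenConfig:
    """The 60-feature / 10-block / 5-factor cohort used across tests."""
    kwargs = dict(
        n_subjects=2000,
        n_features=60,
        n_latent=5,
        block_sizes=tuple(default_block_sizes(60, 10)),
        signal_r2=0.2,
        seed=seed,
    )
    kwargs.update(overrides)
    return m.GenConfig(**kwargs)


def prepare_splits(cohort: m.CohortTable, seed: int = 0, ratios=(0.56, 0.14, 0.30)):
    """Split, scale and standardize; returns (assignment, target_scaler, parts).

    parts maps split name -> (X_scaled, y_standardized, y_raw).
    """
    assignment = m.split_cohort(cohort, ratios, seed)
    scaler = m.fit_robust_scaler(cohort, assignment)
    scaled = m.apply_scaler(cohort, scaler)
    tscaler = m.fit_target_scaler(cohort, assignment)
    parts = {}
    for part in ("train", "val", "test"):
        mask = assignment.mask(cohort, part)
        if mask.any():
            parts[part] = (
                scaled.features[mask],
                m.standardize_outcome(cohort.outcome[mask], tscaler),
                cohort.outcome[mask],
            )
    return assignment, tscaler, parts


@pytest.fixture(scope="session")
def ref_cohort() -> m.CohortTable:
    return m.generate_cohort(reference_gen_config())


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
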