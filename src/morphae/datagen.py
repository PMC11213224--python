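"""Synthetic cohort generator.

Emulates the statistical regime of a large adolescent neuroimaging cohort:
a few hundred strongly inter-correlated morphometric features (volume, area,
sulcal depth, cortical thickness per cortical region), a continuous cognitive
outcome with a fixed population mean/SD, and a sex-modulated latent signal so
that subgroup analyses have something to find.

Features follow a block-structured linear latent-factor model

    X = Z W + eps,   Z ~ N(0, I_k),  eps ~ N(0, sigma^2)

where W is block-sparse: the feature set is partitioned into contiguous
blocks and every feature in a block loads on a single latent factor (blocks
are assigned to factors round-robin, so with more blocks than factors some
blocks share a factor).  The outcome is an affine rescaling of a (possibly
tanh-saturated) linear read-out of the first ``n_signal_latent`` factors,
mixed with Gaussian noise so that the population R^2 equals ``signal_r2``
and the population mean/SD equal ``outcome_mean``/``outcome_sd``.  The
rescaling uses *analytic* population moments, never sample moments, so the
calibration is a statistical property one can test, not an identity.

Sex modulates the signal amplitude: with ``sex_effect_ratio = r`` the
standardized-signal coefficient for females is ``r`` times the male one,
while per-subject outcome variance stays 1 in standardized units for both
sexes (noise absorbs the difference).  ``r > 1`` therefore yields a higher
predicted-vs-true correlation ceiling in the female subgroup.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenConfig",
    "CohortTable",
    "generate_cohort",
    "correlation_census",
    "CorrelationCensus",
    "default_block_sizes",
    "write_cohort",
]

_MEASURES = ("volume", "area", "depth", "thickness")
_HEMIS = ("lh", "rh")


class ConfigurationError(ValueError):
    """Raised when a GenConfig is internally inconsistent."""


def default_block_sizes(n_features: int, n_blocks: int) -> list[int]:
    """Partition ``n_features`` into ``n_blocks`` near-equal contiguous blocks.

    The first ``n_features % n_blocks`` blocks get one extra feature.
    """
    if n_blocks < 1 or n_blocks > n_features:
        raise ConfigurationError(
            f"n_blocks must be in [1, n_features]; got {n_blocks} for {n_features} features"
        )
    base, extra = divmod(n_features, n_blocks)
    return [base + 1 if i < extra else base for i in range(n_blocks)]


@dataclass(frozen=True)
class GenConfig:
    """Configuration of the synthetic cohort generator.

    Defaults target the regime of the motivating study: 604 morphometric
    features over 148 cortical regions, an outcome distributed as
    91.60 (10.62), and a correlation structure in which roughly 12% of
    feature pairs correlate above 0.3 (8 factor groups of ~75 features with
    within-group correlation 0.5).
    """

    n_subjects: int = 1000
    n_features: int = 604
    n_latent: int = 8
    block_sizes: tuple[int, ...] | None = None  # None -> near-equal split into n_latent blocks
    loading_scale: float = 1.0
    feature_noise_sd: float = 1.0
    outcome_mean: float = 91.60
    outcome_sd: float = 10.62
    signal_r2: float = 0.2
    sex_effect_ratio: float = 1.0  # female:male standardized signal amplitude
    nonlinearity: str = "linear"  # or "tanh"
    seed: int = 0
    n_signal_latent: int | None = None  # factors carrying outcome signal; None -> all
    male_fraction: float = 0.523
    age_mean_months: float = 130.47
    age_sd_months: float = 14.30

    def resolved_block_sizes(self) -> list[int]:
        if self.block_sizes is None:
            return default_block_sizes(self.n_features, self.n_latent)
        return list(self.block_sizes)

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        if self.n_features < 1 or self.n_latent < 1:
            raise ConfigurationError("n_features and n_latent must be >= 1")
        sizes = self.resolved_block_sizes()
        if sum(sizes) != self.n_features:
            raise ConfigurationError(
                f"block_sizes sum to {sum(sizes)} but n_features is {self.n_features}"
            )
        if any(s < 1 for s in sizes):
            raise ConfigurationError("every block must contain at least one feature")
        if not 0.0 <= self.signal_r2 <= 1.0:
            raise ConfigurationError("signal_r2 must lie in [0, 1]")
        if self.outcome_sd <= 0:
            raise ConfigurationError("outcome_sd must be positive")
        if self.sex_effect_ratio <= 0:
            raise ConfigurationError("sex_effect_ratio must be positive")
        if self.feature_noise_sd < 0:
            raise ConfigurationError("feature_noise_sd must be >= 0")
        if self.nonlinearity not in ("linear", "tanh"):
            raise ConfigurationError(f"unknown nonlinearity {self.nonlinearity!r}")
        k_sig = self.n_latent if self.n_signal_latent is None else self.n_signal_latent
        if not 0 < k_sig <= self.n_latent:
            raise ConfigurationError("n_signal_latent must be in [1, n_latent]")
        if not 0.0 <= self.male_fraction <= 1.0:
            raise ConfigurationError("male_fraction must lie in [0, 1]")


@dataclass
class CohortTable:
    """Subjects x features table plus covariates, outcome and optional ground truth.

    ``frame`` holds columns ``subject_id, sex, age_months, outcome`` followed
    by one column per named feature.  ``ground_truth`` (synthetic cohorts
    only) records latent factor values and the planted signal-feature set.
    """

    frame: pd.DataFrame
    feature_names: list[str] = field(default_factory=list)
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        if not self.feature_names:
            reserved = {"subject_id", "sex", "age_months", "outcome"}
            self.feature_names = [c for c in self.frame.columns if c not in reserved]
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")

    @property
    def n_subjects(self) -> int:
        return len(self.frame)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    @property
    def subject_ids(self) -> np.ndarray:
        return self.frame["subject_id"].to_numpy()

    @property
    def sex(self) -> np.ndarray:
        return self.frame["sex"].to_numpy()

    @property
    def features(self) -> np.ndarray:
        """(n_subjects, n_features) float array in feature_names order."""
        return self.frame[self.feature_names].to_numpy(dtype=float)

    @property
    def outcome(self) -> np.ndarray:
        return self.frame["outcome"].to_numpy(dtype=float)

    def subset(self, mask: np.ndarray) -> "CohortTable":
        return CohortTable(
            frame=self.frame.loc[mask].reset_index(drop=True),
            feature_names=list(self.feature_names),
            ground_truth=self.ground_truth,
        )

    def with_features(self, X: np.ndarray) -> "CohortTable":
        """Return a copy whose feature columns are replaced by ``X``."""
        if X.shape != (self.n_subjects, self.n_features):
            raise ValueError("replacement feature matrix has wrong shape")
        frame = self.frame.copy()
        frame[self.feature_names] = X
        return CohortTable(frame, list(self.feature_names), self.ground_truth)


def _feature_names(m: int) -> list[str]:
    """Names shaped like '<measure>.<hemisphere>.<region>'."""
    names = []
    for j in range(m):
        measure = _MEASURES[j % len(_MEASURES)]
        hemi = _HEMIS[(j // len(_MEASURES)) % len(_HEMIS)]
        region = f"roi{j // (len(_MEASURES) * len(_HEMIS)):03d}"
        names.append(f"{measure}.{hemi}.{region}")
    return names


def _tanh_second_moment(sigma: float, order: int = 80) -> float:
    """E[tanh(V)^2] for V ~ N(0, sigma^2), by Gauss-Hermite quadrature."""
    nodes, weights = np.polynomial.hermite_e.hermegauss(order)
    vals = np.tanh(sigma * nodes) ** 2
    return float(np.sum(weights * vals) / math.sqrt(2.0 * math.pi))


def _signal_amplitudes(cfg: GenConfig) -> tuple[float, float]:
    """Standardized-signal coefficients (a_male, a_female).

    Chosen so the population outcome variance in standardized units is 1 and
    the overall variance fraction explained by the latent signal equals
    signal_r2, with a_female / a_male = sex_effect_ratio.
    """
    p_m = cfg.male_fraction
    p_f = 1.0 - p_m
    r = cfg.sex_effect_ratio
    denom = p_m + p_f * r * r
    a_m = math.sqrt(cfg.signal_r2 / denom) if denom > 0 else 0.0
    a_f = r * a_m
    if max(a_m, a_f) > 1.0 + 1e-12:
        raise ConfigurationError(
            "signal_r2 and sex_effect_ratio imply a subgroup signal amplitude > 1; "
            "reduce one of them"
        )
    return a_m, min(a_f, 1.0)


def generate_cohort(config: GenConfig) -> CohortTable:
    """Draw a synthetic cohort under ``config``.

    Identical configs (including seed) give bit-identical tables.
    """
    config.validate()
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n, m, k = cfg.n_subjects, cfg.n_features, cfg.n_latent
    sizes = cfg.resolved_block_sizes()
    k_sig = k if cfg.n_signal_latent is None else cfg.n_signal_latent

    # loading matrix: block b -> factor b mod k
    W = np.zeros((k, m))
    block_factor = []
    start = 0
    for b, s in enumerate(sizes):
        W[b % k, start : start + s] = cfg.loading_scale
        block_factor.append(b % k)
        start += s

    sex_is_male = rng.random(n) < cfg.male_fraction
    age = rng.normal(cfg.age_mean_months, cfg.age_sd_months, size=n)
    Z = rng.standard_normal((n, k))
    X = Z @ W + cfg.feature_noise_sd * rng.standard_normal((n, m))

    # standardized signal s with population SD 1 (analytic moments)
    beta = np.zeros(k)
    beta[:k_sig] = 1.0
    v = Z @ beta
    sigma_v = math.sqrt(k_sig)
    if cfg.nonlinearity == "tanh":
        g = np.tanh(v)
        g_sd = math.sqrt(_tanh_second_moment(sigma_v))  # E[tanh]=0 by symmetry
    else:
        g = v
        g_sd = sigma_v
    s = g / g_sd if g_sd > 0 else np.zeros(n)

    a_m, a_f = _signal_amplitudes(cfg)
    a = np.where(sex_is_male, a_m, a_f)
    noise = rng.standard_normal(n)
    t = a * s + np.sqrt(np.clip(1.0 - a * a, 0.0, None)) * noise
    outcome = cfg.outcome_mean + cfg.outcome_sd * t

    names = _feature_names(m)
    signal_factors = set(range(k_sig))
    signal_features: list[int] = []
    start = 0
    for b, sblk in enumerate(sizes):
        if block_factor[b] in signal_factors:
            signal_features.extend(range(start, start + sblk))
        start += sblk

    frame = pd.DataFrame(
        {
            "subject_id": [f"S{i:06d}" for i in range(n)],
            "sex": np.where(sex_is_male, "male", "female"),
            "age_months": age,
            "outcome": outcome,
        }
    )
    frame = pd.concat([frame, pd.DataFrame(X, columns=names)], axis=1)

    ground_truth = {
        "latent": Z.tolist(),
        "signal_feature_indices": signal_features,
        "signal_feature_names": [names[j] for j in signal_features],
        "signal_amplitude_male": a_m,
        "signal_amplitude_female": a_f,
        "config": {kk: (list(vv) if isinstance(vv, tuple) else vv) for kk, vv in asdict(cfg).items()},
    }
    return CohortTable(frame, names, ground_truth)


@dataclass(frozen=True)
class CorrelationCensus:
    """Fraction of unordered feature pairs with Pearson |r| above a threshold."""

    fraction: float
    n_pairs: int
    n_excluded: int  # pairs involving a zero-variance feature

    def __float__(self) -> float:  # allows use as a plain number
        return self.fraction


def correlation_census(cohort: CohortTable, threshold: float = 0.3) -> CorrelationCensus:
    """Census of pairwise feature correlations exceeding ``threshold``.

    Pairs involving a zero-variance feature have undefined correlation; they
    are excluded from the denominator and counted in ``n_excluded``.
    """
    X = cohort.features
    n, m = X.shape
    if n < 3 or m < 2:
        raise ValueError("need at least 3 subjects and 2 features")
    sd = X.std(axis=0)
    ok = sd > 0
    m_ok = int(ok.sum())
    total_pairs = m * (m - 1) // 2
    valid_pairs = m_ok * (m_ok - 1) // 2
    excluded = total_pairs - valid_pairs
    if valid_pairs == 0:
        return CorrelationCensus(float("nan"), 0, excluded)
    C = np.corrcoef(X[:, ok], rowvar=False)
    iu = np.triu_indices(m_ok, k=1)
    frac = float(np.mean(C[iu] > threshold))
    return CorrelationCensus(frac, valid_pairs, excluded)


def write_cohort(cohort: CohortTable, path: str, fmt: str = "csv") -> None:
    """Write the cohort as CSV/TSV; ground truth goes to a '<path>.truth.json' sidecar."""
    sep = {"csv": ",", "tsv": "\t"}[fmt]
    cols = ["subject_id", "sex", "age_months", "outcome"] + cohort.feature_names
    cohort.frame[cols].to_csv(path, sep=sep, index=False)
    if cohort.ground_truth is not None:
        with open(str(path) + ".truth.json", "w") as fh:
            json.dump(cohort.ground_truth, fh)
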