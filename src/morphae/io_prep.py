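"""Cohort I/O, robust percentile scaling, splitting, outcome standardization.

Preprocessing contract:

* features are robust-scaled:  x_scaled = (x - median) / (p95 - p5), with the
  median and percentiles fitted (by default) on training subjects only,
  percentiles by the linear-interpolation convention;
* the cohort is split train/val/test uniformly at random (default overall
  ratios 0.56 / 0.14 / 0.30 — i.e. a 7:3 train:test split with a validation
  set carved out of the 70% training share);
* the outcome is standardized to zero mean / unit sample SD (ddof=1) using
  training-set statistics, applied identically to val and test.

No statistic of validation or test subjects ever enters a fitted scaler
(a ``scaler_scope="all"`` switch reproduces fitting on the pooled sample,
for comparison with pipelines that normalize before splitting).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datagen import CohortTable

__all__ = [
    "read_cohort",
    "write_cohort",
    "SplitAssignment",
    "split_cohort",
    "ScalerParams",
    "fit_robust_scaler",
    "apply_scaler",
    "TargetScaler",
    "fit_target_scaler",
    "standardize_outcome",
    "inverse_transform_outcome",
]

logger = logging.getLogger("morphae")

RESERVED = ("subject_id", "sex", "age_months", "outcome")


class CohortFormatError(ValueError):
    pass


def read_cohort(path: str, fmt: str = "csv") -> CohortTable:
    """Read a cohort table from CSV/TSV.

    Rows with any missing feature or outcome value are dropped with a logged
    count.  Duplicate subject ids or non-numeric feature cells are errors.
    """
    sep = {"csv": ",", "tsv": "\t"}[fmt]
    frame = pd.read_csv(path, sep=sep)
    missing_cols = [c for c in ("subject_id", "outcome") if c not in frame.columns]
    if missing_cols:
        raise CohortFormatError(f"{path}: missing required columns {missing_cols}")
    if frame["subject_id"].duplicated().any():
        dupes = frame.loc[frame["subject_id"].duplicated(), "subject_id"].tolist()
        raise CohortFormatError(f"{path}: duplicate subject_id values {dupes[:5]}")
    feature_names = [c for c in frame.columns if c not in RESERVED]
    for col in feature_names + ["outcome"]:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna() & frame[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise CohortFormatError(
                f"{path}: non-numeric value {frame[col].iloc[row]!r} in column {col!r}, row {row}"
            )
        frame[col] = coerced
    complete = frame[feature_names + ["outcome"]].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.warning("read_cohort: dropped %d row(s) with missing values", n_dropped)
        frame = frame.loc[complete].reset_index(drop=True)
    return CohortTable(frame, feature_names)


def write_cohort(cohort: CohortTable, path: str, fmt: str = "csv") -> None:
    from .datagen import write_cohort as _write

    _write(cohort, path, fmt)


# ---------------------------------------------------------------- splitting


@dataclass(frozen=True)
class SplitAssignment:
    """Disjoint, exhaustive subject_id -> {train, val, test} partition."""

    assignment: dict[str, str]
    split_seed: int
    ratios: tuple[float, float, float]

    def ids(self, part: str) -> list[str]:
        return [s for s, p in self.assignment.items() if p == part]

    def mask(self, cohort: CohortTable, part: str) -> np.ndarray:
        return np.array([self.assignment[s] == part for s in cohort.subject_ids])

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"assignment": self.assignment, "split_seed": self.split_seed, "ratios": self.ratios},
                fh,
            )

    @staticmethod
    def from_json(path: str) -> "SplitAssignment":
        with open(path) as fh:
            d = json.load(fh)
        return SplitAssignment(d["assignment"], d["split_seed"], tuple(d["ratios"]))


def split_cohort(
    cohort: CohortTable,
    ratios: tuple[float, float, float] = (0.56, 0.14, 0.30),
    seed: int = 0,
) -> SplitAssignment:
    """Uniform random train/val/test partition.

    Rounding rule: the pooled training share (train + val) gets
    ``floor((r_train + r_val) * n)`` subjects and the remainder is the test
    set; the validation set takes ``floor(r_val * n)`` of that share.  At
    n = 11534 with a 7:3 split this yields 8073 training and 3461 test
    subjects.
    """
    r_train, r_val, r_test = ratios
    if any(r < 0 for r in ratios) or not math.isclose(sum(ratios), 1.0, abs_tol=1e-9):
        raise ValueError(f"ratios must be nonnegative and sum to 1; got {ratios}")
    n = cohort.n_subjects
    n_share = int(math.floor((r_train + r_val) * n))
    n_val = int(math.floor(r_val * n))
    n_train = n_share - n_val
    n_test = n - n_share
    for label, r, size in (("train", r_train, n_train), ("val", r_val, n_val), ("test", r_test, n_test)):
        if r > 0 and size < 1:
            raise ValueError(f"cohort too small: {label} part would be empty at n={n}, ratios={ratios}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    ids = cohort.subject_ids
    assignment: dict[str, str] = {}
    for idx in order[:n_train]:
        assignment[ids[idx]] = "train"
    for idx in order[n_train : n_train + n_val]:
        assignment[ids[idx]] = "val"
    for idx in order[n_train + n_val :]:
        assignment[ids[idx]] = "test"
    return SplitAssignment(assignment, seed, tuple(ratios))


# ---------------------------------------------------------------- scaling


@dataclass
class ScalerParams:
    """Per-feature robust-scaling parameters (median and 5th/95th percentiles)."""

    feature_names: list[str]
    median: np.ndarray
    p5: np.ndarray
    p95: np.ndarray
    constant_features: list[str] = field(default_factory=list)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "feature_names": self.feature_names,
                    "median": self.median.tolist(),
                    "p5": self.p5.tolist(),
                    "p95": self.p95.tolist(),
                    "constant_features": self.constant_features,
                },
                fh,
            )

    @staticmethod
    def from_json(path: str) -> "ScalerParams":
        with open(path) as fh:
            d = json.load(fh)
        return ScalerParams(
            d["feature_names"],
            np.asarray(d["median"]),
            np.asarray(d["p5"]),
            np.asarray(d["p95"]),
            d["constant_features"],
        )


def fit_robust_scaler(
    cohort: CohortTable,
    assignment: SplitAssignment | None = None,
    scope: str = "train",
) -> ScalerParams:
    """Fit per-feature median / p5 / p95 on the training subjects.

    ``scope="all"`` fits on every subject instead (pool-then-split variant).
    Percentiles use linear interpolation between order statistics.  Features
    with p95 == p5 are flagged constant; their divisor is replaced by 1 so
    scaled values are 0, and a warning is logged.
    """
    if scope == "train":
        if assignment is None:
            raise ValueError("assignment required when scope='train'")
        X = cohort.features[assignment.mask(cohort, "train")]
    elif scope == "all":
        X = cohort.features
    else:
        raise ValueError(f"unknown scaler scope {scope!r}")
    if X.shape[0] < 20:
        raise ValueError(f"need >= 20 training subjects for stable percentiles; got {X.shape[0]}")
    med = np.median(X, axis=0)
    p5 = np.percentile(X, 5, axis=0)  # linear interpolation (numpy default)
    p95 = np.percentile(X, 95, axis=0)
    const = p95 - p5 == 0
    constant_features = [cohort.feature_names[j] for j in np.flatnonzero(const)]
    if constant_features:
        logger.warning(
            "fit_robust_scaler: %d constant feature(s) (p95==p5), divisor set to 1: %s",
            len(constant_features),
            constant_features[:5],
        )
    return ScalerParams(list(cohort.feature_names), med, p5, p95, constant_features)


def apply_scaler(cohort: CohortTable, scaler: ScalerParams) -> CohortTable:
    """Return a cohort whose features are (x - median) / (p95 - p5)."""
    if list(cohort.feature_names) != list(scaler.feature_names):
        raise ValueError("feature-name set does not match fitted scaler")
    rng_ = scaler.p95 - scaler.p5
    divisor = np.where(rng_ == 0, 1.0, rng_)
    X = (cohort.features - scaler.median) / divisor
    return cohort.with_features(X)


@dataclass
class TargetScaler:
    """Training-outcome mean and sample SD (ddof=1)."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ValueError("target SD must be positive")

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump({"mean": self.mean, "sd": self.sd}, fh)

    @staticmethod
    def from_json(path: str) -> "TargetScaler":
        with open(path) as fh:
            d = json.load(fh)
        return TargetScaler(d["mean"], d["sd"])


def fit_target_scaler(cohort: CohortTable, assignment: SplitAssignment) -> TargetScaler:
    """Fit outcome mean/SD on training subjects only."""
    y = cohort.outcome[assignment.mask(cohort, "train")]
    mean = float(np.mean(y))
    sd = float(np.std(y, ddof=1))
    if sd <= 1e-12 * max(1.0, abs(mean)):  # tolerate float residue of a constant column
        raise ValueError("training outcome has zero variance")
    return TargetScaler(mean, sd)


def standardize_outcome(y: np.ndarray, scaler: TargetScaler) -> np.ndarray:
    return (np.asarray(y, dtype=float) - scaler.mean) / scaler.sd


def inverse_transform_outcome(y_std: np.ndarray, scaler: TargetScaler) -> np.ndarray:
    return np.asarray(y_std, dtype=float) * scaler.sd + scaler.mean
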