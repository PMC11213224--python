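"""Classical regression baselines: OLS, random forest, SVR, gradient boosting.

All baselines consume robust-scaled features and the standardized outcome —
the identical pipeline the neural models see — and predictions are mapped
back to the original score scale with the training target scaler.  The
comparison table header "LR" is ordinary least squares linear regression
(a logistic model cannot target a continuous score).  Hyperparameters are
the libraries' defaults, pinned here with fixed seeds; no tuning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.svm import SVR
from xgboost import XGBRegressor

from .datagen import CohortTable
from .io_prep import TargetScaler, inverse_transform_outcome

__all__ = ["BaselineSpec", "BaselineHandle", "fit_baseline", "predict_baseline", "BASELINE_KINDS"]

BASELINE_KINDS = ("linear_regression", "random_forest", "svr", "xgboost")


@dataclass(frozen=True)
class BaselineSpec:
    kind: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in BASELINE_KINDS:
            raise ValueError(f"unknown baseline kind {self.kind!r}; expected one of {BASELINE_KINDS}")


@dataclass
class BaselineHandle:
    spec: BaselineSpec
    model: object
    n_features: int


def _make_model(spec: BaselineSpec):
    hp = dict(spec.hyperparameters)
    if spec.kind == "linear_regression":
        return LinearRegression(**hp)
    if spec.kind == "random_forest":
        hp.setdefault("random_state", spec.seed)
        return RandomForestRegressor(**hp)
    if spec.kind == "svr":
        return SVR(**hp)
    if spec.kind == "xgboost":
        hp.setdefault("random_state", spec.seed)
        hp.setdefault("n_jobs", 1)
        return XGBRegressor(**hp)
    raise ValueError(spec.kind)


def fit_baseline(spec: BaselineSpec, X: np.ndarray, y_std: np.ndarray) -> BaselineHandle:
    """Fit a baseline on scaled features and standardized outcomes."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y_std = np.asarray(y_std, dtype=float)
    model = _make_model(spec)
    model.fit(X, y_std)
    return BaselineHandle(spec, model, X.shape[1])


def predict_baseline(
    handle: BaselineHandle,
    data: CohortTable | np.ndarray,
    target_scaler: TargetScaler | None = None,
) -> np.ndarray:
    """Predict on the original outcome scale (standardized if no scaler given)."""
    X = data.features if isinstance(data, CohortTable) else np.atleast_2d(np.asarray(data, dtype=float))
    if X.shape[1] != handle.n_features:
        raise ValueError(f"expected {handle.n_features} features, got {X.shape[1]}")
    yp = np.asarray(handle.model.predict(X), dtype=float)
    if not np.all(np.isfinite(yp)):
        raise ValueError("baseline produced non-finite predictions")
    if target_scaler is None:
        return yp
    return inverse_transform_outcome(yp, target_scaler)
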