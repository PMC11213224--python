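"""Reconstruction-regularized autoencoder regression, and its MLP ablation.

The model maps a scaled feature vector x in R^m to a hidden code
z = act(W_enc x + b_enc) in R^n shared by two heads: a linear decoder
x' = W_dec z + b_dec that reconstructs the input, and a regression head
y' = f(z) that predicts the standardized outcome.  Both heads are trained
jointly, so the reconstruction error acts as an auxiliary task that forces
the code to preserve the correlation structure of the features rather than
whatever direction happens to fit the (weak) outcome signal in the training
sample — the multi-task mechanism this package exists to study.  The MLP
ablation is the identical encoder + regression head with the decoder (and
its loss term) removed.

The training objective over a batch {(x_i, y_i)} is

    L = w_r * mean_i ||x_i - x'_i||^2
      + w_y * mean_i (y_i - y'_i)^2
      + lambda_theta ||theta||^2 + lambda_phi ||phi||^2 + lambda_psi ||psi||^2

with theta/phi/psi the decoder/encoder/regression-head parameters (biases
included in the squared-L2 penalties by default).  The reconstruction term
is the squared L2 norm of the residual vector, i.e. a *sum* over features,
averaged over the batch (``recon_convention="sum"``); this keeps the data
terms large relative to the L2 penalties so the auxiliary task actually
shapes the encoder.  A ``"mean"`` convention (additionally averaged over
features, making the two data terms scale-comparable) is available, but
with a few hundred features and lambda = 0.1 it leaves the penalties
dominant and both models collapse onto the same ridge-limited solution.

Optimization is full-batch gradient descent by default (``batch_size=None``;
any minibatch size can be configured) under a stepped exponential
learning-rate schedule, with early stopping at the first epoch whose
validation regression MSE exceeds the previous epoch's (the previous
epoch's parameters are kept).  Full-batch descent keeps the per-epoch
validation curve smooth, so the first-increase rule responds to genuine
overfitting rather than minibatch jitter.

Everything is plain numpy with analytic gradients (verified against central
differences in the test suite); no GPU, no autograd framework.
"""

from __future__ import annotations

import copy
import json
import math
from collections import deque
from dataclasses import dataclass, field, asdict

import numpy as np

from .datagen import CohortTable
from .io_prep import TargetScaler, inverse_transform_outcome

__all__ = [
    "TrainConfig",
    "NetworkParams",
    "TrainHistory",
    "init_params",
    "build_mlp",
    "encode",
    "decode",
    "regress",
    "objective",
    "objective_components",
    "objective_and_grads",
    "lr_at",
    "train",
    "grid_search_hidden",
    "predict",
    "DivergenceError",
]


class DivergenceError(RuntimeError):
    def __init__(self, msg: str, history: "TrainHistory | None" = None):
        super().__init__(msg)
        self.history = history


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of the joint objective and the training protocol."""

    hidden_size: int = 100
    hidden_grid: tuple[int, ...] = (50, 100, 200, 400)
    lambda_theta: float = 0.1  # decoder L2
    lambda_phi: float = 0.1  # encoder L2
    lambda_psi: float = 0.1  # regression-head L2
    lr_init: float = 0.1
    lr_decay: float = 0.99
    lr_step: int = 5  # epochs between decay steps
    max_epochs: int = 100
    batch_size: int | None = None  # None -> full batch
    seed: int = 0
    loss_weight_recon: float = 1.0
    loss_weight_reg: float = 1.0
    recon_convention: str = "sum"  # ||x-x'||^2 per subject; "mean" averages over features too
    model_kind: str = "ae"  # or "mlp"
    activation: str = "relu"  # or "tanh"
    reg_hidden: int | None = None  # optional hidden layer in the regression head
    penalize_biases: bool = True
    patience: int = 1  # consecutive val-MSE increases tolerated before stopping

    def __post_init__(self) -> None:
        if min(self.lambda_theta, self.lambda_phi, self.lambda_psi) < 0:
            raise ValueError("regularization weights must be >= 0")
        if not self.lr_init > 0:
            raise ValueError("lr_init must be positive")
        if not 0 < self.lr_decay <= 1:
            raise ValueError("lr_decay must lie in (0, 1]")
        if self.model_kind not in ("ae", "mlp"):
            raise ValueError(f"unknown model_kind {self.model_kind!r}")
        if self.activation not in ("relu", "tanh"):
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.recon_convention not in ("sum", "mean"):
            raise ValueError(f"unknown recon_convention {self.recon_convention!r}")


@dataclass
class NetworkParams:
    """Encoder (phi), optional decoder (theta) and regression head (psi)."""

    W_enc: np.ndarray  # (n, m)
    b_enc: np.ndarray  # (n,)
    W_dec: np.ndarray | None  # (m, n); None for the MLP ablation
    b_dec: np.ndarray | None  # (m,)
    W_head: np.ndarray | None  # (h, n) optional head hidden layer
    b_head: np.ndarray | None  # (h,)
    w_out: np.ndarray  # (n,) or (h,)
    b_out: float
    activation: str = "relu"
    model_kind: str = "ae"

    @property
    def hidden_size(self) -> int:
        return self.W_enc.shape[0]

    @property
    def n_features(self) -> int:
        return self.W_enc.shape[1]

    def copy(self) -> "NetworkParams":
        return copy.deepcopy(self)

    def check_finite(self) -> bool:
        for a in (self.W_enc, self.b_enc, self.W_dec, self.b_dec, self.W_head, self.b_head, self.w_out):
            if a is not None and not np.all(np.isfinite(a)):
                return False
        return bool(np.isfinite(self.b_out))

    def to_json(self, path: str) -> None:
        d = {
            "activation": self.activation,
            "model_kind": self.model_kind,
            "b_out": float(self.b_out),
        }
        for name in ("W_enc", "b_enc", "W_dec", "b_dec", "W_head", "b_head", "w_out"):
            a = getattr(self, name)
            d[name] = None if a is None else np.asarray(a).tolist()
        with open(path, "w") as fh:
            json.dump(d, fh)

    @staticmethod
    def from_json(path: str) -> "NetworkParams":
        with open(path) as fh:
            d = json.load(fh)
        arr = lambda v: None if v is None else np.asarray(v, dtype=float)
        return NetworkParams(
            arr(d["W_enc"]), arr(d["b_enc"]), arr(d["W_dec"]), arr(d["b_dec"]),
            arr(d["W_head"]), arr(d["b_head"]), arr(d["w_out"]), float(d["b_out"]),
            d["activation"], d["model_kind"],
        )


@dataclass
class TrainHistory:
    """Per-epoch objective/validation trace (epochs are 1-based)."""

    train_objective: list[float] = field(default_factory=list)
    val_mse: list[float] = field(default_factory=list)
    stop_epoch: int = 0  # epoch whose parameters were returned
    epochs_run: int = 0
    selected_hidden_size: int = 0

    @property
    def final_val_mse(self) -> float:
        """Validation MSE of the returned parameters."""
        return self.val_mse[self.stop_epoch - 1]


# ---------------------------------------------------------------- forward


def _act(pre: np.ndarray, kind: str) -> np.ndarray:
    return np.maximum(pre, 0.0) if kind == "relu" else np.tanh(pre)


def _act_deriv(pre: np.ndarray, kind: str) -> np.ndarray:
    return (pre > 0).astype(float) if kind == "relu" else 1.0 - np.tanh(pre) ** 2


def encode(X: np.ndarray, params: NetworkParams) -> np.ndarray:
    """z = act(W_enc x + b_enc); accepts a single vector or a batch."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != params.n_features:
        raise ValueError(f"expected {params.n_features} features, got {X.shape[1]}")
    return _act(X @ params.W_enc.T + params.b_enc, params.activation)


def decode(Z: np.ndarray, params: NetworkParams) -> np.ndarray:
    """Linear reconstruction x' = W_dec z + b_dec."""
    if params.W_dec is None:
        raise ValueError("model has no decoder (model_kind='mlp')")
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    return Z @ params.W_dec.T + params.b_dec


def regress(Z: np.ndarray, params: NetworkParams) -> np.ndarray:
    """Regression head y' = f(z), linear output."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if params.W_head is not None:
        U = _act(Z @ params.W_head.T + params.b_head, params.activation)
        return U @ params.w_out + params.b_out
    return Z @ params.w_out + params.b_out


def forward_predict(X: np.ndarray, params: NetworkParams) -> np.ndarray:
    """Standardized-scale prediction f(E(x)) for a batch."""
    return regress(encode(X, params), params)


# ---------------------------------------------------------------- objective


def objective_components(
    X: np.ndarray, y: np.ndarray, params: NetworkParams, config: TrainConfig
) -> dict[str, float]:
    """The five terms of the objective, separately (recon term 0 for the MLP)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if X.shape[0] == 0:
        raise ValueError("empty batch")
    Z = encode(X, params)
    yp = regress(Z, params)
    if params.model_kind == "ae":
        Xr = decode(Z, params)
        sq = (X - Xr) ** 2
        per_subject = sq.sum(axis=1) if config.recon_convention == "sum" else sq.mean(axis=1)
        recon = config.loss_weight_recon * float(per_subject.mean())
    else:
        recon = 0.0
    regmse = config.loss_weight_reg * float(np.mean((y - yp) ** 2))

    def ssq(*arrays):
        total = 0.0
        for a in arrays:
            if a is not None:
                total += float(np.sum(np.square(a)))
        return total

    bias = config.penalize_biases
    pen_theta = 0.0
    if params.model_kind == "ae":
        pen_theta = config.lambda_theta * ssq(params.W_dec, params.b_dec if bias else None)
    pen_phi = config.lambda_phi * ssq(params.W_enc, params.b_enc if bias else None)
    psi_parts = [params.w_out, params.W_head]
    if bias:
        psi_parts += [params.b_head, np.array([params.b_out])]
    pen_psi = config.lambda_psi * ssq(*psi_parts)
    return {
        "reconstruction": recon,
        "regression": regmse,
        "penalty_theta": pen_theta,
        "penalty_phi": pen_phi,
        "penalty_psi": pen_psi,
    }


def objective(X: np.ndarray, y: np.ndarray, params: NetworkParams, config: TrainConfig) -> float:
    return float(sum(objective_components(X, y, params, config).values()))


def objective_and_grads(
    X: np.ndarray, y: np.ndarray, params: NetworkParams, config: TrainConfig
) -> tuple[float, dict[str, np.ndarray | float]]:
    """Objective value and analytic gradients w.r.t. every parameter array."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    B, m = X.shape
    act, bias = params.activation, config.penalize_biases

    z_pre = X @ params.W_enc.T + params.b_enc
    Z = _act(z_pre, act)
    grads: dict[str, np.ndarray | float] = {}
    dZ = np.zeros_like(Z)
    loss = 0.0

    if params.model_kind == "ae":
        Xr = Z @ params.W_dec.T + params.b_dec
        resid = Xr - X
        denom = B if config.recon_convention == "sum" else B * m
        loss += config.loss_weight_recon * float(np.sum(resid**2)) / denom
        dXr = (2.0 * config.loss_weight_recon / denom) * resid
        grads["W_dec"] = dXr.T @ Z + 2.0 * config.lambda_theta * params.W_dec
        grads["b_dec"] = dXr.sum(axis=0) + (2.0 * config.lambda_theta * params.b_dec if bias else 0.0)
        dZ += dXr @ params.W_dec
        loss += config.lambda_theta * (
            float(np.sum(params.W_dec**2)) + (float(np.sum(params.b_dec**2)) if bias else 0.0)
        )

    if params.W_head is not None:
        u_pre = Z @ params.W_head.T + params.b_head
        U = _act(u_pre, act)
        yp = U @ params.w_out + params.b_out
    else:
        yp = Z @ params.w_out + params.b_out
    if not np.all(np.isfinite(yp)):
        raise DivergenceError("non-finite activations in forward pass")
    rresid = yp - y
    loss += config.loss_weight_reg * float(np.mean(rresid**2))
    dyp = (2.0 * config.loss_weight_reg / B) * rresid

    lam = config.lambda_psi
    if params.W_head is not None:
        grads["w_out"] = U.T @ dyp + 2.0 * lam * params.w_out
        grads["b_out"] = float(dyp.sum()) + (2.0 * lam * params.b_out if bias else 0.0)
        dU_pre = np.outer(dyp, params.w_out) * _act_deriv(u_pre, act)
        grads["W_head"] = dU_pre.T @ Z + 2.0 * lam * params.W_head
        grads["b_head"] = dU_pre.sum(axis=0) + (2.0 * lam * params.b_head if bias else 0.0)
        dZ += dU_pre @ params.W_head
        loss += lam * (
            float(np.sum(params.w_out**2))
            + float(np.sum(params.W_head**2))
            + ((float(np.sum(params.b_head**2)) + params.b_out**2) if bias else 0.0)
        )
    else:
        grads["w_out"] = Z.T @ dyp + 2.0 * lam * params.w_out
        grads["b_out"] = float(dyp.sum()) + (2.0 * lam * params.b_out if bias else 0.0)
        dZ += np.outer(dyp, params.w_out)
        loss += lam * (float(np.sum(params.w_out**2)) + (params.b_out**2 if bias else 0.0))

    dz_pre = dZ * _act_deriv(z_pre, act)
    grads["W_enc"] = dz_pre.T @ X + 2.0 * config.lambda_phi * params.W_enc
    grads["b_enc"] = dz_pre.sum(axis=0) + (2.0 * config.lambda_phi * params.b_enc if bias else 0.0)
    loss += config.lambda_phi * (
        float(np.sum(params.W_enc**2)) + (float(np.sum(params.b_enc**2)) if bias else 0.0)
    )
    return loss, grads


# ---------------------------------------------------------------- training


def lr_at(epoch: int, config: TrainConfig) -> float:
    """Stepped exponential schedule: lr_init * lr_decay**floor(epoch/lr_step)."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    return config.lr_init * config.lr_decay ** (epoch // config.lr_step)


def init_params(n_features: int, config: TrainConfig, rng: np.random.Generator) -> NetworkParams:
    """Scaled-Gaussian initialization (He-style fan-in scaling)."""
    n = config.hidden_size
    W_enc = rng.standard_normal((n, n_features)) * math.sqrt(2.0 / n_features)
    b_enc = np.zeros(n)
    if config.model_kind == "ae":
        W_dec = rng.standard_normal((n_features, n)) * math.sqrt(2.0 / n)
        b_dec = np.zeros(n_features)
    else:
        W_dec = b_dec = None
    if config.reg_hidden:
        h = config.reg_hidden
        W_head = rng.standard_normal((h, n)) * math.sqrt(2.0 / n)
        b_head = np.zeros(h)
        w_out = rng.standard_normal(h) * math.sqrt(2.0 / h)
    else:
        W_head = b_head = None
        w_out = rng.standard_normal(n) * math.sqrt(2.0 / n)
    return NetworkParams(
        W_enc, b_enc, W_dec, b_dec, W_head, b_head, w_out, 0.0,
        config.activation, config.model_kind,
    )


def build_mlp(n_features: int, config: TrainConfig, rng: np.random.Generator | None = None) -> NetworkParams:
    """Decoder-free network: same encoder + regression head as the AE."""
    cfg = TrainConfig(**{**asdict(config), "model_kind": "mlp"})
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    return init_params(n_features, cfg, rng)


def _sgd_step(params: NetworkParams, grads: dict, lr: float) -> None:
    for name, g in grads.items():
        if name == "b_out":
            params.b_out -= lr * g
        else:
            setattr(params, name, getattr(params, name) - lr * g)


def validation_mse(params: NetworkParams, X_val: np.ndarray, y_val: np.ndarray) -> float:
    """Regression MSE of the head on the validation set (standardized scale)."""
    yp = forward_predict(X_val, params)
    return float(np.mean((np.asarray(y_val, dtype=float) - yp) ** 2))


def train(
    train_set: tuple[np.ndarray, np.ndarray],
    val_set: tuple[np.ndarray, np.ndarray],
    config: TrainConfig,
    val_mse_fn=None,
    init: NetworkParams | None = None,
) -> tuple[NetworkParams, TrainHistory]:
    """Minibatch SGD on the joint objective with first-increase early stopping.

    After each (1-based) epoch the validation regression MSE is evaluated;
    when it has risen relative to the preceding epoch on ``patience``
    consecutive epochs, training stops and the parameters from the epoch
    before the run of increases are returned.  Fixed seed implies a
    bit-identical history.  ``val_mse_fn(params, epoch)`` may replace the
    validation evaluator (used for protocol tests).
    """
    X, y = np.atleast_2d(np.asarray(train_set[0], dtype=float)), np.asarray(train_set[1], dtype=float)
    Xv, yv = np.atleast_2d(np.asarray(val_set[0], dtype=float)), np.asarray(val_set[1], dtype=float)
    rng = np.random.default_rng(config.seed)
    params = init.copy() if init is not None else init_params(X.shape[1], config, rng)
    history = TrainHistory(selected_hidden_size=config.hidden_size)
    snapshots: deque[NetworkParams] = deque(maxlen=config.patience + 1)
    n = X.shape[0]
    n_increasing = 0

    for epoch in range(1, config.max_epochs + 1):
        lr = lr_at(epoch - 1, config)
        order = rng.permutation(n)
        batch = config.batch_size or n
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, batch):
            idx = order[start : start + batch]
            try:
                loss, grads = objective_and_grads(X[idx], y[idx], params, config)
            except DivergenceError as err:
                raise DivergenceError(
                    f"objective non-finite at epoch {epoch}, batch {n_batches}", history
                ) from err
            if not math.isfinite(loss):
                raise DivergenceError(f"objective non-finite at epoch {epoch}", history)
            _sgd_step(params, grads, lr)
            epoch_loss += loss
            n_batches += 1
        history.train_objective.append(epoch_loss / max(n_batches, 1))
        vmse = float(val_mse_fn(params, epoch)) if val_mse_fn is not None else validation_mse(params, Xv, yv)
        history.val_mse.append(vmse)
        history.epochs_run = epoch
        snapshots.append(params.copy())
        if epoch >= 2 and history.val_mse[-1] > history.val_mse[-2]:
            n_increasing += 1
            if n_increasing >= config.patience:
                history.stop_epoch = epoch - config.patience
                return snapshots[-(config.patience + 1)], history
        else:
            n_increasing = 0
    history.stop_epoch = history.epochs_run
    return params, history


def grid_search_hidden(
    train_set: tuple[np.ndarray, np.ndarray],
    val_set: tuple[np.ndarray, np.ndarray],
    config: TrainConfig,
    train_fn=None,
) -> tuple[int, dict[int, float]]:
    """Train one model per hidden size; return the size with the lowest
    validation MSE of the returned parameters, ties toward the smaller size.

    Grid points whose training fails are recorded as +inf and skipped.
    """
    if not config.hidden_grid:
        raise ValueError("hidden_grid is empty")
    train_fn = train_fn or train
    results: dict[int, float] = {}
    for n in config.hidden_grid:
        cfg_n = TrainConfig(**{**asdict(config), "hidden_size": n})
        try:
            _, hist = train_fn(train_set, val_set, cfg_n)
            results[n] = hist.final_val_mse
        except DivergenceError:
            results[n] = float("inf")
    best = min(sorted(results), key=lambda n: results[n])  # sorted -> ties to smaller n
    if not math.isfinite(results[best]):
        raise DivergenceError("every grid point diverged")
    return best, results


def predict(
    data: CohortTable | np.ndarray,
    params: NetworkParams,
    target_scaler: TargetScaler | None = None,
) -> np.ndarray:
    """Predictions on the original outcome scale.

    ``data`` must already be robust-scaled features (a scaled CohortTable or
    a plain array).  Without a target scaler, standardized-scale predictions
    are returned.
    """
    X = data.features if isinstance(data, CohortTable) else np.asarray(data, dtype=float)
    yp = forward_predict(X, params)
    if target_scaler is None:
        return yp
    return inverse_transform_outcome(yp, target_scaler)
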