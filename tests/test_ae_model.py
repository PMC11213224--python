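"""Network forward passes, objective, gradients, training protocol."""

import dataclasses

import numpy as np
import pytest

import morphae as m
from morphae.ae_model import (
    DivergenceError,
    forward_predict,
    init_params,
    validation_mse,
)
from conftest import reference_gen_config, prepare_splits


def identity_net(mdim: int, bias_out: float = 0.0) -> m.NetworkParams:
    """m = n identity encoder/decoder with relu (exact on nonnegative input)."""
    eye = np.eye(mdim)
    return m.NetworkParams(
        W_enc=eye.copy(), b_enc=np.zeros(mdim), W_dec=eye.copy(), b_dec=np.zeros(mdim),
        W_head=None, b_head=None, w_out=np.ones(mdim), b_out=bias_out,
        activation="relu", model_kind="ae",
    )


def randomized_params(mdim, cfg, seed=0):
    rng = np.random.default_rng(seed)
    p = init_params(mdim, cfg, rng)
    p.b_enc = rng.standard_normal(p.b_enc.shape) * 0.1
    if p.b_dec is not None:
        p.b_dec = rng.standard_normal(p.b_dec.shape) * 0.1
    if p.b_head is not None:
        p.b_head = rng.standard_normal(p.b_head.shape) * 0.1
    p.b_out = 0.3
    return p


# ----------------------------------------------------------- forward passes


def test_identity_network_reconstructs_nonnegative_input(rng):
    p = identity_net(4)
    X = np.abs(rng.standard_normal((7, 4)))
    Z = m.encode(X, p)
    np.testing.assert_array_equal(Z, X)  # relu of nonnegative identity map
    np.testing.assert_array_equal(m.decode(Z, p), X)


def test_zero_weight_network_outputs_biases(rng):
    p = identity_net(3, bias_out=1.5)
    p.W_enc[:] = 0; p.W_dec[:] = 0; p.w_out[:] = 0
    p.b_dec = np.array([1.0, 2.0, 3.0])
    X = rng.standard_normal((5, 3))
    np.testing.assert_array_equal(m.decode(m.encode(X, p), p), np.tile([1.0, 2.0, 3.0], (5, 1)))
    np.testing.assert_array_equal(m.regress(m.encode(X, p), p), np.full(5, 1.5))


def test_hand_computed_forward_pass_two_features_one_hidden():
    # scalar arithmetic oracle: z = relu(0.5*x1 - 1.0*x2 + 0.25)
    p = m.NetworkParams(
        W_enc=np.array([[0.5, -1.0]]), b_enc=np.array([0.25]),
        W_dec=np.array([[2.0], [-3.0]]), b_dec=np.array([0.1, 0.2]),
        W_head=None, b_head=None, w_out=np.array([1.5]), b_out=-0.5,
        activation="relu", model_kind="ae",
    )
    x = np.array([[2.0, 0.5]])
    z = max(0.5 * 2.0 - 1.0 * 0.5 + 0.25, 0.0)  # = 0.75
    assert m.encode(x, p)[0, 0] == pytest.approx(z)
    np.testing.assert_allclose(m.decode([[z]], p)[0], [2.0 * z + 0.1, -3.0 * z + 0.2])
    assert m.regress([[z]], p)[0] == pytest.approx(1.5 * z - 0.5)


def test_dimension_mismatch_raises():
    p = identity_net(4)
    with pytest.raises(ValueError, match="features"):
        m.encode(np.ones((2, 3)), p)


# --------------------------------------------------------------- objective


def test_objective_zero_for_perfect_model_without_penalties(rng):
    p = identity_net(4)
    X = np.abs(rng.standard_normal((6, 4)))
    y = forward_predict(X, p)  # targets constructed to match the head
    cfg = m.TrainConfig(hidden_size=4, lambda_theta=0, lambda_phi=0, lambda_psi=0)
    assert m.objective(X, y, p, cfg) == pytest.approx(0.0, abs=1e-12)


def test_objective_all_zero_params_equals_data_terms(rng):
    cfg = m.TrainConfig(hidden_size=3)
    p = init_params(5, cfg, rng)
    for name in ("W_enc", "b_enc", "W_dec", "b_dec", "w_out"):
        getattr(p, name)[:] = 0.0
    p.b_out = 0.0
    X = rng.standard_normal((4, 5))
    y = rng.standard_normal(4)
    # penalties vanish at zero parameters; recon residual is x itself
    expected = np.mean(np.sum(X**2, axis=1)) + np.mean(y**2)
    assert m.objective(X, y, p, cfg) == pytest.approx(expected, abs=1e-12)


def test_objective_linear_in_lambda_theta(rng):
    cfg = m.TrainConfig(hidden_size=3)
    p = randomized_params(5, cfg, seed=1)
    X = rng.standard_normal((4, 5)); y = rng.standard_normal(4)
    base = m.objective(X, y, p, cfg)
    cfg2 = dataclasses.replace(cfg, lambda_theta=2 * cfg.lambda_theta)
    pen = cfg.lambda_theta * (np.sum(p.W_dec**2) + np.sum(p.b_dec**2))
    assert m.objective(X, y, p, cfg2) - base == pytest.approx(pen, rel=1e-12)


def test_objective_decomposes_into_its_five_terms(rng):
    cfg = m.TrainConfig(hidden_size=4, lambda_theta=0.07, lambda_phi=0.05, lambda_psi=0.03)
    p = randomized_params(6, cfg, seed=2)
    X = rng.standard_normal((8, 6)); y = rng.standard_normal(8)
    comps = m.objective_components(X, y, p, cfg)
    assert len(comps) == 5
    assert m.objective(X, y, p, cfg) == pytest.approx(sum(comps.values()), abs=1e-10)


def test_mlp_objective_equals_ae_with_recon_disabled(rng):
    cfg = m.TrainConfig(hidden_size=4, model_kind="mlp")
    mlp = randomized_params(6, cfg, seed=3)
    ae = m.NetworkParams(
        mlp.W_enc.copy(), mlp.b_enc.copy(),
        np.zeros((6, 4)), np.zeros(6),  # decoder present but disabled below
        None, None, mlp.w_out.copy(), mlp.b_out, "relu", "ae",
    )
    X = rng.standard_normal((5, 6)); y = rng.standard_normal(5)
    cfg_ae = dataclasses.replace(cfg, model_kind="ae", loss_weight_recon=0.0, lambda_theta=0.0)
    assert m.objective(X, y, mlp, cfg) == pytest.approx(m.objective(X, y, ae, cfg_ae), abs=1e-10)
    np.testing.assert_allclose(forward_predict(X, mlp), m.regress(m.encode(X, ae), ae), atol=1e-12)
    assert mlp.W_enc.shape == ae.W_enc.shape


@pytest.mark.parametrize("kind", ["ae", "mlp"])
@pytest.mark.parametrize("act", ["relu", "tanh"])
@pytest.mark.parametrize("reg_hidden", [None, 4])
def test_analytic_gradients_match_central_differences(kind, act, reg_hidden):
    cfg = m.TrainConfig(
        hidden_size=2, model_kind=kind, activation=act, reg_hidden=reg_hidden,
        lambda_theta=0.07, lambda_phi=0.05, lambda_psi=0.03,
    )
    rng = np.random.default_rng(17)
    p = randomized_params(3, cfg, seed=17)
    X = rng.standard_normal((5, 3)); y = rng.standard_normal(5)
    loss, grads = m.objective_and_grads(X, y, p, cfg)
    assert loss == pytest.approx(m.objective(X, y, p, cfg), abs=1e-12)
    eps = 1e-6
    for name, g in grads.items():
        if name == "b_out":
            p.b_out += eps; up = m.objective(X, y, p, cfg)
            p.b_out -= 2 * eps; dn = m.objective(X, y, p, cfg)
            p.b_out += eps
            assert (up - dn) / (2 * eps) == pytest.approx(g, rel=1e-5, abs=1e-7)
            continue
        arr = getattr(p, name)
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            ix = it.multi_index
            arr[ix] += eps; up = m.objective(X, y, p, cfg)
            arr[ix] -= 2 * eps; dn = m.objective(X, y, p, cfg)
            arr[ix] += eps
            num = (up - dn) / (2 * eps)
            assert num == pytest.approx(g[ix], rel=1e-5, abs=1e-7), (name, ix)


# ------------------------------------------------------------- lr schedule


@pytest.mark.parametrize(
    "epoch,expected",
    [(0, 0.1), (4, 0.1), (5, 0.099), (9, 0.099), (10, 0.09801), (12, 0.09801)],
)
def test_learning_rate_schedule(epoch, expected):
    assert m.lr_at(epoch, m.TrainConfig()) == pytest.approx(expected, abs=1e-12)


# ----------------------------------------------------------------- training


def toy_sets(rng, n=64, mdim=3):
    X = rng.standard_normal((n, mdim))
    y = X @ np.array([2.0] + [0.0] * (mdim - 1))
    return (X[: n // 2], y[: n // 2]), (X[n // 2 :], y[n // 2 :])


def test_early_stopping_on_forced_validation_sequence(rng):
    seq = [5.0, 4.0, 4.5]
    captured = {}

    def fake_val(params, epoch):
        captured[epoch] = params.copy()
        return seq[epoch - 1]

    tr, va = toy_sets(rng)
    cfg = m.TrainConfig(hidden_size=2, max_epochs=10, seed=0)
    params, hist = m.train(tr, va, cfg, val_mse_fn=fake_val)
    assert hist.stop_epoch == 2
    assert hist.val_mse == seq
    assert hist.epochs_run == 3
    np.testing.assert_array_equal(params.W_enc, captured[2].W_enc)  # epoch-2 snapshot


def test_monotone_decreasing_validation_runs_to_max_epochs(rng):
    tr, va = toy_sets(rng)
    cfg = m.TrainConfig(hidden_size=2, max_epochs=6, seed=0)
    params, hist = m.train(tr, va, cfg, val_mse_fn=lambda p, e: 10.0 - e)
    assert hist.epochs_run == cfg.max_epochs
    assert hist.stop_epoch == cfg.max_epochs


def test_training_is_seed_deterministic(rng):
    cohort = m.generate_cohort(reference_gen_config(n_subjects=300, seed=4))
    _, _, parts = prepare_splits(cohort, seed=4)
    cfg = m.TrainConfig(hidden_size=10, max_epochs=8, seed=11)
    p1, h1 = m.train(parts["train"][:2], parts["val"][:2], cfg)
    p2, h2 = m.train(parts["train"][:2], parts["val"][:2], cfg)
    assert h1.train_objective == h2.train_objective
    assert h1.val_mse == h2.val_mse
    np.testing.assert_array_equal(p1.W_enc, p2.W_enc)


def test_noiseless_linear_problem_learned_to_high_precision(rng):
    # y = 2x with no noise and no penalties: the end-to-end map converges to
    # the closed-form least-squares solution (train MSE -> 0)
    X = rng.standard_normal((200, 1))
    y = 2.0 * X[:, 0]
    cfg = m.TrainConfig(
        hidden_size=8, max_epochs=400, seed=0,
        lambda_theta=0, lambda_phi=0, lambda_psi=0, loss_weight_recon=0.0,
        model_kind="mlp", lr_init=0.05, patience=10**6,
    )
    params, hist = m.train((X, y), (X, y), cfg)
    resid = y - forward_predict(X, params)
    assert float(np.mean(resid**2)) < 1e-3
    beta = float(X[:, 0] @ y / (X[:, 0] @ X[:, 0]))  # closed form = 2 exactly
    assert beta == pytest.approx(2.0)


def test_divergence_raises_with_history(rng):
    tr, va = toy_sets(rng)
    # patience disabled: the first-increase rule would otherwise halt the
    # run gracefully before the objective overflows
    cfg = m.TrainConfig(hidden_size=4, lr_init=1e6, max_epochs=5, seed=0, patience=10**6)
    with pytest.raises(DivergenceError):
        m.train(tr, va, cfg)


# -------------------------------------------------------------- grid search


def stub_trainer(val_mses):
    def fn(tr, va, cfg):
        hist = m.TrainHistory(
            train_objective=[0.0], val_mse=[val_mses[cfg.hidden_size]],
            stop_epoch=1, epochs_run=1, selected_hidden_size=cfg.hidden_size,
        )
        return None, hist
    return fn


def test_grid_search_singleton_grid(rng):
    tr, va = toy_sets(rng)
    cfg = m.TrainConfig(hidden_grid=(2,), hidden_size=2, max_epochs=2, seed=0)
    best, _ = m.grid_search_hidden(tr, va, cfg)
    assert best == 2


def test_grid_search_returns_argmin_of_stubbed_val_mse(rng):
    tr, va = toy_sets(rng)
    cfg = m.TrainConfig(hidden_grid=(50, 100, 200))
    best, results = m.grid_search_hidden(tr, va, cfg, train_fn=stub_trainer({50: 1.0, 100: 0.5, 200: 0.7}))
    assert best == 100
    assert results == {50: 1.0, 100: 0.5, 200: 0.7}


def test_grid_search_tie_broken_toward_smaller_size(rng):
    tr, va = toy_sets(rng)
    cfg = m.TrainConfig(hidden_grid=(100, 50))
    best, _ = m.grid_search_hidden(tr, va, cfg, train_fn=stub_trainer({50: 0.5, 100: 0.5}))
    assert best == 50


def test_grid_search_survives_failing_grid_point(rng):
    tr, va = toy_sets(rng)
    cfg = m.TrainConfig(hidden_grid=(8, 16))

    def flaky(tr_, va_, cfg_):
        if cfg_.hidden_size == 8:
            raise DivergenceError("boom")
        return stub_trainer({16: 0.4})(tr_, va_, cfg_)

    best, results = m.grid_search_hidden(tr, va, cfg, train_fn=flaky)
    assert best == 16 and results[8] == float("inf")


# ------------------------------------------------------------------ predict


def test_zero_weight_net_predicts_constant_inverse_transform(rng):
    p = identity_net(3, bias_out=0.5)
    p.W_enc[:] = 0; p.w_out[:] = 0
    ts = m.TargetScaler(91.6, 10.62)
    yp = m.predict(rng.standard_normal((6, 3)), p, ts)
    np.testing.assert_allclose(yp, 91.6 + 10.62 * 0.5)


def test_metric_scale_consistency_between_spaces(rng):
    # MSE on the raw scale equals sd^2 times MSE on the standardized scale
    cfg = m.TrainConfig(hidden_size=4, seed=0)
    p = randomized_params(5, cfg, seed=5)
    ts = m.TargetScaler(91.6, 10.62)
    X = rng.standard_normal((30, 5))
    y_std = rng.standard_normal(30)
    y_raw = m.inverse_transform_outcome(y_std, ts)
    mse_std = m.mse(y_std, forward_predict(X, p))
    mse_raw = m.mse(y_raw, m.predict(X, p, ts))
    assert mse_raw == pytest.approx(ts.sd**2 * mse_std, rel=1e-10)


def test_predict_with_identity_scaler_returns_raw_head_output(rng):
    cfg = m.TrainConfig(hidden_size=4, seed=0)
    p = randomized_params(5, cfg, seed=6)
    X = rng.standard_normal((10, 5))
    np.testing.assert_allclose(m.predict(X, p, m.TargetScaler(0.0, 1.0)), forward_predict(X, p))


def test_checkpoint_json_round_trip(tmp_path, rng):
    cfg = m.TrainConfig(hidden_size=4, seed=0)
    p = randomized_params(5, cfg, seed=7)
    p.to_json(str(tmp_path / "net.json"))
    q = m.NetworkParams.from_json(str(tmp_path / "net.json"))
    X = rng.standard_normal((4, 5))
    np.testing.assert_allclose(forward_predict(X, p), forward_predict(X, q), atol=1e-12)
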