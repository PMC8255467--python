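"""Core model: objective, zeroing rule, training, coefficient extraction."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dlasso import (DlassoConfig, NetworkState, dlasso_objective, extract_beta,
                    gen_experiment1, solve_lasso, train_dlasso,
                    zeroing_condition, zeroing_mask)
from dlasso.model import _standardize


class TestObjective:
    @pytest.mark.parametrize(
        "X, w, gamma, y, lam0, expected",
        [
            ([[1.0, 0.0], [0.0, 1.0]], [0.0, 0.0], 1.0, [3.0, 4.0], 1.0, 12.5),
            ([[1.0], [2.0]], [2.0], 1.0, [2.0, 4.0], 0.0, 0.0),
            ([[1.0], [2.0]], [0.5], 1.0, [2.0, 4.0], 0.5, 5.875),
        ],
    )
    def test_hand_computed_values(self, X, w, gamma, y, lam0, expected):
        val = dlasso_objective(np.array(w), gamma, np.array(X), np.array(y), lam0)
        assert val == pytest.approx(expected)

    def test_dimension_mismatch_names_axes(self):
        X = np.ones((3, 2))
        with pytest.raises(ValueError, match="rows|columns|length"):
            dlasso_objective(np.ones(2), 1.0, X, np.ones(4), 1.0)
        with pytest.raises(ValueError, match="columns|length"):
            dlasso_objective(np.ones(3), 1.0, X, np.ones(3), 1.0)

    def test_negative_penalty_rejected(self):
        with pytest.raises(ValueError):
            dlasso_objective(np.ones(2), 1.0, np.ones((2, 2)), np.ones(2), -1.0)

    @given(c=st.floats(0.1, 10.0), sign=st.sampled_from([-1.0, 1.0]))
    def test_prediction_invariance_under_rescaling(self, c, sign):
        """(w, gamma) -> (c*w, gamma/c) leaves the quadratic term unchanged
        while the L1 penalty scales by |c|."""
        rng = np.random.default_rng(7)
        X = rng.standard_normal((12, 4))
        y = rng.standard_normal(12)
        w = rng.standard_normal(4)
        c = sign * c
        base = dlasso_objective(w, 2.0, X, y, 0.0)
        scaled = dlasso_objective(c * w, 2.0 / c, X, y, 0.0)
        assert scaled == pytest.approx(base, rel=1e-9)
        pen = dlasso_objective(c * w, 2.0 / c, X, y, 1.0) - scaled
        assert pen == pytest.approx(abs(c) * np.abs(w).sum(), rel=1e-9)


class TestZeroingCondition:
    def test_orthogonal_response_is_zeroed(self):
        X = np.eye(3)
        y = np.zeros(3)
        state = NetworkState(w=np.zeros(3), gamma=1.0, mask=np.ones(3, bool))
        assert zeroing_condition(X, y, state, lambda0=0.5, j=0)

    def test_orthonormal_soft_threshold_case(self):
        # closed form: w_j = sign(X_j'y) * max(|X_j'y| - lam0/2, 0)
        X = np.eye(2)
        y = np.array([0.4, 3.0])
        state = NetworkState(w=np.array([0.0, 2.5]), gamma=1.0,
                             mask=np.ones(2, bool))
        assert zeroing_condition(X, y, state, lambda0=1.0, j=0)  # |0.8| <= 1
        assert not zeroing_condition(X, y, state, lambda0=1.0, j=1)  # 6 > 1

    def test_gamma_zero_rejected(self):
        with pytest.raises(ValueError):
            NetworkState(w=np.zeros(2), gamma=0.0, mask=np.ones(2, bool))

    @pytest.mark.parametrize("seed", range(6))
    def test_agrees_with_kkt_status_at_lasso_solution(self, seed):
        """At a coordinate-descent lasso minimizer the condition holds exactly
        for the zero coefficients and fails for the nonzero ones."""
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((8, 3))
        y = X @ np.array([1.5, 0.0, 0.0]) + 0.3 * rng.standard_normal(8)
        lam = 4.0
        fit = solve_lasso(X, y, lam)
        state = NetworkState(w=fit.beta_hat, gamma=1.0, mask=np.ones(3, bool))
        cond = zeroing_mask(X, y, state, lambda0=lam)
        np.testing.assert_array_equal(cond, fit.beta_hat == 0)


class TestNetworkState:
    def test_masked_weights_must_be_zero(self):
        with pytest.raises(ValueError):
            NetworkState(w=np.array([1.0, 2.0]), gamma=1.0,
                         mask=np.array([True, False]))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            NetworkState(w=np.zeros(3), gamma=1.0, mask=np.ones(2, bool))


class TestExtractBeta:
    @pytest.mark.parametrize(
        "gamma, w, expected",
        [
            (1.0, [0.3, 0.0], [0.3, 0.0]),
            (5.0, [0.0, 0.0], [0.0, 0.0]),
            (2.0, [0.5, -1.0], [1.0, -2.0]),
        ],
    )
    def test_scaling(self, gamma, w, expected):
        state = NetworkState(w=np.array(w), gamma=gamma,
                             mask=np.array(w) != 0)
        np.testing.assert_allclose(extract_beta(state), expected)


class TestTraining:
    def test_zero_response_gives_empty_support(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((30, 4))
        y = np.zeros(30)
        cfg = DlassoConfig(epochs=600, restarts=2, standardize=False, seed=0)
        model = train_dlasso(X, y, cfg)
        np.testing.assert_array_equal(model.beta_hat, 0.0)
        assert model.support.size == 0

    def test_noiseless_exact_recovery(self):
        ds = gen_experiment1(p=5, n_train=200, n_test=10, seed=3, noise_var=0.0)
        cfg = DlassoConfig(lambda0=0.01, restarts=3, seed=0)
        model = train_dlasso(ds.X_train, ds.y_train, cfg)
        beta, _ = model.coef_original()
        np.testing.assert_allclose(beta, [3.0, 1.5, 0.0, 0.0, 2.0], atol=0.05)
        assert set(model.support) == {0, 1, 4}

    def test_frozen_gamma_matches_coordinate_descent(self, small_instance):
        """With gamma pinned at 1 the network solves the classical lasso at
        the (sum-form) penalty N * lambda0."""
        X, y, _ = small_instance
        lam0 = 0.1
        cfg = DlassoConfig(lambda0=lam0, epochs=4000, restarts=1,
                           learning_rate=0.005, freeze_gamma=True,
                           standardize=False, seed=0)
        model = train_dlasso(X, y, cfg)
        oracle = solve_lasso(X, y, lam=X.shape[0] * lam0)
        assert np.max(np.abs(model.beta_hat - oracle.beta_hat)) < 1e-2

    def test_reported_zeros_are_exact(self):
        ds = gen_experiment1(p=20, seed=2)
        model = train_dlasso(ds.X_train, ds.y_train,
                             DlassoConfig(restarts=2, seed=0))
        zeros = model.beta_hat[model.beta_hat == 0]
        assert zeros.size > 0  # some features are dropped
        # support is exactly the nonzero set, no epsilon thresholding
        assert set(model.support) == set(np.flatnonzero(model.beta_hat))

    def test_restart_selection_by_training_mse(self):
        ds = gen_experiment1(p=10, seed=4)
        model = train_dlasso(ds.X_train, ds.y_train,
                             DlassoConfig(restarts=4, seed=1))
        finite = model.restart_losses[np.isfinite(model.restart_losses)]
        assert model.train_mse == pytest.approx(finite.min())

    def test_determinism(self):
        ds = gen_experiment1(p=10, seed=5)
        cfg = DlassoConfig(restarts=2, epochs=200, seed=9)
        a = train_dlasso(ds.X_train, ds.y_train, cfg)
        b = train_dlasso(ds.X_train, ds.y_train, cfg)
        np.testing.assert_array_equal(a.beta_hat, b.beta_hat)
        assert a.gamma == b.gamma

    def test_constant_response_rejected_when_standardizing(self):
        X = np.random.default_rng(0).standard_normal((10, 2))
        with pytest.raises(ValueError, match="constant"):
            train_dlasso(X, np.ones(10), DlassoConfig(epochs=10))

    def test_all_restarts_diverged_raises(self, small_instance):
        X, y, _ = small_instance
        cfg = DlassoConfig(learning_rate=1e300, epochs=50, restarts=2,
                           standardize=False, seed=0)
        with np.errstate(over="ignore", invalid="ignore"):
            with pytest.raises(RuntimeError, match="diverged"):
                train_dlasso(X, y, cfg)


class TestPredict:
    def test_null_model_predicts_training_mean(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((40, 3))
        y = rng.standard_normal(40) + 5.0
        # huge penalty: everything zeroed, prediction = mean(y)
        model = train_dlasso(X, y, DlassoConfig(lambda0=100.0, epochs=600,
                                                restarts=1, seed=0))
        assert model.support.size == 0
        np.testing.assert_allclose(model.predict(X), y.mean(), atol=1e-9)

    def test_identity_design_returns_coefficients(self, small_instance):
        X, y, _ = small_instance
        cfg = DlassoConfig(epochs=300, restarts=1, standardize=False, seed=0)
        model = train_dlasso(X, y, cfg)
        np.testing.assert_allclose(model.predict(np.eye(X.shape[1])),
                                   model.beta_hat)

    def test_column_mismatch_rejected(self, small_instance):
        X, y, _ = small_instance
        model = train_dlasso(X, y, DlassoConfig(epochs=50, restarts=1, seed=0))
        with pytest.raises(ValueError, match="columns"):
            model.predict(np.ones((2, 3)))


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"lambda0": 0.0},
            {"lambda0": -1.0},
            {"epochs": 0},
            {"restarts": 0},
            {"learning_rate": 0.0},
            {"zero_check_start": 2000},
            {"optimizer": "sgd"},
        ],
    )
    def test_invalid_values_rejected(self, kwargs):
        with pytest.raises(ValueError):
            DlassoConfig(**kwargs)


def test_standardize_helper_centers_and_scales(rng):
    X = rng.standard_normal((30, 3)) * [1.0, 4.0, 0.5] + [2.0, -1.0, 0.0]
    y = rng.standard_normal(30) + 3.0
    Xs, yc, _, _, _ = _standardize(X, y)
    np.testing.assert_allclose(Xs.mean(0), 0.0, atol=1e-12)
    np.testing.assert_allclose(Xs.std(0), 1.0, atol=1e-12)
    assert yc.mean() == pytest.approx(0.0, abs=1e-12)
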