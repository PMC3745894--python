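"""Tests for the network engine: forward pass, backpropagation, the four
minimizers, early stopping, thresholding and serialization."""

import math

import numpy as np
import pytest

from berascreen import (
    NetworkModel,
    NetworkSpec,
    TrainConfig,
    ValidationError,
    classify,
    forward,
    gradient,
    init_network,
    jacobian,
    train,
)
from berascreen.ann_core import (
    _EarlyStopper,
    _fit_levenberg_marquardt,
    _fit_once,
    mse,
    pack_parameters,
    unpack_parameters,
)


def naive_forward(model, x):
    """Matrix-free per-node oracle for the forward pass."""
    act = (lambda z: 1.0 / (1.0 + math.exp(-z))) \
        if model.spec.hidden_activation == "logistic" else math.tanh
    a = list(x)
    for W, b in zip(model.weights[:-1], model.biases[:-1]):
        a = [
            act(sum(a[i] * W[i, j] for i in range(W.shape[0])) + b[j])
            for j in range(W.shape[1])
        ]
    W, b = model.weights[-1], model.biases[-1]
    return sum(a[i] * W[i, 0] for i in range(W.shape[0])) + b[0]


def finite_difference_gradient(model, X, y, h=1e-6):
    """Central-difference oracle for the MSE gradient."""
    theta = pack_parameters(model.weights, model.biases)
    grad = np.empty_like(theta)
    for k in range(theta.size):
        for sign, store in ((1, "plus"), (-1, "minus")):
            t = theta.copy()
            t[k] += sign * h
            w, b = unpack_parameters(model.spec, t)
            m = NetworkModel(spec=model.spec, weights=w, biases=b)
            if sign == 1:
                f_plus = mse(m, X, y)
            else:
                f_minus = mse(m, X, y)
        grad[k] = (f_plus - f_minus) / (2 * h)
    return grad


def _random_model(spec, seed, scale=1.0):
    model = init_network(spec, seed)
    rng = np.random.default_rng(seed + 1)
    for b in model.biases:
        b[:] = rng.normal(scale=0.3 * scale, size=b.shape)
    for W in model.weights:
        W *= scale
    return model


class TestInitAndShapes:
    def test_same_seed_identical_parameters(self):
        spec = NetworkSpec(14, (10, 10), "logistic")
        a, b = init_network(spec, 7), init_network(spec, 7)
        assert all(np.array_equal(x, y) for x, y in zip(a.weights, b.weights))
        assert all(np.array_equal(x, y) for x, y in zip(a.biases, b.biases))

    @pytest.mark.parametrize(
        "spec,expected",
        [
            (NetworkSpec(14, (10, 10)), 14 * 10 + 10 + 10 * 10 + 10 + 10 + 1),  # 271
            (NetworkSpec(12, (10,)), 12 * 10 + 10 + 10 + 1),  # 141
        ],
    )
    def test_parameter_counts(self, spec, expected):
        assert spec.n_parameters == expected
        model = init_network(spec, 0)
        assert pack_parameters(model.weights, model.biases).size == expected

    def test_glorot_range_and_zero_biases(self):
        spec = NetworkSpec(12, (10,))
        model = init_network(spec, 3)
        r = np.sqrt(6.0 / (12 + 10))
        assert np.all(np.abs(model.weights[0]) < r)
        assert np.all(model.biases[0] == 0.0)

    def test_more_than_two_hidden_layers_rejected(self):
        with pytest.raises(ValidationError):
            NetworkSpec(12, (5, 5, 5))


class TestForward:
    @pytest.mark.parametrize("activation", ["logistic", "tanh"])
    @pytest.mark.parametrize("hidden", [(4,), (3, 5)])
    def test_matches_per_node_oracle(self, activation, hidden):
        spec = NetworkSpec(6, hidden, activation)
        model = _random_model(spec, 11)
        rng = np.random.default_rng(2)
        for _ in range(5):
            x = rng.normal(size=6)
            assert forward(model, x) == pytest.approx(naive_forward(model, x), abs=1e-12)

    def test_zero_weights_output_is_bias(self):
        spec = NetworkSpec(4, (3,), "logistic")
        model = init_network(spec, 0)
        for W in model.weights:
            W[:] = 0.0
        model.biases[-1][0] = 0.75
        assert forward(model, np.ones(4)) == pytest.approx(0.75)

    def test_tanh_hidden_activations_are_odd(self):
        """With zero biases, negating the input negates every tanh hidden
        activation, so the output moves symmetrically about the output bias."""
        spec = NetworkSpec(5, (4,), "tanh")
        model = _random_model(spec, 21)
        for b in model.biases:
            b[:] = 0.0
        x = np.random.default_rng(3).normal(size=5)
        assert forward(model, x) == pytest.approx(-forward(model, -x), abs=1e-12)

    def test_batch_equals_per_row(self):
        spec = NetworkSpec(6, (3, 3), "logistic")
        model = _random_model(spec, 4)
        X = np.random.default_rng(5).normal(size=(7, 6))
        batch = forward(model, X)
        assert batch == pytest.approx([forward(model, row) for row in X], abs=1e-14)

    def test_input_width_mismatch_rejected(self):
        model = init_network(NetworkSpec(6, (3,)), 0)
        with pytest.raises(ValidationError):
            forward(model, np.ones(5))


class TestGradient:
    @pytest.mark.parametrize("activation", ["logistic", "tanh"])
    @pytest.mark.parametrize("hidden", [(4,), (3, 4)])
    def test_matches_central_finite_differences(self, activation, hidden):
        spec = NetworkSpec(5, hidden, activation)
        model = _random_model(spec, 13)
        rng = np.random.default_rng(17)
        X = rng.normal(size=(5, 5))
        y = rng.integers(0, 2, size=5).astype(float)
        g = gradient(model, X, y)
        g_fd = finite_difference_gradient(model, X, y)
        denom = np.maximum(np.abs(g_fd), 1e-8)
        assert np.max(np.abs(g - g_fd) / denom) < 1e-5

    def test_zero_residuals_give_zero_gradient(self):
        spec = NetworkSpec(4, (3,), "tanh")
        model = _random_model(spec, 19)
        X = np.random.default_rng(23).normal(size=(6, 4))
        y = forward(model, X)  # targets equal outputs
        assert np.allclose(gradient(model, X, y), 0.0, atol=1e-14)

    def test_linear_single_sample_closed_form(self):
        """One sample through a linear model: gradient is 2 (w.x + b - y) [x, 1]."""
        spec = NetworkSpec(3, ())
        model = init_network(spec, 29)
        x = np.array([0.5, -1.0, 2.0])
        y = np.array([1.0])
        out = forward(model, x)
        expected = 2.0 * (out - y[0]) * np.concatenate([x, [1.0]])
        assert gradient(model, x[None, :], y) == pytest.approx(expected, rel=1e-12)

    def test_gradient_is_jacobian_transpose_residual(self):
        spec = NetworkSpec(4, (3,), "logistic")
        model = _random_model(spec, 31)
        X = np.random.default_rng(37).normal(size=(8, 4))
        y = np.zeros(8)
        J, out = jacobian(model, X)
        assert gradient(model, X, y) == pytest.approx(
            (2.0 / 8) * (J.T @ (out - y)), rel=1e-12
        )


def _linear_problem(seed=0, n=20, p=3):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    y = rng.normal(size=n)
    A = np.column_stack([X, np.ones(n)])
    theta_star, *_ = np.linalg.lstsq(A, y, rcond=None)
    return X, y, theta_star


class TestMinimizers:
    def test_lm_reaches_normal_equation_solution_in_one_step(self):
        """With vanishing damping, Levenberg-Marquardt on a full-rank linear
        least-squares problem is an exact Gauss-Newton step."""
        X, y, theta_star = _linear_problem()
        spec = NetworkSpec(3, ())
        config = TrainConfig(
            algorithm="levenberg_marquardt", lm_lambda0=1e-10, max_iterations=1,
            patience=5,
        )
        theta0 = pack_parameters(
            *(lambda m: (m.weights, m.biases))(init_network(spec, 1))
        )
        val, theta, history = _fit_once(spec, theta0, X, y, X, y, config)
        assert np.allclose(theta, theta_star, atol=1e-8)
        assert len(history["train_mse"]) == 2  # initial error + one accepted step

    def test_lm_training_error_monotone_under_accepted_steps(self):
        rng = np.random.default_rng(41)
        X = rng.normal(size=(30, 5))
        y = rng.integers(0, 2, size=30).astype(float)
        spec = NetworkSpec(5, (4,), "logistic")
        config = TrainConfig(algorithm="levenberg_marquardt", max_iterations=40,
                             patience=40)
        theta0 = pack_parameters(
            *(lambda m: (m.weights, m.biases))(init_network(spec, 2))
        )
        _, _, history = _fit_once(spec, theta0, X, y, X, y, config)
        errors = history["train_mse"]
        assert all(b < a for a, b in zip(errors, errors[1:]))

    @pytest.mark.parametrize(
        "algorithm",
        ["steepest_descent", "quasi_newton", "conjugate_gradient", "levenberg_marquardt"],
    )
    def test_all_minimizers_halve_mse_within_200_iterations(self, algorithm):
        """Fixed 20-sample problem, shared initialization: each minimizer cuts
        the MSE by at least half."""
        rng = np.random.default_rng(100)
        X = rng.normal(size=(20, 4))
        y = rng.integers(0, 2, size=20).astype(float)
        spec = NetworkSpec(4, (5,), "logistic")
        theta0 = pack_parameters(
            *(lambda m: (m.weights, m.biases))(init_network(spec, 3))
        )
        config = TrainConfig(algorithm=algorithm, max_iterations=200, patience=200)
        _, _, history = _fit_once(spec, theta0, X, y, X, y, config)
        errors = history["train_mse"]
        assert errors[-1] <= 0.5 * errors[0]

    def test_quasi_newton_solves_xor(self):
        """The classic non-linearly-separable benchmark: a 4-node tanh network
        trained with BFGS reaches near-zero MSE from at least one restart."""
        X4 = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
        y4 = np.array([0.0, 1.0, 1.0, 0.0])
        X = np.tile(X4, (4, 1))
        y = np.tile(y4, 4)
        spec = NetworkSpec(2, (4,), "tanh")
        config = TrainConfig(
            algorithm="quasi_newton", max_iterations=300, patience=300,
            n_restarts=6, validation_fraction=0.25, seed=0,
        )
        result = train(spec, X, y, config)
        assert mse(result.model, X4, y4) < 0.01

    def test_quasi_newton_competitive_with_scipy_bfgs(self):
        """Independent oracle: scipy's BFGS on the same objective from the
        same start reaches a comparable objective value."""
        from scipy.optimize import minimize

        rng = np.random.default_rng(55)
        X = rng.normal(size=(25, 3))
        y = rng.integers(0, 2, size=25).astype(float)
        spec = NetworkSpec(3, (4,), "tanh")
        theta0 = pack_parameters(
            *(lambda m: (m.weights, m.biases))(init_network(spec, 5))
        )

        def fun(theta):
            w, b = unpack_parameters(spec, theta)
            return mse(NetworkModel(spec=spec, weights=w, biases=b), X, y)

        config = TrainConfig(algorithm="quasi_newton", max_iterations=300, patience=300)
        _, _, history = _fit_once(spec, theta0, X, y, X, y, config)
        reference = minimize(fun, theta0, method="BFGS",
                             options={"maxiter": 300}).fun
        assert history["train_mse"][-1] <= reference + 1e-3


class TestTrainContract:
    @pytest.fixture()
    def problem(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(60, 4))
        w = np.array([1.5, -2.0, 0.5, 1.0])
        y = (X @ w > 0).astype(float)
        return X, y

    def test_snapshot_is_validation_minimum(self, problem):
        X, y = problem
        spec = NetworkSpec(4, (5,), "logistic")
        config = TrainConfig(algorithm="levenberg_marquardt", max_iterations=30,
                             n_restarts=1, seed=3)
        result = train(spec, X, y, config)
        val_history = result.history["val_mse"]
        assert result.val_error == min(val_history)
        assert val_history[result.history["best_iteration"]] == result.val_error

    def test_training_is_deterministic_per_seed(self, problem):
        X, y = problem
        spec = NetworkSpec(4, (3,), "tanh")
        config = TrainConfig(algorithm="quasi_newton", max_iterations=20,
                             n_restarts=2, seed=9)
        a = train(spec, X, y, config)
        b = train(spec, X, y, config)
        assert all(np.array_equal(u, v) for u, v in zip(a.model.weights, b.model.weights))
        assert a.val_error == b.val_error

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValidationError):
            train(NetworkSpec(2, (2,)), np.zeros((5, 2)), np.zeros(5))

    def test_unknown_algorithm_rejected(self, problem):
        X, y = problem
        with pytest.raises(ValidationError):
            train(NetworkSpec(4, (3,)), X, y, TrainConfig(algorithm="adam"))


class TestClassify:
    def _constant_output_model(self, value):
        spec = NetworkSpec(2, ())
        model = init_network(spec, 0)
        model.weights[0][:] = 0.0
        model.biases[0][0] = value
        return model

    @pytest.mark.parametrize(
        "output,expected",
        [(0.5, 1), (0.499, 0), (1.3, 1), (-0.2, 0), (0.501, 1)],
    )
    def test_threshold_boundary_inclusive(self, output, expected):
        model = self._constant_output_model(output)
        assert classify(model, np.zeros(2)) == expected

    def test_batch_classification(self):
        model = self._constant_output_model(0.7)
        assert np.array_equal(classify(model, np.zeros((3, 2))), [1, 1, 1])


class TestSerialization:
    def test_round_trip_reproduces_forward_bit_identically(self):
        spec = NetworkSpec(14, (5, 15), "logistic")
        model = _random_model(spec, 77)
        restored = NetworkModel.from_dict(model.to_dict())
        X = np.random.default_rng(78).normal(size=(10, 14))
        assert np.array_equal(forward(model, X), forward(restored, X))
        assert restored.init_seed == model.init_seed
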