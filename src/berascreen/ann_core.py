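"""Feedforward network engine with four classic backpropagation minimizers.

The classifier is a fully connected network with one or two hidden layers
(logistic or tanh activations), a single linear-summation output node, and a
mean-squared-error objective against 0/1 class targets.  The raw output is a
real value, usually but not necessarily inside [0, 1]; the decision rule is a
fixed threshold: class 1 iff output >= 0.5.

Training is full-batch minimization of the MSE by one of

* steepest descent (fixed learning rate),
* quasi-Newton (BFGS inverse-Hessian approximation, Armijo backtracking),
* conjugate gradient (Polak-Ribiere, periodic restart, same line search),
* Levenberg-Marquardt (damped Gauss-Newton on the residual Jacobian),

with a stratified validation holdout for early stopping: the parameter
snapshot with the lowest validation error is returned, and training stops
after ``patience`` non-improving iterations.  Because weights are randomly
initialized, several independent restarts are run and the restart with the
lowest validation error wins.

Everything operates on a flat parameter vector (layer by layer, weight matrix
then bias) so the minimizers and the finite-difference tests share one
coordinate system.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import NumericalError, ValidationError

ALGORITHMS = (
    "steepest_descent",
    "quasi_newton",
    "levenberg_marquardt",
    "conjugate_gradient",
)

ACTIVATIONS = ("logistic", "tanh")

#: damping ceiling above which a Levenberg-Marquardt run is considered stuck
_LM_LAMBDA_MAX = 1e12


# -- domain types -------------------------------------------------------------


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture description: input width, 1-2 hidden layers, activation.

    An empty ``hidden_layers`` tuple yields a plain linear model; that
    degenerate form exists for closed-form optimizer tests, the classifiers
    themselves always use one or two hidden layers.
    """

    n_inputs: int
    hidden_layers: tuple[int, ...]
    hidden_activation: str = "logistic"

    def __post_init__(self) -> None:
        object.__setattr__(self, "hidden_layers", tuple(self.hidden_layers))
        if self.n_inputs < 1:
            raise ValidationError("n_inputs must be >= 1")
        if len(self.hidden_layers) > 2:
            raise ValidationError("at most 2 hidden layers are supported")
        if any(h < 1 for h in self.hidden_layers):
            raise ValidationError("hidden node counts must be >= 1")
        if self.hidden_activation not in ACTIVATIONS:
            raise ValidationError(
                f"hidden_activation must be one of {ACTIVATIONS}"
            )

    @property
    def layer_sizes(self) -> tuple[int, ...]:
        return (self.n_inputs, *self.hidden_layers, 1)

    @property
    def n_parameters(self) -> int:
        sizes = self.layer_sizes
        return sum(
            sizes[i] * sizes[i + 1] + sizes[i + 1] for i in range(len(sizes) - 1)
        )

    def to_dict(self) -> dict:
        return {
            "n_inputs": self.n_inputs,
            "hidden_layers": list(self.hidden_layers),
            "hidden_activation": self.hidden_activation,
        }

    @classmethod
    def from_dict(cls, d) -> "NetworkSpec":
        return cls(
            n_inputs=int(d["n_inputs"]),
            hidden_layers=tuple(d["hidden_layers"]),
            hidden_activation=d["hidden_activation"],
        )


@dataclass
class NetworkModel:
    """A spec plus concrete weight matrices and bias vectors per layer."""

    spec: NetworkSpec
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    init_seed: int | None = None

    def __post_init__(self) -> None:
        sizes = self.spec.layer_sizes
        if len(self.weights) != len(sizes) - 1 or len(self.biases) != len(sizes) - 1:
            raise ValidationError("layer count inconsistent with spec")
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            if W.shape != (sizes[i], sizes[i + 1]) or b.shape != (sizes[i + 1],):
                raise ValidationError(
                    f"layer {i} parameter shapes {W.shape}/{b.shape} do not "
                    f"match spec sizes {sizes[i]}x{sizes[i + 1]}"
                )
            if not (np.all(np.isfinite(W)) and np.all(np.isfinite(b))):
                raise ValidationError(f"layer {i} has non-finite parameters")

    def to_dict(self) -> dict:
        return {
            "spec": self.spec.to_dict(),
            "weights": [W.tolist() for W in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "init_seed": self.init_seed,
        }

    @classmethod
    def from_dict(cls, d) -> "NetworkModel":
        return cls(
            spec=NetworkSpec.from_dict(d["spec"]),
            weights=[np.asarray(W, float) for W in d["weights"]],
            biases=[np.asarray(b, float) for b in d["biases"]],
            init_seed=d.get("init_seed"),
        )


@dataclass
class TrainConfig:
    """Hyperparameters of one training run.

    ``validation_fraction`` of the training rows (stratified by label) is held
    out for early stopping; ``patience`` is the number of consecutive
    non-improving validation iterations tolerated before stopping.
    ``learning_rate`` applies to steepest descent only; ``lm_lambda0`` and
    ``lm_factor`` control the Levenberg-Marquardt damping schedule.
    """

    algorithm: str = "levenberg_marquardt"
    max_iterations: int = 200
    validation_fraction: float = 0.2
    patience: int = 25
    n_restarts: int = 10
    learning_rate: float = 0.01
    lm_lambda0: float = 1e-3
    lm_factor: float = 10.0
    seed: int = 0

    def validate(self) -> "TrainConfig":
        if self.algorithm not in ALGORITHMS:
            raise ValidationError(
                f"unknown algorithm {self.algorithm!r}; expected one of {ALGORITHMS}"
            )
        if not (0.0 < self.validation_fraction < 1.0):
            raise ValidationError("validation_fraction must be in (0, 1)")
        if self.patience < 1:
            raise ValidationError("patience must be >= 1")
        if self.n_restarts < 1:
            raise ValidationError("n_restarts must be >= 1")
        if self.max_iterations < 1:
            raise ValidationError("max_iterations must be >= 1")
        return self


@dataclass
class TrainResult:
    """Winning model plus the training history of its restart."""

    model: NetworkModel
    val_error: float
    history: dict


# -- parameter vector <-> layer parameters ------------------------------------


def pack_parameters(weights: Sequence[np.ndarray], biases: Sequence[np.ndarray]) -> np.ndarray:
    return np.concatenate(
        [np.concatenate([W.ravel(), b]) for W, b in zip(weights, biases)]
    )


def unpack_parameters(spec: NetworkSpec, theta: np.ndarray):
    sizes = spec.layer_sizes
    weights, biases, pos = [], [], 0
    for i in range(len(sizes) - 1):
        n_in, n_out = sizes[i], sizes[i + 1]
        weights.append(theta[pos: pos + n_in * n_out].reshape(n_in, n_out))
        pos += n_in * n_out
        biases.append(theta[pos: pos + n_out])
        pos += n_out
    return weights, biases


# -- forward / backward -------------------------------------------------------


def _activation(name: str) -> Callable[[np.ndarray], np.ndarray]:
    if name == "logistic":
        def logistic(z):
            # exp overflow for very negative z saturates harmlessly to 0
            with np.errstate(over="ignore"):
                return 1.0 / (1.0 + np.exp(-z))

        return logistic
    return np.tanh


def _activation_deriv(name: str) -> Callable[[np.ndarray], np.ndarray]:
    # derivative expressed through the activation value itself
    if name == "logistic":
        return lambda a: a * (1.0 - a)
    return lambda a: 1.0 - a * a


def init_network(spec: NetworkSpec, seed: int) -> NetworkModel:
    """Glorot-style uniform initialization: weights from (-r, r) with
    ``r = sqrt(6 / (fan_in + fan_out))`` per layer, biases zero."""
    rng = np.random.default_rng(seed)
    sizes = spec.layer_sizes
    weights, biases = [], []
    for i in range(len(sizes) - 1):
        r = np.sqrt(6.0 / (sizes[i] + sizes[i + 1]))
        weights.append(rng.uniform(-r, r, size=(sizes[i], sizes[i + 1])))
        biases.append(np.zeros(sizes[i + 1]))
    return NetworkModel(spec=spec, weights=weights, biases=biases, init_seed=int(seed))


def _forward_layers(weights, biases, act, X: np.ndarray):
    """All layer activations for a batch; returns (activations, outputs)."""
    acts = [X]
    for W, b in zip(weights[:-1], biases[:-1]):
        acts.append(act(acts[-1] @ W + b))
    out = acts[-1] @ weights[-1][:, 0] + biases[-1][0]
    return acts, out


def forward(model: NetworkModel, x: np.ndarray) -> "float | np.ndarray":
    """Network output: hidden activations per spec, linear output node.

    Accepts a single input vector (returns a float) or a batch matrix
    (returns a 1-D array).
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = x[None, :] if single else x
    if X.shape[1] != model.spec.n_inputs:
        raise ValidationError(
            f"input width {X.shape[1]} does not match spec "
            f"n_inputs={model.spec.n_inputs}"
        )
    act = _activation(model.spec.hidden_activation)
    _, out = _forward_layers(model.weights, model.biases, act, X)
    return float(out[0]) if single else out


def classify(model: NetworkModel, x: np.ndarray) -> "int | np.ndarray":
    """Threshold decision: class 1 iff the raw output is >= 0.5 (boundary
    inclusive), applied to the output even when it falls outside [0, 1]."""
    out = forward(model, x)
    if np.isscalar(out):
        return int(out >= 0.5)
    return (out >= 0.5).astype(int)


def _batch_jacobian(spec: NetworkSpec, weights, biases, X: np.ndarray):
    """Per-sample derivatives of the network output w.r.t. every parameter.

    Returns ``(J, out)`` with ``J`` of shape (n_samples, n_parameters) in
    pack order.  Since the residual is ``output - target``, J is also the
    residual Jacobian used by Levenberg-Marquardt.
    """
    act = _activation(spec.hidden_activation)
    dact = _activation_deriv(spec.hidden_activation)
    acts, out = _forward_layers(weights, biases, act, X)
    n = X.shape[0]
    n_layers = len(weights)
    delta = np.ones((n, 1))  # d out / d (output pre-activation)
    blocks = [None] * n_layers
    for layer in reversed(range(n_layers)):
        gW = acts[layer][:, :, None] * delta[:, None, :]
        blocks[layer] = np.concatenate([gW.reshape(n, -1), delta], axis=1)
        if layer > 0:
            delta = (delta @ weights[layer].T) * dact(acts[layer])
    return np.concatenate(blocks, axis=1), out


def jacobian(model: NetworkModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Residual Jacobian and raw outputs for a batch (see _batch_jacobian)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 0:
        raise ValidationError("batch must be non-empty")
    return _batch_jacobian(model.spec, model.weights, model.biases, X)


def mse(model: NetworkModel, X: np.ndarray, y: np.ndarray) -> float:
    out = forward(model, np.atleast_2d(X))
    return float(np.mean((out - np.asarray(y, float)) ** 2))


def gradient(model: NetworkModel, X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Exact analytic gradient of the batch MSE w.r.t. the flat parameter
    vector: ``(2 / n) * J^T r`` with residuals ``r = output - target``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if X.shape[0] == 0:
        raise ValidationError("batch must be non-empty")
    J, out = _batch_jacobian(model.spec, model.weights, model.biases, X)
    r = out - y
    return (2.0 / X.shape[0]) * (J.T @ r)


# -- minimizers ---------------------------------------------------------------


def _backtracking_line_search(fval, theta, f0, g, d, c1=1e-4, shrink=0.5):
    """Armijo backtracking from unit step; falls back to the steepest-descent
    direction if ``d`` is not a descent direction.  Returns
    (theta_new, f_new) or None when no acceptable step exists."""
    gd = float(g @ d)
    if gd >= 0.0:
        d = -g
        gd = -float(g @ g)
        if gd == 0.0:
            return None
    step = 1.0
    while step > 1e-16:
        candidate = theta + step * d
        f_new = fval(candidate)
        if np.isfinite(f_new) and f_new <= f0 + c1 * step * gd:
            return candidate, f_new
        step *= shrink
    return None


class _EarlyStopper:
    """Tracks the best-validation snapshot and the patience counter."""

    def __init__(self, val_error_fn, theta0, patience: int):
        self._val = val_error_fn
        self.patience = patience
        v0 = float(self._val(theta0))
        self.best_val = v0
        self.best_theta = theta0.copy()
        self.best_iteration = 0
        self.val_history = [v0]
        self._since_best = 0

    def update(self, theta) -> bool:
        """Record one iteration; True means training should stop."""
        v = float(self._val(theta))
        self.val_history.append(v)
        if np.isfinite(v) and v < self.best_val:
            self.best_val = v
            self.best_theta = theta.copy()
            self.best_iteration = len(self.val_history) - 1
            self._since_best = 0
        else:
            self._since_best += 1
        return self._since_best >= self.patience


def _fit_gradient_based(theta, fgrad, fval, stopper, config: TrainConfig):
    """Shared loop for steepest descent, BFGS and Polak-Ribiere CG."""
    algorithm = config.algorithm
    f0, g = fgrad(theta)
    train_history = [f0]
    n_params = theta.size
    H = np.eye(n_params) if algorithm == "quasi_newton" else None
    d = -g
    iters_since_cg_restart = 0
    for _ in range(config.max_iterations):
        if not np.all(np.isfinite(g)):
            raise NumericalError("non-finite gradient encountered")
        if algorithm == "steepest_descent":
            theta_new = theta - config.learning_rate * g
            f_new = fval(theta_new)
            if not np.isfinite(f_new):
                raise NumericalError("steepest descent produced non-finite error")
        else:
            if algorithm == "quasi_newton":
                d = -(H @ g)
            result = _backtracking_line_search(fval, theta, train_history[-1], g, d)
            if result is None:
                break
            theta_new, f_new = result
        f_check, g_new = fgrad(theta_new)
        if algorithm == "quasi_newton":
            s = theta_new - theta
            yv = g_new - g
            sy = float(s @ yv)
            if sy > 1e-12:
                rho = 1.0 / sy
                Hy = H @ yv
                # BFGS inverse-Hessian update (Sherman-Morrison form)
                H = (
                    H
                    - rho * (np.outer(s, Hy) + np.outer(Hy, s))
                    + rho * (rho * float(yv @ Hy) + 1.0) * np.outer(s, s)
                )
        elif algorithm == "conjugate_gradient":
            iters_since_cg_restart += 1
            denom = float(g @ g)
            if iters_since_cg_restart >= n_params or denom == 0.0:
                d = -g_new
                iters_since_cg_restart = 0
            else:
                beta = max(0.0, float(g_new @ (g_new - g)) / denom)
                d = -g_new + beta * d
        theta, g = theta_new, g_new
        train_history.append(f_new)
        if stopper.update(theta):
            break
    return theta, train_history


def _fit_levenberg_marquardt(theta, jac_resid, stopper, config: TrainConfig):
    """Damped Gauss-Newton: solve (J^T J + lambda I) delta = -J^T r, accept on
    error decrease (divide lambda by the factor), otherwise raise lambda and
    retry.  The run stops once lambda exceeds a fixed ceiling."""
    lam = float(config.lm_lambda0)
    n = None
    train_history = None
    identity = np.eye(theta.size)
    for _ in range(config.max_iterations):
        J, r = jac_resid(theta)
        if n is None:
            n = r.size
            train_history = [float(r @ r) / n]
        g = J.T @ r
        A = J.T @ J
        sse = float(r @ r)
        accepted = False
        while lam <= _LM_LAMBDA_MAX:
            try:
                delta = np.linalg.solve(A + lam * identity, -g)
            except np.linalg.LinAlgError as exc:
                raise NumericalError(
                    f"singular Levenberg-Marquardt system at lambda={lam:g}"
                ) from exc
            _, r_new = jac_resid(theta + delta)
            sse_new = float(r_new @ r_new)
            if np.isfinite(sse_new) and sse_new < sse:
                theta = theta + delta
                lam = max(lam / config.lm_factor, 1e-14)
                accepted = True
                break
            lam = max(lam, 1e-14) * config.lm_factor
        if not accepted:
            break
        train_history.append(sse_new / n)
        if stopper.update(theta):
            break
    if train_history is None:
        train_history = []
    return theta, train_history


def _fit_once(spec: NetworkSpec, theta0, X_fit, y_fit, X_val, y_val, config):
    """One restart: minimize on the fit part, early-stop on the validation
    part, return the best-validation snapshot and its history."""
    act = _activation(spec.hidden_activation)

    def fval(theta):
        w, b = unpack_parameters(spec, theta)
        _, out = _forward_layers(w, b, act, X_fit)
        return float(np.mean((out - y_fit) ** 2))

    def fgrad(theta):
        w, b = unpack_parameters(spec, theta)
        J, out = _batch_jacobian(spec, w, b, X_fit)
        r = out - y_fit
        return float(np.mean(r**2)), (2.0 / r.size) * (J.T @ r)

    def jac_resid(theta):
        w, b = unpack_parameters(spec, theta)
        J, out = _batch_jacobian(spec, w, b, X_fit)
        return J, out - y_fit

    def val_error(theta):
        w, b = unpack_parameters(spec, theta)
        _, out = _forward_layers(w, b, act, X_val)
        return float(np.mean((out - y_val) ** 2))

    stopper = _EarlyStopper(val_error, theta0, config.patience)
    if config.algorithm == "levenberg_marquardt":
        _, train_history = _fit_levenberg_marquardt(theta0, jac_resid, stopper, config)
    else:
        _, train_history = _fit_gradient_based(theta0, fgrad, fval, stopper, config)
    history = {
        "train_mse": train_history,
        "val_mse": stopper.val_history,
        "best_iteration": stopper.best_iteration,
    }
    return stopper.best_val, stopper.best_theta, history


def _stratified_holdout(y: np.ndarray, fraction: float, rng: np.random.Generator):
    """Per-class random split into fit and validation index arrays."""
    fit_idx, val_idx = [], []
    for cls in np.unique(y):
        members = np.flatnonzero(y == cls)
        members = members[rng.permutation(members.size)]
        n_val = max(1, int(round(fraction * members.size)))
        if n_val >= members.size:
            raise ValidationError(
                f"class {cls:g} has too few members ({members.size}) for a "
                f"validation fraction of {fraction}"
            )
        val_idx.append(members[:n_val])
        fit_idx.append(members[n_val:])
    return np.sort(np.concatenate(fit_idx)), np.sort(np.concatenate(val_idx))


def train(
    spec: NetworkSpec,
    X: np.ndarray,
    y: np.ndarray,
    config: TrainConfig | None = None,
) -> TrainResult:
    """Train a network on standardized inputs with restarts and early stopping.

    The training rows are split into a fit part and a stratified validation
    holdout; the chosen minimizer runs on the fit part and the snapshot with
    minimal validation error is kept.  ``config.n_restarts`` independent
    random initializations are tried and the restart with the lowest
    validation error is returned.
    """
    config = (config or TrainConfig()).validate()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValidationError("X must be 2-D with one target per row")
    if X.shape[0] < 10:
        raise ValidationError("training requires at least 10 rows")
    if X.shape[1] != spec.n_inputs:
        raise ValidationError(
            f"feature width {X.shape[1]} does not match spec n_inputs={spec.n_inputs}"
        )

    master = np.random.default_rng(config.seed)
    fit_idx, val_idx = _stratified_holdout(y, config.validation_fraction, master)
    X_fit, y_fit = X[fit_idx], y[fit_idx]
    X_val, y_val = X[val_idx], y[val_idx]

    restart_seeds = master.integers(0, 2**31 - 1, size=config.n_restarts)
    best = None
    failures = []
    for seed in restart_seeds:
        theta0 = pack_parameters(
            *(lambda m: (m.weights, m.biases))(init_network(spec, int(seed)))
        )
        try:
            val, theta, history = _fit_once(
                spec, theta0, X_fit, y_fit, X_val, y_val, config
            )
        except NumericalError as exc:
            failures.append(f"restart seed {seed}: {exc}")
            continue
        if not np.isfinite(val):
            failures.append(f"restart seed {seed}: non-finite validation error")
            continue
        if best is None or val < best[0]:
            best = (val, theta, history, int(seed))
    if best is None:
        raise NumericalError(
            "all restarts failed: " + "; ".join(failures) if failures else
            "all restarts failed"
        )
    val, theta, history, seed = best
    weights, biases = unpack_parameters(spec, theta)
    history = dict(history, restart_failures=failures, n_restarts=config.n_restarts)
    model = NetworkModel(spec=spec, weights=weights, biases=biases, init_seed=seed)
    return TrainResult(model=model, val_error=val, history=history)
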