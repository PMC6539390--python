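"""Back-propagation neural network regressor for OD prediction.

A single sigmoid hidden layer feeding a linear output node, trained by
classic sequential back-propagation: a gradient step with classical
momentum after every sample presentation, on the half-squared
prediction error.  The architecture and hyperparameter defaults follow
the colorimetric-sensor monitoring protocol: 10 hidden neurons, learning
rate 0.1, momentum 0.1, initial weights uniform in [-0.3, 0.3], error
goal 0.01, at most 1000 epochs.

Notation: for input x, hidden unit j computes
H_j = sigmoid(sum_i w_ij x_i - theta_j) and the output node
O = sum_j H_j w_j - b (linear; a sigmoid output could not span the OD
range of a dense culture).  The tracked training error is
E = (1/N) sum_n (1/2)(O_n - y_n)^2, the per-sample half-squared error
averaged over the batch so the 0.01 goal is sample-size independent.

Exposed both as a functional API (initialize / forward / train / predict
over an explicit :class:`Network`) and as the scikit-learn estimator
:class:`BPNNRegressor`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

__all__ = [
    "Network",
    "TrainConfig",
    "TrainTrace",
    "TrainingDivergedError",
    "initialize",
    "forward",
    "train",
    "predict",
    "BPNNRegressor",
]


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes non-finite."""

    def __init__(self, epoch: int):
        self.epoch = epoch
        super().__init__(f"non-finite training error at epoch {epoch}")


@dataclass
class TrainConfig:
    """Training hyperparameters (defaults are the study protocol's)."""

    n_hidden: int = 10
    learning_rate: float = 0.1
    momentum: float = 0.1
    init_weight_scale: float = 0.3
    error_goal: float = 0.01
    max_epochs: int = 1000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 and self.learning_rate != 0.0:
            raise ValueError("learning_rate must be non-negative")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")


@dataclass
class Network:
    """Weights and thresholds of the two-layer network."""

    input_hidden_weights: np.ndarray   # (n_inputs, n_hidden), w_ij
    hidden_thresholds: np.ndarray      # (n_hidden,), theta_j
    hidden_output_weights: np.ndarray  # (n_hidden, n_out), w_jk
    output_thresholds: np.ndarray      # (n_out,), b_k

    @property
    def n_inputs(self) -> int:
        return self.input_hidden_weights.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.input_hidden_weights.shape[1]


@dataclass
class TrainTrace:
    """Per-epoch training record."""

    errors: np.ndarray          # E after each epoch's update
    epochs_run: int
    converged: bool
    gamma: np.ndarray = field(default=None)  # cumulative carried error

    def __post_init__(self) -> None:
        if self.gamma is None:
            self.gamma = np.cumsum(self.errors)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def initialize(n_inputs: int, config: TrainConfig = TrainConfig(),
               n_outputs: int = 1) -> Network:
    """Draw initial weights uniformly from [-s, s]; thresholds start at zero."""
    if n_inputs < 1:
        raise ValueError("n_inputs must be >= 1")
    rng = np.random.default_rng(config.seed)
    s = config.init_weight_scale
    return Network(
        input_hidden_weights=rng.uniform(-s, s, (n_inputs, config.n_hidden)),
        hidden_thresholds=np.zeros(config.n_hidden),
        hidden_output_weights=rng.uniform(-s, s, (config.n_hidden, n_outputs)),
        output_thresholds=np.zeros(n_outputs),
    )


def _forward_batch(net: Network, X: np.ndarray):
    H = _sigmoid(X @ net.input_hidden_weights - net.hidden_thresholds)
    O = H @ net.hidden_output_weights - net.output_thresholds
    return H, O


def forward(net: Network, x: np.ndarray) -> float:
    """Single-sample forward pass; returns the scalar OD prediction."""
    x = np.asarray(x, dtype=float)
    if x.shape != (net.n_inputs,):
        raise ValueError(f"expected input of length {net.n_inputs}")
    _, O = _forward_batch(net, x[None, :])
    return float(O[0, 0])


def predict(net: Network, X: np.ndarray) -> np.ndarray:
    """Row-wise forward pass over a sample matrix."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != net.n_inputs:
        raise ValueError(f"expected X with {net.n_inputs} columns")
    _, O = _forward_batch(net, X)
    return O[:, 0]


def gradients(net: Network, X: np.ndarray, y: np.ndarray):
    """Analytic gradients of E w.r.t. all four parameter groups.

    Returns (dW_ih, dtheta, dW_ho, db, E).  E is the batch-mean
    half-squared error of the current network.
    """
    n = X.shape[0]
    H, O = _forward_batch(net, X)
    e = O - y[:, None]                       # (n, n_out)
    E = float(0.5 * np.sum(e ** 2) / n)
    dW_ho = H.T @ e / n
    db = -e.mean(axis=0)
    back = (e @ net.hidden_output_weights.T) * H * (1.0 - H)  # (n, n_hidden)
    dW_ih = X.T @ back / n
    dtheta = -back.mean(axis=0)
    return dW_ih, dtheta, dW_ho, db, E


@njit(cache=True)
def _train_loop(W1, th, W2, b, X, y, eta, mu, max_epochs, goal):
    """Sequential (per-sample) BP with momentum; returns per-epoch E."""
    n, d = X.shape
    q = W1.shape[1]
    vW1 = np.zeros_like(W1)
    vth = np.zeros_like(th)
    vW2 = np.zeros_like(W2)
    vb = 0.0
    H = np.empty(q)
    back = np.empty(q)
    errors = np.empty(max_epochs)
    for ep in range(max_epochs):
        for s in range(n):
            for j in range(q):
                z = -th[j]
                for i in range(d):
                    z += X[s, i] * W1[i, j]
                H[j] = 1.0 / (1.0 + np.exp(-z))
            O = -b[0]
            for j in range(q):
                O += H[j] * W2[j, 0]
            e = O - y[s]
            for j in range(q):
                back[j] = e * W2[j, 0] * H[j] * (1.0 - H[j])
            for j in range(q):
                vW2[j, 0] = mu * vW2[j, 0] - eta * H[j] * e
                W2[j, 0] += vW2[j, 0]
                vth[j] = mu * vth[j] - eta * (-back[j])
                th[j] += vth[j]
                for i in range(d):
                    vW1[i, j] = mu * vW1[i, j] - eta * X[s, i] * back[j]
                    W1[i, j] += vW1[i, j]
            vb = mu * vb - eta * (-e)
            b[0] += vb
        # epoch-end error over the whole batch
        E = 0.0
        for s in range(n):
            for j in range(q):
                z = -th[j]
                for i in range(d):
                    z += X[s, i] * W1[i, j]
                H[j] = 1.0 / (1.0 + np.exp(-z))
            O = -b[0]
            for j in range(q):
                O += H[j] * W2[j, 0]
            E += 0.5 * (O - y[s]) ** 2
        E /= n
        errors[ep] = E
        if not np.isfinite(E):
            return errors[:ep + 1], ep + 1, False, True
        if E <= goal:
            return errors[:ep + 1], ep + 1, True, False
    return errors, max_epochs, False, False


def train(net: Network, X: np.ndarray, y: np.ndarray,
          config: TrainConfig = TrainConfig()) -> tuple[Network, TrainTrace]:
    """Sequential gradient descent with momentum; stops at the error goal.

    Updates follow classic back-propagation: one gradient step with
    momentum after every sample, in fixed presentation order (so
    training is deterministic given the initial weights).  E is
    recomputed over the whole batch after each epoch, so the final trace
    entry equals the error of the returned network on the training data.
    The network is updated in place and also returned.
    """
    X = np.ascontiguousarray(X, dtype=float)
    y = np.ascontiguousarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X rows must match y")
    if net.hidden_output_weights.shape[1] != 1:
        raise ValueError("train supports a single output node")
    errors, epochs_run, converged, diverged = _train_loop(
        net.input_hidden_weights, net.hidden_thresholds,
        net.hidden_output_weights, net.output_thresholds,
        X, y, config.learning_rate, config.momentum,
        config.max_epochs, config.error_goal)
    if diverged:
        raise TrainingDivergedError(epochs_run - 1)
    trace = TrainTrace(errors=np.asarray(errors), epochs_run=int(epochs_run),
                       converged=bool(converged))
    return net, trace


class BPNNRegressor(RegressorMixin, BaseEstimator):
    """Scikit-learn interface to the back-propagation network.

    Features are min-max scaled to [0, 1] using training-set ranges
    before entering the sigmoid hidden layer (raw 8-bit gray-level
    differences of up to +/-255 would saturate it); the OD target is
    left on its natural scale through the linear output node.

    Parameters mirror :class:`TrainConfig`; ``random_state`` seeds both
    weight initialization and nothing else (training is deterministic).

    Attributes
    ----------
    network_ : Network
        Trained weights and thresholds.
    trace_ : TrainTrace
        Per-epoch error record.
    scale_min_, scale_range_ : ndarray
        Per-feature min-max scaling parameters from the training set.
    """

    def __init__(self, n_hidden: int = 10, learning_rate: float = 0.1,
                 momentum: float = 0.1, init_weight_scale: float = 0.3,
                 error_goal: float = 0.01, max_epochs: int = 1000,
                 scale_inputs: bool = True, random_state: int | None = None):
        self.n_hidden = n_hidden
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.init_weight_scale = init_weight_scale
        self.error_goal = error_goal
        self.max_epochs = max_epochs
        self.scale_inputs = scale_inputs
        self.random_state = random_state

    def _config(self) -> TrainConfig:
        return TrainConfig(
            n_hidden=self.n_hidden, learning_rate=self.learning_rate,
            momentum=self.momentum, init_weight_scale=self.init_weight_scale,
            error_goal=self.error_goal, max_epochs=self.max_epochs,
            seed=self.random_state)

    def fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=True)
        if self.scale_inputs:
            self.scale_min_ = X.min(axis=0)
            rng = X.max(axis=0) - self.scale_min_
            rng[rng == 0] = 1.0  # constant feature maps to 0
            self.scale_range_ = rng
            Xs = (X - self.scale_min_) / self.scale_range_
        else:
            self.scale_min_ = np.zeros(X.shape[1])
            self.scale_range_ = np.ones(X.shape[1])
            Xs = X
        cfg = self._config()
        net = initialize(X.shape[1], cfg)
        self.network_, self.trace_ = train(net, Xs, y, cfg)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "network_")
        X = check_array(X)
        Xs = (X - self.scale_min_) / self.scale_range_
        return predict(self.network_, Xs)

    # --- JSON round-trip -------------------------------------------------

    def to_json(self) -> str:
        check_is_fitted(self, "network_")
        doc = {
            "params": self.get_params(),
            "scale_min": self.scale_min_.tolist(),
            "scale_range": self.scale_range_.tolist(),
            "network": {
                "input_hidden_weights": self.network_.input_hidden_weights.tolist(),
                "hidden_thresholds": self.network_.hidden_thresholds.tolist(),
                "hidden_output_weights": self.network_.hidden_output_weights.tolist(),
                "output_thresholds": self.network_.output_thresholds.tolist(),
            },
        }
        return json.dumps(doc, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "BPNNRegressor":
        doc = json.loads(text)
        est = cls(**doc["params"])
        est.scale_min_ = np.asarray(doc["scale_min"])
        est.scale_range_ = np.asarray(doc["scale_range"])
        net = doc["network"]
        est.network_ = Network(
            input_hidden_weights=np.asarray(net["input_hidden_weights"]),
            hidden_thresholds=np.asarray(net["hidden_thresholds"]),
            hidden_output_weights=np.asarray(net["hidden_output_weights"]),
            output_thresholds=np.asarray(net["output_thresholds"]),
        )
        est.n_features_in_ = est.network_.n_inputs
        est.trace_ = TrainTrace(errors=np.asarray([]), epochs_run=0,
                                converged=False)
        return est
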