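"""Feedforward 4-h-1 backpropagation surrogate for extraction yield.

The network has four inputs (the process factors), one logistic-sigmoid
hidden layer of ``h`` neurons, and a linear output neuron for yield.
Inputs and the output are min-max normalized to [−1, 1] with parameters
frozen at training time.  Training is batch gradient descent on the mean
squared error of normalized outputs, with classic momentum and, by
default, the adaptive learning-rate rule of toolbox-era BP trainers: grow
the rate slightly after an improving epoch, shrink it and reject the step
when the error worsens by more than a few percent.  Training stops at the
epoch cap or once the epoch MSE falls below the target error; the
best-so-far weights (by training error) are returned together with the
per-epoch error trace.

The weight vector layout is: input→hidden matrix (h×4, row-major), hidden
biases (h), hidden→output weights (h), output bias (1) — 6h+1 values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .data_io import DesignTable
from .errors import DimensionError, TrainingError

__all__ = [
    "MLPSurrogate",
    "TrainConfig",
    "n_weights",
    "init_weights",
    "forward",
    "loss_and_gradient",
    "train_bp",
    "predict_mlp",
    "golden_section_hidden_search",
    "golden_section_minimize",
]

N_INPUTS = 4


def n_weights(n_hidden: int) -> int:
    """Length of the flat weight vector for a 4-h-1 network."""
    return 6 * n_hidden + 1


@dataclass
class Normalization:
    """Frozen per-feature min-max maps onto [−1, 1]."""

    x_min: np.ndarray
    x_max: np.ndarray
    y_min: float
    y_max: float

    @classmethod
    def fit(cls, X: np.ndarray, y: np.ndarray) -> "Normalization":
        x_min, x_max = X.min(axis=0), X.max(axis=0)
        if np.any(x_max - x_min == 0):
            raise ValueError("constant input feature cannot be normalized")
        if y.max() - y.min() == 0:
            raise ValueError("constant response cannot be normalized")
        return cls(x_min, x_max, float(y.min()), float(y.max()))

    def norm_x(self, X: np.ndarray) -> np.ndarray:
        return 2.0 * (X - self.x_min) / (self.x_max - self.x_min) - 1.0

    def norm_y(self, y):
        return 2.0 * (y - self.y_min) / (self.y_max - self.y_min) - 1.0

    def denorm_y(self, yn):
        return (yn + 1.0) / 2.0 * (self.y_max - self.y_min) + self.y_min

    def to_dict(self):
        return {"x_min": self.x_min.tolist(), "x_max": self.x_max.tolist(),
                "y_min": self.y_min, "y_max": self.y_max}

    @classmethod
    def from_dict(cls, d):
        return cls(np.asarray(d["x_min"], float), np.asarray(d["x_max"], float),
                   d["y_min"], d["y_max"])


@dataclass
class TrainConfig:
    """Supervised-training configuration for the BP network."""

    max_epochs: int = 1000
    target_error: float = 1e-5
    learning_rate: float = 0.05
    momentum: float = 0.9
    adaptive_lr: bool = True
    lr_increase: float = 1.05
    lr_decrease: float = 0.7
    max_error_growth: float = 1.04
    seed: Optional[int] = None

    def __post_init__(self):
        if self.max_epochs < 1:
            raise ValueError(f"max_epochs must be >= 1, got {self.max_epochs}")
        if self.target_error <= 0:
            raise ValueError(f"target_error must be > 0, got {self.target_error}")


@dataclass
class MLPSurrogate:
    """A 4-h-1 network plus its frozen normalization."""

    n_hidden: int
    weights: np.ndarray
    normalization: Optional[Normalization] = None

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        expected = n_weights(self.n_hidden)
        if self.weights.shape != (expected,):
            raise DimensionError(
                f"4-{self.n_hidden}-1 network needs {expected} weights, "
                f"got {self.weights.shape}"
            )

    def unpack(self):
        h, w = self.n_hidden, self.weights
        return (w[: 4 * h].reshape(h, 4), w[4 * h : 5 * h],
                w[5 * h : 6 * h], w[6 * h])

    def predict(self, points) -> np.ndarray:
        return predict_mlp(self, points)

    def to_dict(self) -> dict:
        return {
            "n_hidden": self.n_hidden,
            "weights": self.weights.tolist(),
            "normalization": None if self.normalization is None
            else self.normalization.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MLPSurrogate":
        norm = None if d["normalization"] is None else Normalization.from_dict(d["normalization"])
        return cls(d["n_hidden"], np.asarray(d["weights"], float), norm)


def init_weights(n_hidden: int, seed: Optional[int] = None,
                 external_vector=None) -> np.ndarray:
    """Uniform [−1, 1] random initialization, or verbatim adoption of an
    externally optimized vector (the GA-ACO hand-off)."""
    if n_hidden < 1:
        raise ValueError(f"n_hidden must be >= 1, got {n_hidden}")
    expected = n_weights(n_hidden)
    if external_vector is not None:
        w = np.asarray(external_vector, dtype=float)
        if w.shape != (expected,):
            raise DimensionError(
                f"external vector has length {w.size}, expected {expected} "
                f"for h={n_hidden}"
            )
        return w.copy()
    rng = np.random.default_rng(seed)
    return rng.uniform(-1.0, 1.0, expected)


def forward(weights: np.ndarray, n_hidden: int, Xn: np.ndarray) -> np.ndarray:
    """Normalized-space forward pass for a flat weight vector."""
    h = n_hidden
    W1 = weights[: 4 * h].reshape(h, 4)
    b1 = weights[4 * h : 5 * h]
    W2 = weights[5 * h : 6 * h]
    b2 = weights[6 * h]
    A = 1.0 / (1.0 + np.exp(-(Xn @ W1.T + b1)))
    return A @ W2 + b2


def loss_and_gradient(weights: np.ndarray, n_hidden: int,
                      Xn: np.ndarray, yn: np.ndarray):
    """Mean-squared error and its analytic gradient (backpropagation)."""
    h, n = n_hidden, len(yn)
    W1 = weights[: 4 * h].reshape(h, 4)
    b1 = weights[4 * h : 5 * h]
    W2 = weights[5 * h : 6 * h]
    Zh = Xn @ W1.T + b1
    A = 1.0 / (1.0 + np.exp(-Zh))
    out = A @ W2 + weights[6 * h]
    e = out - yn
    loss = float(e @ e) / n
    g_out = 2.0 * e / n
    g_W2 = A.T @ g_out
    g_b2 = g_out.sum()
    g_Z = np.outer(g_out, W2) * A * (1.0 - A)
    g_W1 = g_Z.T @ Xn
    g_b1 = g_Z.sum(axis=0)
    grad = np.concatenate([g_W1.ravel(), g_b1, g_W2, [g_b2]])
    return loss, grad


@dataclass
class TrainingTrace:
    """Per-epoch training error and the epoch count actually run."""

    errors: np.ndarray
    n_epochs: int
    converged: bool  # stopped because MSE < target_error


def train_bp(net: MLPSurrogate, data: DesignTable, config: TrainConfig = TrainConfig()):
    """Batch-gradient-descent backpropagation training.

    Returns a new :class:`MLPSurrogate` carrying the best-so-far weights
    (lowest training MSE seen at any epoch) plus the training trace.
    """
    X, y = data.factors, data.yields
    if len(y) == 0 or np.isnan(y).any():
        raise ValueError("training data must be non-empty with observed yields")
    norm = net.normalization or Normalization.fit(X, y)
    Xn, yn = norm.norm_x(X), norm.norm_y(y)

    h = net.n_hidden
    w = net.weights.copy()
    velocity = np.zeros_like(w)
    lr = config.learning_rate
    best_w, best_loss = w.copy(), np.inf
    errors = []
    loss, grad = loss_and_gradient(w, h, Xn, yn)
    converged = False
    for epoch in range(config.max_epochs):
        if not np.isfinite(loss):
            raise TrainingError(f"non-finite training loss at epoch {epoch}")
        errors.append(loss)
        if loss < best_loss:
            best_loss, best_w = loss, w.copy()
        if loss < config.target_error:
            converged = True
            break
        velocity = config.momentum * velocity - lr * grad
        w_new = w + velocity
        new_loss, new_grad = loss_and_gradient(w_new, h, Xn, yn)
        if config.adaptive_lr and new_loss > loss * config.max_error_growth:
            lr *= config.lr_decrease  # reject the step, damp the rate
            velocity = np.zeros_like(w)
        else:
            if config.adaptive_lr and new_loss < loss:
                lr *= config.lr_increase
            w, loss, grad = w_new, new_loss, new_grad
    trained = MLPSurrogate(h, best_w, norm)
    return trained, TrainingTrace(np.asarray(errors), len(errors), converged)


def predict_mlp(net: MLPSurrogate, points) -> np.ndarray:
    """Denormalized yield prediction at points in actual factor units."""
    if net.normalization is None:
        raise ValueError("network has no frozen normalization; train it first")
    pts = np.asarray(points, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    out = net.normalization.denorm_y(forward(net.weights, net.n_hidden,
                                             net.normalization.norm_x(pts)))
    return float(out[0]) if single else out


def _validation_mse(h, train_table, valid_table, config, seed):
    net = MLPSurrogate(h, init_weights(h, seed=seed))
    trained, _ = train_bp(net, train_table, config)
    pred = predict_mlp(trained, valid_table.factors)
    return float(np.mean((pred - valid_table.yields) ** 2))


def golden_section_hidden_search(train_table: DesignTable, valid_table: DesignTable,
                                 h_range=(6, 12), config: TrainConfig = TrainConfig(),
                                 n_seeds: int = 3, base_seed: int = 0):
    """Golden-section search for the hidden-layer size minimizing MSE.

    Probes are rounded to integers over ``[h_lo, h_hi]``; each candidate is
    scored by validation MSE averaged over ``n_seeds`` random
    initializations.  Every probed size is evaluated at most once.

    Returns
    -------
    (best_h, table) : int and dict mapping probed h -> mean validation MSE.
    """
    def score(h: int) -> float:
        return float(np.mean([
            _validation_mse(h, train_table, valid_table, config,
                            seed=base_seed * 1000 + 97 * h + s)
            for s in range(n_seeds)
        ]))

    return golden_section_minimize(score, int(h_range[0]), int(h_range[1]))


def golden_section_minimize(score, h_lo: int, h_hi: int):
    """Golden-section bracketing over an integer interval.

    Probes are rounded to integers and each is scored at most once; for a
    unimodal profile the bracketing converges on the argmin.  Returns
    ``(best, probed)`` where ``probed`` maps every evaluated integer to its
    score.
    """
    if h_lo > h_hi:
        raise ValueError(f"empty range ({h_lo}, {h_hi})")
    cache: dict = {}

    def probe(h: int) -> float:
        if h not in cache:
            cache[h] = score(h)
        return cache[h]

    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = h_lo, h_hi
    while b - a > 2:
        offset = int(round(invphi * (b - a)))
        c, d = b - offset, a + offset
        if c == d:  # integer rounding collapsed the interior points
            d += 1
        if probe(c) <= probe(d):
            b = d  # min lies in [a, d]; d < b so the interval shrinks
        else:
            a = c
    for h in range(a, b + 1):
        probe(h)
    best = min(cache, key=cache.get)
    return best, dict(sorted(cache.items()))
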