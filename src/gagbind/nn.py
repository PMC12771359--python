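"""A small fully connected neural network regressor in pure NumPy.

Implements the pieces the benchmarking protocol needs from an MLP: arbitrary
hidden-layer stacks (including the zero-hidden-layer "input -> 1" linear map),
six activation functions, inverted dropout (applied to the input layer and
after every hidden activation), the Adam optimiser with L2 weight decay,
mean-squared-error loss, early stopping on a carved-out validation fraction,
learning-rate reduction on plateau, and Monte Carlo dropout prediction
(stochastic forward passes with dropout left on at inference).

All randomness -- initialisation, mini-batch shuffling, dropout masks, the
early-stopping carve-out and MC-dropout passes -- flows from a single seed,
so training and prediction are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf, expit

_SQRT2 = math.sqrt(2.0)
_INV_SQRT2PI = 1.0 / math.sqrt(2.0 * math.pi)


def _gelu(x):
    return 0.5 * x * (1.0 + erf(x / _SQRT2))


def _gelu_grad(x):
    return 0.5 * (1.0 + erf(x / _SQRT2)) + x * _INV_SQRT2PI * np.exp(-0.5 * x * x)


ACTIVATIONS = {
    "relu": (lambda x: np.maximum(x, 0.0), lambda x: (x > 0).astype(float)),
    "elu": (
        lambda x: np.where(x > 0, x, np.expm1(x)),
        lambda x: np.where(x > 0, 1.0, np.exp(x)),
    ),
    "gelu": (_gelu, _gelu_grad),
    "leaky_relu": (
        lambda x: np.where(x > 0, x, 0.01 * x),
        lambda x: np.where(x > 0, 1.0, 0.01),
    ),
    "sigmoid": (expit, lambda x: expit(x) * (1.0 - expit(x))),
    "tanh": (np.tanh, lambda x: 1.0 - np.tanh(x) ** 2),
}


@dataclass
class FCNNConfig:
    """Architecture and optimisation settings for the MLP regressor.

    ``hidden_sizes`` excludes the input width and the final width-1 output;
    an empty tuple gives the plain linear "input -> 1" map (with dropout still
    applied to the input layer).
    """

    hidden_sizes: tuple[int, ...] = ()
    dropout_rate: float = 0.01
    activation: str = "relu"
    learning_rate: float = 1e-3
    weight_decay: float = 1e-4
    batch_size: int = 256
    max_epochs: int = 200
    early_stop_patience: int = 15
    plateau_factor: float = 0.5
    plateau_patience: int = 7
    val_fraction: float = 0.1
    mc_passes: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.activation not in ACTIVATIONS:
            raise ValueError(
                f"unknown activation {self.activation!r}; choose from {sorted(ACTIVATIONS)}"
            )


class FCNNRegressor:
    """Feed-forward MSE regressor with dropout, Adam and early stopping."""

    def __init__(self, config: FCNNConfig | None = None, **overrides):
        if config is None:
            config = FCNNConfig(**overrides)
        elif overrides:
            raise ValueError("pass either a config or keyword overrides, not both")
        self.config = config
        self.weights_: list[np.ndarray] | None = None
        self.biases_: list[np.ndarray] | None = None
        self.history_: dict = {}

    # -- internals ---------------------------------------------------------

    def _init_params(self, n_features: int, rng: np.random.Generator):
        sizes = [n_features, *self.config.hidden_sizes, 1]
        weights, biases = [], []
        for layer, (fan_in, fan_out) in enumerate(zip(sizes[:-1], sizes[1:])):
            if layer == len(sizes) - 2:
                # zero-initialised output layer: the net starts at the target
                # mean, so optimisation only has to travel the signal distance
                weights.append(np.zeros((fan_in, fan_out)))
            else:
                limit = math.sqrt(6.0 / (fan_in + fan_out))
                weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
            biases.append(np.zeros(fan_out))
        return weights, biases

    def _forward(self, X, weights, biases, rng=None):
        """Returns (output, cache); dropout is active iff ``rng`` is given."""
        act, _ = ACTIVATIONS[self.config.activation]
        p = self.config.dropout_rate
        a = X
        cache = {"inputs": [], "pre": [], "masks": []}
        for layer, (W, b) in enumerate(zip(weights, biases)):
            if rng is not None and p > 0:
                mask = (rng.random(a.shape) >= p) / (1.0 - p)
                a = a * mask
            else:
                mask = None
            cache["masks"].append(mask)
            cache["inputs"].append(a)
            z = a @ W + b
            cache["pre"].append(z)
            a = act(z) if layer < len(weights) - 1 else z
        return a[:, 0], cache

    def _backward(self, y_pred, y_true, weights, cache):
        _, act_grad = ACTIVATIONS[self.config.activation]
        n = len(y_true)
        delta = (2.0 / n) * (y_pred - y_true)[:, None]
        grads_w, grads_b = [None] * len(weights), [None] * len(weights)
        for layer in range(len(weights) - 1, -1, -1):
            a_in = cache["inputs"][layer]
            grads_w[layer] = a_in.T @ delta
            grads_b[layer] = delta.sum(axis=0)
            if layer > 0:
                delta = delta @ weights[layer].T
                mask = cache["masks"][layer]
                if mask is not None:
                    delta = delta * mask
                delta = delta * act_grad(cache["pre"][layer - 1])
        return grads_w, grads_b

    # -- public API --------------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray) -> "FCNNRegressor":
        cfg = self.config
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        # standardise the target internally: Adam's per-step displacement is
        # bounded by the learning rate, so training in target units of kcal/mol
        # would need step counts proportional to the energy scale
        self.y_mean_ = float(y.mean())
        self.y_scale_ = float(y.std()) or 1.0
        y = (y - self.y_mean_) / self.y_scale_
        rng = np.random.default_rng(cfg.seed)
        n = len(X)

        n_val = max(1, int(round(cfg.val_fraction * n))) if n >= 20 else 0
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        X_tr, y_tr = X[tr_idx], y[tr_idx]
        X_val, y_val = X[val_idx], y[val_idx]

        weights, biases = self._init_params(X.shape[1], rng)
        m_w = [np.zeros_like(w) for w in weights]
        v_w = [np.zeros_like(w) for w in weights]
        m_b = [np.zeros_like(b) for b in biases]
        v_b = [np.zeros_like(b) for b in biases]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        lr = cfg.learning_rate
        t = 0

        best_loss = np.inf
        best_params = None
        stall_stop = 0
        stall_lr = 0
        history = {"train_loss": [], "val_loss": [], "lr": []}

        for epoch in range(cfg.max_epochs):
            order = rng.permutation(len(X_tr))
            for start in range(0, len(X_tr), cfg.batch_size):
                batch = order[start : start + cfg.batch_size]
                y_pred, cache = self._forward(X_tr[batch], weights, biases, rng=rng)
                grads_w, grads_b = self._backward(y_pred, y_tr[batch], weights, cache)
                t += 1
                for i in range(len(weights)):
                    gw = grads_w[i] + cfg.weight_decay * weights[i]
                    m_w[i] = beta1 * m_w[i] + (1 - beta1) * gw
                    v_w[i] = beta2 * v_w[i] + (1 - beta2) * gw * gw
                    weights[i] -= lr * (m_w[i] / (1 - beta1**t)) / (
                        np.sqrt(v_w[i] / (1 - beta2**t)) + eps
                    )
                    gb = grads_b[i]
                    m_b[i] = beta1 * m_b[i] + (1 - beta1) * gb
                    v_b[i] = beta2 * v_b[i] + (1 - beta2) * gb * gb
                    biases[i] -= lr * (m_b[i] / (1 - beta1**t)) / (
                        np.sqrt(v_b[i] / (1 - beta2**t)) + eps
                    )

            train_pred, _ = self._forward(X_tr, weights, biases)
            train_loss = float(np.mean((train_pred - y_tr) ** 2))
            if n_val:
                val_pred, _ = self._forward(X_val, weights, biases)
                monitor = float(np.mean((val_pred - y_val) ** 2))
            else:
                monitor = train_loss
            history["train_loss"].append(train_loss)
            history["val_loss"].append(monitor)
            history["lr"].append(lr)

            if monitor < best_loss - 1e-12:
                best_loss = monitor
                best_params = ([w.copy() for w in weights], [b.copy() for b in biases])
                stall_stop = 0
                stall_lr = 0
            else:
                stall_stop += 1
                stall_lr += 1
                if stall_lr > cfg.plateau_patience:
                    lr *= cfg.plateau_factor
                    stall_lr = 0
                if stall_stop >= cfg.early_stop_patience:
                    break

        if best_params is not None:
            weights, biases = best_params
        self.weights_, self.biases_ = weights, biases
        self.history_ = history
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Deterministic prediction (dropout disabled)."""
        if self.weights_ is None:
            raise RuntimeError("model is not fitted")
        out, _ = self._forward(np.asarray(X, dtype=float), self.weights_, self.biases_)
        return out * self.y_scale_ + self.y_mean_

    def mc_predict(
        self, X: np.ndarray, n_passes: int | None = None, seed: int | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """Monte Carlo dropout: per-row mean and std over stochastic passes.

        With ``dropout_rate == 0`` every pass is identical and the std is
        exactly zero.
        """
        if self.weights_ is None:
            raise RuntimeError("model is not fitted")
        n_passes = n_passes or self.config.mc_passes
        rng = np.random.default_rng(self.config.seed + 1 if seed is None else seed)
        X = np.asarray(X, dtype=float)
        if self.config.dropout_rate == 0 or n_passes == 1:
            # every stochastic pass is identical; the spread is exactly zero
            out = self.predict(X)
            return out, np.zeros_like(out)
        draws = np.empty((n_passes, len(X)))
        for k in range(n_passes):
            out, _ = self._forward(X, self.weights_, self.biases_, rng=rng)
            draws[k] = out * self.y_scale_ + self.y_mean_
        return draws.mean(axis=0), draws.std(axis=0)

    # weight introspection (zero-hidden-layer models are linear maps)

    @property
    def linear_weights(self) -> np.ndarray:
        """Fitted coefficients in original target units (zero-hidden models only)."""
        if self.weights_ is None:
            raise RuntimeError("model is not fitted")
        if self.config.hidden_sizes:
            raise ValueError("linear weights are only defined for zero-hidden-layer models")
        return self.weights_[0][:, 0] * self.y_scale_
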