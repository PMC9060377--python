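"""Multitask feed-forward network: forward pass, dropout, momentum-SGD training.

The architecture is fixed at two hidden layers feeding four output neurons,
one per electrophysiological parameter (I_Ks, V1/2, tau_act, tau_deact).
Hidden units use a leaky rectifier, f(x) = x for x > 0 and 0.05*x otherwise;
the output neurons are logistic so every prediction lies in [0, 1] and can be
thresholded.  Dropout uses inverted scaling (activations divided by the keep
probability at training time), so inference needs no rescaling.  Training is
momentum SGD over mini-batch passes of the training fold on a
binary-cross-entropy surrogate in the classic total-error convention (summed
over patterns and output neurons); classification accuracy at threshold 0.5
on a held-out monitor set is tracked periodically and the best snapshot (ties
broken toward the later one) is returned.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .features import FeatureScaler

N_OUTPUTS = 4
LEAKY_SLOPE = 0.05


class NetworkError(ValueError):
    """Shape mismatch, invalid configuration, or diverged training."""


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture and optimization hyper-parameters.

    Published configurations per feature set (see :func:`config_for`):
    32 first-hidden units with 33% dropout in all models; the
    biophysical-only model uses 8 second-hidden units without dropout and 20%
    input dropout, the other two use 12 second-hidden units with 33% dropout
    and 5% input dropout.
    """

    n_inputs: int
    hidden1: int = 32
    hidden2: int = 12
    input_dropout: float = 0.05
    hidden1_dropout: float = 0.33
    hidden2_dropout: float = 0.33
    leaky_slope: float = LEAKY_SLOPE
    learning_rate: float = 0.001
    momentum: float = 0.5
    iterations: int = 1200
    batch_size: int | None = 32  # None = full-batch updates
    monitor_every: int = 10
    loss: str = "bce"  # or "mse"

    def __post_init__(self):
        if min(self.n_inputs, self.hidden1, self.hidden2) < 1:
            raise NetworkError("layer sizes must be >= 1")
        for r in (self.input_dropout, self.hidden1_dropout, self.hidden2_dropout):
            if not 0.0 <= r < 1.0:
                raise NetworkError("dropout rates must lie in [0, 1)")
        if self.loss not in ("bce", "mse"):
            raise NetworkError(f"unknown loss {self.loss!r}")


def config_for(feature_set: str, **overrides) -> NetworkConfig:
    """The published hyper-parameters for BIOPHYS14 / EVO2 / COMBINED12."""
    presets = {
        "BIOPHYS14": dict(n_inputs=14, hidden2=8, hidden2_dropout=0.0, input_dropout=0.20),
        "EVO2": dict(n_inputs=2, hidden2=12, hidden2_dropout=0.33, input_dropout=0.05),
        "COMBINED12": dict(n_inputs=12, hidden2=12, hidden2_dropout=0.33, input_dropout=0.05),
    }
    if feature_set not in presets:
        raise NetworkError(f"unknown feature set {feature_set!r}")
    kwargs = presets[feature_set]
    kwargs.update(overrides)
    return NetworkConfig(**kwargs)


def leaky_relu(x, slope: float = LEAKY_SLOPE):
    x = np.asarray(x, dtype=float)
    return np.where(x > 0, x, slope * x)


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def parameter_count(config: NetworkConfig) -> int:
    """Total trainable weights + biases across the three layer transitions."""
    sizes = (config.n_inputs, config.hidden1, config.hidden2, N_OUTPUTS)
    return sum(a * b + b for a, b in zip(sizes, sizes[1:]))


def _init_weights(config: NetworkConfig, rng: np.random.Generator):
    sizes = (config.n_inputs, config.hidden1, config.hidden2, N_OUTPUTS)
    Ws, bs = [], []
    for fan_in, fan_out in zip(sizes, sizes[1:]):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        Ws.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
        bs.append(np.zeros(fan_out))
    return Ws, bs


@dataclass
class TrainedModel:
    """Weights, fitted feature scaler, and the configuration that produced them."""

    config: NetworkConfig
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    scaler: FeatureScaler | None = None
    monitor_accuracy: float = float("nan")

    def predict(self, X: np.ndarray, scaled: bool = False) -> np.ndarray:
        """Four scores in [0, 1] per row; applies the model's scaler unless
        ``scaled`` says the input is already standardized."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if not scaled and self.scaler is not None:
            X = self.scaler.transform(X)
        return forward(self, X)

    def to_dict(self) -> dict:
        return {
            "config": self.config.__dict__,
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "scaler": self.scaler.to_dict() if self.scaler else None,
            "monitor_accuracy": self.monitor_accuracy,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrainedModel":
        return cls(
            config=NetworkConfig(**d["config"]),
            weights=[np.asarray(w, dtype=float) for w in d["weights"]],
            biases=[np.asarray(b, dtype=float) for b in d["biases"]],
            scaler=FeatureScaler.from_dict(d["scaler"]) if d.get("scaler") else None,
            monitor_accuracy=d.get("monitor_accuracy", float("nan")),
        )


def forward(
    model: TrainedModel,
    X: np.ndarray,
    training_mode: bool = False,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Forward pass on standardized inputs -> (n, 4) scores in [0, 1].

    ``training_mode`` applies inverted-scaling dropout masks drawn from
    ``rng``; inference (default) is deterministic and mask-free.
    """
    out, _ = _forward_cached(model, X, training_mode, rng)
    return out


def _dropout_mask(shape, rate, rng):
    if rate == 0.0:
        return None
    keep = 1.0 - rate
    return (rng.random(shape) < keep).astype(float) / keep


def _forward_cached(model, X, training_mode, rng):
    cfg = model.config
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != cfg.n_inputs:
        raise NetworkError(f"expected {cfg.n_inputs} inputs, got {X.shape[1]}")
    if training_mode and rng is None:
        raise NetworkError("training-mode forward pass needs an rng for dropout")
    W1, W2, W3 = model.weights
    b1, b2, b3 = model.biases
    cache = {}
    a0 = X
    if training_mode:
        m0 = _dropout_mask(X.shape, cfg.input_dropout, rng)
        if m0 is not None:
            a0 = X * m0
        cache["m0"] = m0
    z1 = a0 @ W1 + b1
    h1 = leaky_relu(z1, cfg.leaky_slope)
    if training_mode:
        m1 = _dropout_mask(h1.shape, cfg.hidden1_dropout, rng)
        if m1 is not None:
            h1 = h1 * m1
        cache["m1"] = m1
    z2 = h1 @ W2 + b2
    h2 = leaky_relu(z2, cfg.leaky_slope)
    if training_mode:
        m2 = _dropout_mask(h2.shape, cfg.hidden2_dropout, rng)
        if m2 is not None:
            h2 = h2 * m2
        cache["m2"] = m2
    z3 = h2 @ W3 + b3
    out = _sigmoid(z3)
    cache.update(a0=a0, z1=z1, h1=h1, z2=z2, h2=h2, out=out)
    return out, cache


def loss_value(model: TrainedModel, X: np.ndarray, Y: np.ndarray) -> float:
    """Surrogate loss (no dropout): mean BCE or MSE over all outputs."""
    P = forward(model, X)
    Y = np.asarray(Y, dtype=float)
    if model.config.loss == "mse":
        return float(np.sum((P - Y) ** 2))
    eps = 1e-12
    P = np.clip(P, eps, 1.0 - eps)
    return float(-np.sum(Y * np.log(P) + (1.0 - Y) * np.log(1.0 - P)))


def _gradients(model, X, Y, training_mode, rng):
    """Backpropagation of the surrogate loss; returns (loss, dWs, dbs)."""
    cfg = model.config
    out, c = _forward_cached(model, X, training_mode, rng)
    Y = np.asarray(Y, dtype=float)
    n = X.shape[0]
    eps = 1e-12
    # classic total-error convention: the loss (and hence the gradient the
    # learning rate multiplies) is summed over patterns and output neurons,
    # as in per-pattern backpropagation accumulated over the batch
    if cfg.loss == "mse":
        loss = float(np.sum((out - Y) ** 2))
        dz3 = 2.0 * (out - Y) * out * (1.0 - out)
    else:
        P = np.clip(out, eps, 1.0 - eps)
        loss = float(-np.sum(Y * np.log(P) + (1.0 - Y) * np.log(1.0 - P)))
        # BCE + sigmoid collapses to p - y
        dz3 = out - Y
    W1, W2, W3 = model.weights
    dW3 = c["h2"].T @ dz3
    db3 = dz3.sum(axis=0)
    dh2 = dz3 @ W3.T
    if training_mode and c.get("m2") is not None:
        dh2 = dh2 * c["m2"]
    dz2 = dh2 * np.where(c["z2"] > 0, 1.0, cfg.leaky_slope)
    dW2 = c["h1"].T @ dz2
    db2 = dz2.sum(axis=0)
    dh1 = dz2 @ W2.T
    if training_mode and c.get("m1") is not None:
        dh1 = dh1 * c["m1"]
    dz1 = dh1 * np.where(c["z1"] > 0, 1.0, cfg.leaky_slope)
    dW1 = c["a0"].T @ dz1
    db1 = dz1.sum(axis=0)
    return loss, [dW1, dW2, dW3], [db1, db2, db3]


def accuracy_at_half(model: TrainedModel, X: np.ndarray, Y: np.ndarray) -> float:
    """Classification accuracy at threshold 0.5, averaged over the four outputs."""
    P = forward(model, X)
    return float(np.mean((P >= 0.5).astype(int) == np.asarray(Y, dtype=int)))


def train(
    train_X: np.ndarray,
    train_Y: np.ndarray,
    monitor_X: np.ndarray,
    monitor_Y: np.ndarray,
    config: NetworkConfig,
    seed: int,
    scaler: FeatureScaler | None = None,
) -> TrainedModel:
    """Momentum-SGD training with periodic monitor-accuracy snapshot selection.

    Inputs must already be standardized (the caller fits the scaler on the
    training fold only and passes it in for bookkeeping).  Runs
    ``config.iterations`` full-batch updates; every ``config.monitor_every``
    iterations the monitor accuracy at threshold 0.5 is recorded and the
    best-scoring weight snapshot (later wins ties) is kept.
    """
    train_X = np.atleast_2d(np.asarray(train_X, dtype=float))
    train_Y = np.atleast_2d(np.asarray(train_Y, dtype=float))
    if train_X.shape[0] == 0 or monitor_X is None or len(monitor_X) == 0:
        raise NetworkError("training and monitor sets must be non-empty")
    if train_X.shape[1] != config.n_inputs:
        raise NetworkError(
            f"feature length {train_X.shape[1]} does not match config.n_inputs "
            f"{config.n_inputs}"
        )
    rng = np.random.default_rng(seed)
    Ws, bs = _init_weights(config, rng)
    model = TrainedModel(config, Ws, bs, scaler=scaler)
    vWs = [np.zeros_like(w) for w in Ws]
    vbs = [np.zeros_like(b) for b in bs]
    best_acc = -np.inf
    best_snapshot = None
    n = train_X.shape[0]
    batch = config.batch_size or n
    for it in range(1, config.iterations + 1):
        # one iteration = one pass over the shuffled fold in mini-batches
        order = rng.permutation(n) if batch < n else np.arange(n)
        for start in range(0, n, batch):
            sel = order[start : start + batch]
            loss, dWs, dbs = _gradients(model, train_X[sel], train_Y[sel], True, rng)
            if not np.isfinite(loss):
                raise NetworkError(
                    f"training diverged (non-finite loss) at iteration {it}"
                )
            for k in range(3):
                vWs[k] = config.momentum * vWs[k] - config.learning_rate * dWs[k]
                vbs[k] = config.momentum * vbs[k] - config.learning_rate * dbs[k]
                Ws[k] += vWs[k]
                bs[k] += vbs[k]
        if it % config.monitor_every == 0 or it == config.iterations:
            acc = accuracy_at_half(model, monitor_X, monitor_Y)
            if acc >= best_acc:  # >= keeps the later snapshot on ties
                best_acc = acc
                best_snapshot = ([w.copy() for w in Ws], [b.copy() for b in bs])
    model.weights, model.biases = best_snapshot
    model.monitor_accuracy = float(best_acc)
    return model


@dataclass
class TrainedEnsemble:
    """The cross-validation committee: prediction = mean over member models."""

    models: list[TrainedModel]
    feature_set: str
    thresholds: np.ndarray | None = None  # per-output decision thresholds

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Mean of member predictions on raw (unscaled) feature rows."""
        preds = [m.predict(X) for m in self.models]
        return np.mean(preds, axis=0)

    def classify(self, X: np.ndarray) -> np.ndarray:
        if self.thresholds is None:
            raise NetworkError("ensemble has no tuned thresholds")
        return (self.predict(X) >= self.thresholds).astype(int)

    def to_dict(self) -> dict:
        return {
            "feature_set": self.feature_set,
            "thresholds": None if self.thresholds is None else list(map(float, self.thresholds)),
            "models": [m.to_dict() for m in self.models],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrainedEnsemble":
        return cls(
            models=[TrainedModel.from_dict(m) for m in d["models"]],
            feature_set=d["feature_set"],
            thresholds=None if d["thresholds"] is None else np.asarray(d["thresholds"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "TrainedEnsemble":
        return cls.from_dict(json.loads(Path(path).read_text()))
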