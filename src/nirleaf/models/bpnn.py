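"""Backpropagation neural network (single-hidden-layer MLP).

Sigmoid activations on the hidden and output layers, squared error against
one-hot targets, and full-batch gradient descent — the classical shallow
network the convolutional model is compared against.  The default learning
rate is 1e-4, the value used for the baseline models; it is deliberately
conservative and small toy problems (e.g. XOR) want a larger rate and more
epochs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import ParameterError, TrainingError
from .base import BaseClassifier, check_Xy, one_hot
from .elm import _sigmoid

__all__ = ["BPNNConfig", "BPNNClassifier"]


@dataclass
class BPNNConfig:
    n_hidden: int = 20
    learning_rate: float = 1e-4
    epochs: int = 1000
    seed: int = 0
    n_classes: int = 5


class BPNNClassifier(BaseClassifier):
    def __init__(self, config: BPNNConfig | None = None, **kwargs):
        self.config = config or BPNNConfig(**kwargs)
        if self.config.n_hidden < 1:
            raise ParameterError(f"n_hidden must be >= 1, got {self.config.n_hidden}")
        self.loss_history: list[float] = []

    def _init_weights(self, n_features: int) -> None:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        # Xavier-style uniform scaling keeps sigmoid units out of saturation
        s1 = np.sqrt(6.0 / (n_features + cfg.n_hidden))
        s2 = np.sqrt(6.0 / (cfg.n_hidden + cfg.n_classes))
        self.W1 = rng.uniform(-s1, s1, size=(n_features, cfg.n_hidden))
        self.b1 = np.zeros(cfg.n_hidden)
        self.W2 = rng.uniform(-s2, s2, size=(cfg.n_hidden, cfg.n_classes))
        self.b2 = np.zeros(cfg.n_classes)

    def _forward(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        H = _sigmoid(X @ self.W1 + self.b1)
        O = _sigmoid(H @ self.W2 + self.b2)
        return H, O

    def fit(self, X, y) -> "BPNNClassifier":
        X, y = check_Xy(X, y)
        cfg = self.config
        T = one_hot(y, cfg.n_classes)
        self._init_weights(X.shape[1])
        lr = cfg.learning_rate
        n = X.shape[0]
        self.loss_history = []
        for _ in range(cfg.epochs):
            H, O = self._forward(X)
            err = O - T
            loss = float(np.sum(err**2) / n)
            if not np.isfinite(loss):
                raise TrainingError("BPNN diverged: loss is non-finite")
            self.loss_history.append(loss)
            # squared-error objective; sigmoid derivative a(1-a)
            dO = (2.0 / n) * err * O * (1.0 - O)
            dW2 = H.T @ dO
            db2 = dO.sum(axis=0)
            dH = dO @ self.W2.T * H * (1.0 - H)
            dW1 = X.T @ dH
            db1 = dH.sum(axis=0)
            self.W2 -= lr * dW2
            self.b2 -= lr * db2
            self.W1 -= lr * dW1
            self.b1 -= lr * db1
        return self

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        _, O = self._forward(X)
        return np.argmax(O, axis=1)
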