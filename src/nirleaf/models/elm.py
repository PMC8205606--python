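"""Extreme learning machine.

A single-hidden-layer network whose input weights and hidden biases are
drawn once from a seeded uniform(−1, 1) and never trained; the output
weights are the Moore-Penrose least-squares solution mapping the hidden
activations onto one-hot targets.  Training is therefore a single
pseudo-inverse, and with at least as many hidden units as distinct training
rows the network interpolates the training labels exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import ParameterError
from .base import BaseClassifier, check_Xy, one_hot

__all__ = ["ELMConfig", "ELMClassifier"]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class ELMConfig:
    n_hidden: int = 150
    seed: int = 0
    n_classes: int = 5


class ELMClassifier(BaseClassifier):
    def __init__(self, config: ELMConfig | None = None, **kwargs):
        self.config = config or ELMConfig(**kwargs)
        if self.config.n_hidden < 1:
            raise ParameterError(f"n_hidden must be >= 1, got {self.config.n_hidden}")
        self.W_in: np.ndarray | None = None
        self.b_in: np.ndarray | None = None
        self.beta: np.ndarray | None = None

    def _hidden(self, X: np.ndarray) -> np.ndarray:
        return _sigmoid(X @ self.W_in + self.b_in)

    def fit(self, X, y) -> "ELMClassifier":
        X, y = check_Xy(X, y)
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        self.W_in = rng.uniform(-1.0, 1.0, size=(X.shape[1], cfg.n_hidden))
        self.b_in = rng.uniform(-1.0, 1.0, size=cfg.n_hidden)
        H = self._hidden(X)
        self.beta = np.linalg.pinv(H) @ one_hot(y, cfg.n_classes)
        return self

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        scores = self._hidden(X) @ self.beta
        return np.argmax(scores, axis=1)
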