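"""Inverse-distance-weighted k-nearest-neighbor classifier.

Distances are Euclidean or Mahalanobis (training covariance, pseudo-inverse
for safety).  Each of the k nearest training points votes for its class
with weight 1/(d + ε); ε = 1e-12 guards division by zero, so an
exact-match neighbor dominates every other vote.  Ties in the class score
resolve to the lowest class index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from ..errors import ParameterError
from .base import BaseClassifier, check_Xy

__all__ = ["KNNConfig", "KNNClassifier"]

_EPS = 1e-12


@dataclass
class KNNConfig:
    k: int = 5
    metric: str = "euclidean"  # euclidean | mahalanobis
    n_classes: int = 5


class KNNClassifier(BaseClassifier):
    def __init__(self, config: KNNConfig | None = None, **kwargs):
        self.config = config or KNNConfig(**kwargs)
        if self.config.k < 1:
            raise ParameterError(f"k must be >= 1, got {self.config.k}")
        if self.config.metric not in ("euclidean", "mahalanobis"):
            raise ParameterError(f"unknown metric {self.config.metric!r}")
        self._X: np.ndarray | None = None
        self._y: np.ndarray | None = None
        self._VI: np.ndarray | None = None

    def fit(self, X, y) -> "KNNClassifier":
        X, y = check_Xy(X, y)
        if self.config.k > X.shape[0]:
            raise ParameterError(
                f"k={self.config.k} exceeds {X.shape[0]} training samples"
            )
        self._X, self._y = X, y
        if self.config.metric == "mahalanobis":
            cov = np.atleast_2d(np.cov(X, rowvar=False))
            self._VI = np.linalg.pinv(cov)
        return self

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.config.metric == "mahalanobis":
            D = cdist(X, self._X, metric="mahalanobis", VI=self._VI)
        else:
            D = cdist(X, self._X, metric="euclidean")
        k = self.config.k
        # k smallest distances per query; stable ordering not required since
        # the weight depends only on the distance value
        nn = np.argpartition(D, k - 1, axis=1)[:, :k]
        rows = np.arange(X.shape[0])[:, None]
        w = 1.0 / (D[rows, nn] + _EPS)
        labels = self._y[nn]
        scores = np.zeros((X.shape[0], self.config.n_classes))
        for c in range(self.config.n_classes):
            scores[:, c] = np.where(labels == c, w, 0.0).sum(axis=1)
        return np.argmax(scores, axis=1)
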