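from __future__ import annotations

import numpy as np

from ..errors import TrainingError

__all__ = ["BaseClassifier", "one_hot", "check_Xy"]


def one_hot(y, n_classes: int) -> np.ndarray:
    """Integer labels -> one-hot matrix in class-index order."""
    y = np.asarray(y, dtype=int)
    if y.min() < 0 or y.max() >= n_classes:
        raise TrainingError(
            f"labels must lie in [0, {n_classes}), got range [{y.min()}, {y.max()}]"
        )
    out = np.zeros((y.size, n_classes))
    out[np.arange(y.size), y] = 1.0
    return out


def check_Xy(X, y) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2:
        raise TrainingError(f"X must be 2-D, got shape {X.shape}")
    if y.shape != (X.shape[0],):
        raise TrainingError(f"y shape {y.shape} does not match {X.shape[0]} rows")
    return X, y


class BaseClassifier:
    """Common train/predict contract for the five maturity classifiers."""

    def fit(self, X, y) -> "BaseClassifier":
        raise NotImplementedError

    def predict(self, X) -> np.ndarray:
        raise NotImplementedError

    def score_ner(self, X, y) -> float:
        """Discriminant accuracy in percent on (X, y)."""
        y = np.asarray(y, dtype=int)
        return float(np.mean(self.predict(X) == y) * 100.0)
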