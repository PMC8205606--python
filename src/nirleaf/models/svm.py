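"""RBF soft-margin SVM baseline.

One-vs-one multiclass classification with a radial basis kernel.  The
contract here is the decision rule; the quadratic-programming solver is
scikit-learn's SVC.  Penalty and kernel-width values are conventionally
drawn from a powers-of-two grid (see ``evaluate.tune_baselines``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVC

from ..errors import ParameterError, TrainingError
from .base import BaseClassifier, check_Xy

__all__ = ["SVMConfig", "SVMClassifier"]


@dataclass
class SVMConfig:
    C: float = 32.0
    gamma: float = 0.03125  # 2**-5
    n_classes: int = 5


class SVMClassifier(BaseClassifier):
    def __init__(self, config: SVMConfig | None = None, **kwargs):
        self.config = config or SVMConfig(**kwargs)
        if self.config.C <= 0 or self.config.gamma <= 0:
            raise ParameterError(
                f"C and gamma must be positive, got C={self.config.C}, "
                f"gamma={self.config.gamma}"
            )
        self._svc: SVC | None = None

    def fit(self, X, y) -> "SVMClassifier":
        X, y = check_Xy(X, y)
        self._svc = SVC(
            C=self.config.C,
            gamma=self.config.gamma,
            kernel="rbf",
            decision_function_shape="ovo",
        )
        try:
            self._svc.fit(X, y)
        except Exception as exc:
            raise TrainingError(f"SVM solver failed: {exc}") from exc
        return self

    def predict(self, X) -> np.ndarray:
        return np.asarray(self._svc.predict(np.asarray(X, dtype=float)), dtype=int)
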