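"""Gaussian-kernel soft-margin SVM (one-vs-one multi-class).

Thin wrapper over :class:`sklearn.svm.SVC` parameterised by the kernel width
σ of k(x, z) = exp(−‖x−z‖²/(2σ²)) (so gamma = 1/(2σ²)) and cost C.  Features
are z-scored internally.  Serialisation stores the training set and
hyperparameters; the deterministic refit on load reproduces identical
predictions.
"""

from __future__ import annotations

import numpy as np
from sklearn.svm import SVC

from .base import Classifier, StandardScaler

__all__ = ["GKSVMClassifier"]


class GKSVMClassifier(Classifier):
    method = "GK-SVM"

    def __init__(self, sigma: float = 1.0, C: float = 1.0) -> None:
        if sigma <= 0:
            raise ValueError("kernel width sigma must be > 0")
        if C <= 0:
            raise ValueError("cost C must be > 0")
        self.sigma = sigma
        self.C = C
        self.scaler_: StandardScaler | None = None
        self.svc_: SVC | None = None
        self.X_: np.ndarray | None = None
        self.y_: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "GKSVMClassifier":
        X, y = self._check_xy(X, y)
        self.scaler_ = StandardScaler().fit(X)
        Z = self.scaler_.transform(X)
        self.svc_ = SVC(
            C=self.C,
            kernel="rbf",
            gamma=1.0 / (2.0 * self.sigma**2),
            decision_function_shape="ovo",
        ).fit(Z, y)
        self.X_ = X
        self.y_ = y
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.svc_.predict(self.scaler_.transform(np.asarray(X, dtype=float)))

    def to_dict(self) -> dict:
        return {
            "sigma": self.sigma,
            "C": self.C,
            "X": self.X_.tolist(),
            "y": self.y_.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GKSVMClassifier":
        m = cls(sigma=d["sigma"], C=d["C"])
        return m.fit(np.asarray(d["X"], dtype=float), np.asarray(d["y"]))
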