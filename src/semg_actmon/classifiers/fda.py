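"""Fisher discriminant analysis with nearest-class-mean assignment.

The classifier projects onto at most k−1 discriminant directions maximising
between-class over within-class scatter (generalised eigenproblem of S_B
against a ridge-regularised S_W) and assigns a query to the class whose
projected mean is nearest.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import eigh

from .base import Classifier, StandardScaler

__all__ = ["FDAClassifier"]


class FDAClassifier(Classifier):
    method = "FDA"

    def __init__(self, n_components: int | None = None) -> None:
        self.n_components = n_components
        self.scaler_: StandardScaler | None = None
        self.W_: np.ndarray | None = None  # (d, n_components)
        self.classes_: np.ndarray | None = None
        self.proj_means_: np.ndarray | None = None  # (k, n_components)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "FDAClassifier":
        X, y = self._check_xy(X, y)
        self.scaler_ = StandardScaler().fit(X)
        Z = self.scaler_.transform(X)
        classes = np.unique(y)
        d = Z.shape[1]
        means = np.stack([Z[y == c].mean(axis=0) for c in classes])
        grand = means.mean(axis=0)
        S_B = sum(np.outer(m - grand, m - grand) for m in means)
        S_W = np.zeros((d, d))
        for c in classes:
            dev = Z[y == c] - Z[y == c].mean(axis=0)
            S_W += dev.T @ dev
        S_W /= Z.shape[0]
        # ridge keeps the within-class scatter full rank
        S_W += np.eye(d) * (1e-6 * max(np.trace(S_W), 1e-12) / d)

        k = classes.size
        n_comp = self.n_components or min(k - 1, d)
        evals, evecs = eigh(S_B, S_W)
        order = np.argsort(evals)[::-1][:n_comp]
        self.W_ = evecs[:, order]
        self.classes_ = classes
        self.proj_means_ = means @ self.W_
        return self

    def _project(self, X: np.ndarray) -> np.ndarray:
        return self.scaler_.transform(X) @ self.W_

    def predict(self, X: np.ndarray) -> np.ndarray:
        P = self._project(np.asarray(X, dtype=float))
        d2 = ((P[:, None, :] - self.proj_means_[None, :, :]) ** 2).sum(axis=2)
        return self.classes_[np.argmin(d2, axis=1)]

    def to_dict(self) -> dict:
        return {
            "n_components": self.n_components,
            "scaler": self.scaler_.to_dict(),
            "W": self.W_.tolist(),
            "classes": self.classes_.tolist(),
            "proj_means": self.proj_means_.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FDAClassifier":
        m = cls(n_components=d["n_components"])
        m.scaler_ = StandardScaler.from_dict(d["scaler"])
        m.W_ = np.asarray(d["W"], dtype=float)
        m.classes_ = np.asarray(d["classes"])
        m.proj_means_ = np.asarray(d["proj_means"], dtype=float)
        return m
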