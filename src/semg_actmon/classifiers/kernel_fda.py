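"""Kernel Fisher discriminant analysis with a Gaussian kernel.

Identical discriminant criterion to linear FDA but evaluated in the
reproducing-kernel Hilbert space of k(x, z) = exp(−‖x−z‖² / (2σ²)): the
projection directions are expansions α over the training points, found from
the kernelised between/within scatter (generalised eigenproblem with a ridge
on the within matrix), and queries are assigned to the nearest projected class
mean.  For very large σ the kernel linearises and the classifier approaches
linear FDA.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import eigh
from scipy.spatial.distance import cdist

from .base import Classifier, StandardScaler

__all__ = ["KernelFDAClassifier", "rbf_kernel"]


def rbf_kernel(A: np.ndarray, B: np.ndarray, sigma: float) -> np.ndarray:
    d2 = cdist(A, B, "sqeuclidean")
    return np.exp(-d2 / (2.0 * sigma**2))


class KernelFDAClassifier(Classifier):
    method = "GK-FDA"

    def __init__(self, sigma: float = 1.0, ridge: float = 1e-6) -> None:
        if sigma <= 0:
            raise ValueError("kernel width sigma must be > 0")
        self.sigma = sigma
        self.ridge = ridge
        self.scaler_: StandardScaler | None = None
        self.X_: np.ndarray | None = None
        self.alphas_: np.ndarray | None = None  # (n, n_components)
        self.classes_: np.ndarray | None = None
        self.proj_means_: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "KernelFDAClassifier":
        X, y = self._check_xy(X, y)
        self.scaler_ = StandardScaler().fit(X)
        Z = self.scaler_.transform(X)
        n = Z.shape[0]
        classes = np.unique(y)
        K = rbf_kernel(Z, Z, self.sigma)

        mu = K.mean(axis=1)
        M = np.zeros((n, n))
        N = np.zeros((n, n))
        for c in classes:
            idx = np.flatnonzero(y == c)
            nc = idx.size
            mu_c = K[:, idx].mean(axis=1)
            dm = mu_c - mu
            M += nc * np.outer(dm, dm)
            Kc = K[:, idx]
            H = np.eye(nc) - np.full((nc, nc), 1.0 / nc)
            N += Kc @ H @ Kc.T
        N += np.eye(n) * (self.ridge * max(np.trace(N), 1.0) / n)

        n_comp = min(classes.size - 1, n - 1)
        evals, evecs = eigh(M, N)
        order = np.argsort(evals)[::-1][:n_comp]
        self.alphas_ = evecs[:, order]
        self.X_ = Z
        self.classes_ = classes
        proj = K @ self.alphas_  # training projections
        self.proj_means_ = np.stack([proj[y == c].mean(axis=0) for c in classes])
        return self

    def _project(self, X: np.ndarray) -> np.ndarray:
        K = rbf_kernel(self.scaler_.transform(X), self.X_, self.sigma)
        return K @ self.alphas_

    def predict(self, X: np.ndarray) -> np.ndarray:
        P = self._project(np.asarray(X, dtype=float))
        d2 = ((P[:, None, :] - self.proj_means_[None, :, :]) ** 2).sum(axis=2)
        return self.classes_[np.argmin(d2, axis=1)]

    def to_dict(self) -> dict:
        return {
            "sigma": self.sigma,
            "ridge": self.ridge,
            "scaler": self.scaler_.to_dict(),
            "X": self.X_.tolist(),
            "alphas": self.alphas_.tolist(),
            "classes": self.classes_.tolist(),
            "proj_means": self.proj_means_.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KernelFDAClassifier":
        m = cls(sigma=d["sigma"], ridge=d["ridge"])
        m.scaler_ = StandardScaler.from_dict(d["scaler"])
        m.X_ = np.asarray(d["X"], dtype=float)
        m.alphas_ = np.asarray(d["alphas"], dtype=float)
        m.classes_ = np.asarray(d["classes"])
        m.proj_means_ = np.asarray(d["proj_means"], dtype=float)
        return m
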