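"""Fuzzy c-means used as a classifier.

Training runs unsupervised FCM (alternating optimisation of the fuzzy
objective Σ_ik u_ik^m ‖x_k − v_i‖², memberships summing to 1 per sample) on
the z-scored training features with c = number of classes, then maps each
cluster to the majority training label among its hard-assigned members; an
empty cluster inherits the mapped label of the nearest non-empty centroid.
Prediction assigns the mapped label of the maximum-membership cluster.
Initialisation is seeded; several restarts are run and the lowest final
objective kept, since the objective is non-convex.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist

from .base import Classifier, StandardScaler

__all__ = ["FCMClassifier", "fcm_cluster"]


def _memberships(X: np.ndarray, centers: np.ndarray, m: float) -> np.ndarray:
    d2 = cdist(X, centers, "sqeuclidean")
    d2 = np.maximum(d2, 1e-300)
    inv = d2 ** (-1.0 / (m - 1.0))
    return inv / inv.sum(axis=1, keepdims=True)


def fcm_cluster(
    X: np.ndarray,
    c: int,
    m: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 300,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """One FCM run: returns (centers, memberships U, objective trajectory)."""
    if m <= 1:
        raise ValueError("fuzzifier must be > 1")
    rng = rng or np.random.default_rng()
    n = X.shape[0]
    # initialise centers at distinct random data points
    centers = X[rng.choice(n, size=c, replace=False)].copy()
    obj_trace: list[float] = []
    for _ in range(max_iter):
        U = _memberships(X, centers, m)
        Um = U**m
        centers = (Um.T @ X) / Um.sum(axis=0)[:, None]
        d2 = cdist(X, centers, "sqeuclidean")
        obj = float(np.sum(Um * d2))
        if obj_trace and abs(obj_trace[-1] - obj) <= tol:
            obj_trace.append(obj)
            break
        obj_trace.append(obj)
    U = _memberships(X, centers, m)
    return centers, U, obj_trace


class FCMClassifier(Classifier):
    method = "FCM"

    def __init__(
        self,
        n_clusters: int | None = None,
        fuzzifier: float = 2.0,
        tol: float = 1e-6,
        max_iter: int = 300,
        n_init: int = 5,
        seed: int = 0,
    ) -> None:
        if fuzzifier <= 1:
            raise ValueError("fuzzifier must be > 1")
        self.n_clusters = n_clusters
        self.fuzzifier = fuzzifier
        self.tol = tol
        self.max_iter = max_iter
        self.n_init = n_init
        self.seed = seed
        self.scaler_: StandardScaler | None = None
        self.centers_: np.ndarray | None = None
        self.cluster_label_: np.ndarray | None = None
        self.classes_: np.ndarray | None = None
        self.objective_trace_: list[float] | None = None
        self.memberships_: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "FCMClassifier":
        X, y = self._check_xy(X, y)
        self.classes_ = np.unique(y)
        c = self.n_clusters or self.classes_.size
        self.scaler_ = StandardScaler().fit(X)
        Z = self.scaler_.transform(X)

        best = None
        ss = np.random.SeedSequence(self.seed)
        for child in ss.spawn(self.n_init):
            centers, U, trace = fcm_cluster(
                Z, c, self.fuzzifier, self.tol, self.max_iter, np.random.default_rng(child)
            )
            if best is None or trace[-1] < best[2][-1]:
                best = (centers, U, trace)
        centers, U, trace = best
        self.centers_ = centers
        self.memberships_ = U
        self.objective_trace_ = trace

        # map clusters to the majority training label of hard-assigned members
        hard = np.argmax(U, axis=1)
        labels = np.empty(c, dtype=object)
        empty = []
        for i in range(c):
            members = y[hard == i]
            if members.size == 0:
                empty.append(i)
                continue
            vals, counts = np.unique(members, return_counts=True)
            labels[i] = vals[np.argmax(counts)]
        for i in empty:  # inherit from the nearest non-empty centroid
            filled = [j for j in range(c) if j not in empty]
            d2 = ((self.centers_[filled] - self.centers_[i]) ** 2).sum(axis=1)
            labels[i] = labels[filled[int(np.argmin(d2))]]
        self.cluster_label_ = np.asarray([str(v) for v in labels]) if y.dtype.kind in "US" \
            else np.asarray(list(labels))
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        Z = self.scaler_.transform(np.asarray(X, dtype=float))
        U = _memberships(Z, self.centers_, self.fuzzifier)
        return self.cluster_label_[np.argmax(U, axis=1)]

    def to_dict(self) -> dict:
        return {
            "n_clusters": self.n_clusters,
            "fuzzifier": self.fuzzifier,
            "tol": self.tol,
            "max_iter": self.max_iter,
            "n_init": self.n_init,
            "seed": self.seed,
            "scaler": self.scaler_.to_dict(),
            "centers": self.centers_.tolist(),
            "cluster_label": self.cluster_label_.tolist(),
            "classes": self.classes_.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FCMClassifier":
        m = cls(
            n_clusters=d["n_clusters"],
            fuzzifier=d["fuzzifier"],
            tol=d["tol"],
            max_iter=d["max_iter"],
            n_init=d["n_init"],
            seed=d["seed"],
        )
        m.scaler_ = StandardScaler.from_dict(d["scaler"])
        m.centers_ = np.asarray(d["centers"], dtype=float)
        m.cluster_label_ = np.asarray(d["cluster_label"])
        m.classes_ = np.asarray(d["classes"])
        return m
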