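"""Fuzzy min–max neural network classifier.

A labelled pattern set is covered online by axis-aligned hyperboxes, each
defined by its min and max points and carrying a class label.  Training is a
single pass: each pattern either expands the highest-membership expandable
hyperbox of its own class (every box edge is capped at θ) or seeds a new
point-box, and any resulting overlap with a hyperbox of another class is
removed by contracting both boxes along the dimension of minimum overlap.
Membership decays linearly outside a box at sensitivity γ; prediction takes
the class of the maximum-membership hyperbox with ties resolved toward the
smallest class index.  Features are min–max scaled to the unit cube
internally.  The learned geometry depends on presentation order — an inherent
property of the single-pass scheme.
"""

from __future__ import annotations

import numpy as np

from .base import Classifier, MinMaxScaler

__all__ = ["FMMNNClassifier"]


class FMMNNClassifier(Classifier):
    method = "FMMNN"

    def __init__(self, theta: float = 0.3, gamma: float = 4.0) -> None:
        if not 0 < theta <= 1:
            raise ValueError("expansion parameter theta must be in (0, 1]")
        if gamma <= 0:
            raise ValueError("sensitivity gamma must be > 0")
        self.theta = theta
        self.gamma = gamma
        self.scaler_: MinMaxScaler | None = None
        self.V_: np.ndarray | None = None  # (n_boxes, d) min points
        self.W_: np.ndarray | None = None  # (n_boxes, d) max points
        self.box_class_: np.ndarray | None = None
        self.classes_: np.ndarray | None = None

    # membership --------------------------------------------------------------
    def _membership(self, X: np.ndarray) -> np.ndarray:
        """Membership of each pattern in each hyperbox, shape (n, n_boxes)."""
        V, W, g = self.V_, self.W_, self.gamma
        x = X[:, None, :]  # (n, 1, d)
        above = np.maximum(0.0, 1.0 - np.maximum(0.0, g * np.minimum(1.0, x - W[None])))
        below = np.maximum(0.0, 1.0 - np.maximum(0.0, g * np.minimum(1.0, V[None] - x)))
        return (above + below).mean(axis=2) / 2.0

    # training ----------------------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray) -> "FMMNNClassifier":
        X, y = self._check_xy(X, y)
        self.scaler_ = MinMaxScaler().fit(X)
        Z = self.scaler_.transform(X)
        self.classes_ = np.unique(y)

        V: list[np.ndarray] = []
        W: list[np.ndarray] = []
        labels: list = []
        for x, c in zip(Z, y):
            j = self._expandable_box(x, c, V, W, labels)
            if j is None:
                V.append(x.copy())
                W.append(x.copy())
                labels.append(c)
                j = len(V) - 1
            else:
                V[j] = np.minimum(V[j], x)
                W[j] = np.maximum(W[j], x)
            self._resolve_overlaps(j, V, W, labels)

        self.V_ = np.asarray(V)
        self.W_ = np.asarray(W)
        self.box_class_ = np.asarray(labels)
        return self

    def _expandable_box(self, x, c, V, W, labels):
        """Highest-membership same-class box whose expansion keeps edges ≤ θ."""
        if not V:
            return None
        self.V_, self.W_ = np.asarray(V), np.asarray(W)
        memb = self._membership(x[None])[0]
        order = np.argsort(-memb, kind="stable")
        for j in order:
            if labels[j] != c:
                continue
            new_v = np.minimum(V[j], x)
            new_w = np.maximum(W[j], x)
            if np.all(new_w - new_v <= self.theta):
                return int(j)
        return None

    def _resolve_overlaps(self, j, V, W, labels) -> None:
        """Contract box j against every overlapping other-class box.

        A pair overlaps only if the open intervals intersect in every
        dimension; contraction removes the minimum-overlap dimension.  The
        scan repeats until no other-class overlap remains (contraction against
        one box cannot enlarge any interval, so this terminates quickly).
        """
        for _ in range(len(V)):
            dirty = False
            for k in range(len(V)):
                if labels[k] == labels[j]:
                    continue
                if self._contract_pair(V, W, j, k):
                    dirty = True
            if not dirty:
                return

    @staticmethod
    def _contract_pair(V, W, j, k) -> bool:
        """Simpson's four-case overlap test/contraction; True if contracted."""
        vj, wj, vk, wk = V[j], W[j], V[k], W[k]
        d = vj.size
        min_ov = np.inf
        dim = -1
        case = 0
        for i in range(d):
            if vj[i] < vk[i] < wj[i] < wk[i]:
                ov, ci = wj[i] - vk[i], 1
            elif vk[i] < vj[i] < wk[i] < wj[i]:
                ov, ci = wk[i] - vj[i], 2
            elif vj[i] <= vk[i] and wk[i] <= wj[i]:
                ov, ci = min(wj[i] - vk[i], wk[i] - vj[i]), 3
            elif vk[i] <= vj[i] and wj[i] <= wk[i]:
                ov, ci = min(wj[i] - vk[i], wk[i] - vj[i]), 4
            else:
                return False  # disjoint in dimension i
            if ov <= 0:
                return False  # touching is not overlapping
            if ov < min_ov:
                min_ov, dim, case = ov, i, ci
        i = dim
        if case == 1:
            wj[i] = vk[i] = (wj[i] + vk[i]) / 2.0
        elif case == 2:
            vj[i] = wk[i] = (vj[i] + wk[i]) / 2.0
        elif case == 3:
            if wk[i] - vj[i] < wj[i] - vk[i]:
                vj[i] = wk[i]
            else:
                wj[i] = vk[i]
        else:
            if wk[i] - vj[i] < wj[i] - vk[i]:
                wk[i] = vj[i]
            else:
                vk[i] = wj[i]
        return True

    # prediction --------------------------------------------------------------
    def predict(self, X: np.ndarray) -> np.ndarray:
        Z = self.scaler_.transform(np.asarray(X, dtype=float))
        memb = self._membership(Z)
        # per-class max membership; ties between classes -> smallest class index
        out = np.empty(Z.shape[0], dtype=self.box_class_.dtype)
        class_memb = np.stack(
            [memb[:, self.box_class_ == c].max(axis=1) for c in self.classes_], axis=1
        )
        out = self.classes_[np.argmax(class_memb, axis=1)]
        return out

    def to_dict(self) -> dict:
        return {
            "theta": self.theta,
            "gamma": self.gamma,
            "scaler": self.scaler_.to_dict(),
            "V": self.V_.tolist(),
            "W": self.W_.tolist(),
            "box_class": self.box_class_.tolist(),
            "classes": self.classes_.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FMMNNClassifier":
        m = cls(theta=d["theta"], gamma=d["gamma"])
        m.scaler_ = MinMaxScaler.from_dict(d["scaler"])
        m.V_ = np.asarray(d["V"], dtype=float)
        m.W_ = np.asarray(d["W"], dtype=float)
        m.box_class_ = np.asarray(d["box_class"])
        m.classes_ = np.asarray(d["classes"])
        return m
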