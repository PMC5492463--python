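"""Shared train/predict contract, feature scaling, and JSON round-trip."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

__all__ = ["Classifier", "StandardScaler", "MinMaxScaler", "save_model", "load_model"]


class Classifier:
    """Abstract train/predict contract.

    Subclasses implement ``fit(X, y) -> self`` and ``predict(X) -> labels``,
    plus ``to_dict``/``from_dict`` for a lossless JSON round-trip (reloaded
    models must predict identically).
    """

    method: str = "?"

    def fit(self, X: np.ndarray, y: np.ndarray) -> "Classifier":
        raise NotImplementedError

    def predict(self, X: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def to_dict(self) -> dict:
        raise NotImplementedError

    @classmethod
    def from_dict(cls, d: dict) -> "Classifier":
        raise NotImplementedError

    # common input validation -------------------------------------------------
    @staticmethod
    def _check_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_samples, n_features)")
        if len(y) != X.shape[0]:
            raise ValueError("X and y length mismatch")
        if np.unique(y).size < 2:
            raise ValueError("need at least 2 classes")
        if not np.isfinite(X).all():
            raise ValueError("X must be finite")
        return X, y


class StandardScaler:
    """Per-dimension z-scoring with parameters learned on the training folds."""

    def __init__(self) -> None:
        self.mean_: np.ndarray | None = None
        self.std_: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "StandardScaler":
        self.mean_ = X.mean(axis=0)
        std = X.std(axis=0)
        self.std_ = np.where(std > 0, std, 1.0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean_) / self.std_

    def to_dict(self) -> dict:
        return {"mean": self.mean_.tolist(), "std": self.std_.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "StandardScaler":
        s = cls()
        s.mean_ = np.asarray(d["mean"], dtype=float)
        s.std_ = np.asarray(d["std"], dtype=float)
        return s


class MinMaxScaler:
    """Min–max scaling to [0, 1]; test inputs are clipped into the unit box."""

    def __init__(self) -> None:
        self.min_: np.ndarray | None = None
        self.range_: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "MinMaxScaler":
        self.min_ = X.min(axis=0)
        rng = X.max(axis=0) - self.min_
        self.range_ = np.where(rng > 0, rng, 1.0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        z = (np.asarray(X, dtype=float) - self.min_) / self.range_
        return np.clip(z, 0.0, 1.0)

    def to_dict(self) -> dict:
        return {"min": self.min_.tolist(), "range": self.range_.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "MinMaxScaler":
        s = cls()
        s.min_ = np.asarray(d["min"], dtype=float)
        s.range_ = np.asarray(d["range"], dtype=float)
        return s


def save_model(model: Classifier, path: str | Path) -> None:
    payload = {"method": model.method, "state": model.to_dict()}
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> Classifier:
    from . import make_classifier_class

    payload = json.loads(Path(path).read_text())
    cls = make_classifier_class(payload["method"])
    return cls.from_dict(payload["state"])
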