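"""Inner-cross-validation hyperparameter search.

Kernel classifiers sweep the kernel width σ over 0.5–5.0 in steps of 0.1;
the fuzzy min–max network sweeps its expansion parameter θ exhaustively over
0.05–0.5 in steps of 0.05.  Selection maximises mean stratified inner-CV
accuracy on the training data only; ties go to the earliest (smallest) grid
point.
"""

from __future__ import annotations

import numpy as np
from sklearn.model_selection import StratifiedKFold

__all__ = ["default_grid", "hyperparam_search"]


def default_grid(method: str) -> list[dict]:
    if method in ("GK-FDA", "GK-SVM"):
        return [{"sigma": round(s, 10)} for s in np.arange(0.5, 5.0001, 0.1)]
    if method == "FMMNN":
        return [{"theta": round(t, 10)} for t in np.arange(0.05, 0.5001, 0.05)]
    return [{}]  # FDA, FCM: no searched hyperparameters


def hyperparam_search(
    factory,
    X: np.ndarray,
    y: np.ndarray,
    grid: list[dict],
    inner_folds: int = 3,
    seed: int = 0,
) -> tuple[dict, float]:
    """Pick the grid point maximising mean inner-CV accuracy.

    ``factory(**params)`` must return an unfitted classifier.  Returns the
    winning parameter dict and its inner-CV accuracy.  A single-point grid is
    returned as-is (no CV run); degenerate data raise from the classifier.
    """
    if not grid:
        raise ValueError("empty hyperparameter grid")
    if len(grid) == 1:
        return grid[0], float("nan")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    n_folds = int(min(inner_folds, counts.min()))
    if n_folds < 2:
        # not enough per-class samples for an inner split: fall back to
        # training-set accuracy as the selection score
        scores = []
        for params in grid:
            model = factory(**params).fit(X, y)
            scores.append(float(np.mean(model.predict(X) == y)))
    else:
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        splits = list(skf.split(X, y))
        scores = []
        for params in grid:
            accs = []
            for tr, te in splits:
                model = factory(**params).fit(X[tr], y[tr])
                accs.append(float(np.mean(model.predict(X[te]) == y[te])))
            scores.append(float(np.mean(accs)))
    best = int(np.argmax(scores))  # argmax keeps the first (smallest) on ties
    return grid[best], scores[best]
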