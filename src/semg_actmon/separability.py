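"""Fisher class-separability scoring and the separability/time trade-off index.

A feature type is scored by J = trace(S_B) / trace(S_W), the ratio of
between-class to within-class scatter of its feature vectors: higher J means
the activity classes are further apart relative to their spread, i.e. the
feature space is easier to classify in.  A weighted performance index then
trades separability against extraction cost, with both the best separability
and the fastest extraction normalised to 100.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

__all__ = [
    "ScatterSummary",
    "scatter",
    "separability_index",
    "tradeoff_index",
    "rank_agreement",
]


@dataclass
class ScatterSummary:
    """Between/within scatter matrices, class means and the J index."""

    S_B: np.ndarray
    S_W: np.ndarray
    class_means: dict
    grand_mean: np.ndarray
    J: float


def scatter(features: np.ndarray, labels: np.ndarray) -> ScatterSummary:
    """Between- and within-class scatter of a feature matrix.

    S_B sums the outer products of (class mean − grand mean) over classes,
    where the grand mean is the unweighted mean of the class means.  S_W sums
    the within-class covariances E[(x−m_i)(x−m_i)ᵀ] over classes, each with
    population (1/n_i) normalisation; summing (rather than averaging) over
    classes makes the two-class 1-D index equal μ²/σ² for class means ±μ and
    within-class variance σ².  The choice only rescales J by the class count,
    leaving every between-feature comparison unchanged.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    means = {}
    covs = []
    for c in classes:
        Xc = X[y == c]
        if Xc.shape[0] < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
        means[c] = Xc.mean(axis=0)
        d = Xc - means[c]
        covs.append(d.T @ d / Xc.shape[0])
    grand = np.mean(list(means.values()), axis=0)
    S_B = sum(np.outer(means[c] - grand, means[c] - grand) for c in classes)
    S_W = sum(covs)
    summary = ScatterSummary(S_B=S_B, S_W=S_W, class_means=means, grand_mean=grand, J=np.nan)
    summary.J = separability_index(summary)
    return summary


def separability_index(s: ScatterSummary) -> float:
    """J = trace(S_B) / trace(S_W)."""
    tw = float(np.trace(s.S_W))
    if tw <= 0:
        raise ValueError("trace(S_W) must be positive (degenerate within-class spread)")
    return float(np.trace(s.S_B)) / tw


def tradeoff_index(
    J_per_feature: dict[str, float],
    time_per_feature: dict[str, float],
    w_values: np.ndarray | None = None,
) -> pd.DataFrame:
    """Weighted separability/time performance index.

    a = 100·J/max(J) is the normalised separability and t = 100·min(time)/time
    the inverse-normalised calculation time, so the most separable feature and
    the fastest feature each score 100.  The combined index is
    (1−w)·a + w·t for each weight w; by default w sweeps 0 to 0.5 in steps of
    0.05 (separability always keeps the larger share).
    """
    if not J_per_feature:
        raise ValueError("empty input")
    if set(J_per_feature) != set(time_per_feature):
        raise ValueError("feature sets of J and time differ")
    if w_values is None:
        w_values = np.round(np.arange(0.0, 0.5001, 0.05), 10)
    w_values = np.asarray(w_values, dtype=float)
    if ((w_values < 0) | (w_values > 0.5)).any():
        raise ValueError("w must lie in [0, 0.5]")
    times = np.array([time_per_feature[f] for f in J_per_feature])
    if (times <= 0).any():
        raise ValueError("all times must be positive")
    Js = np.array([J_per_feature[f] for f in J_per_feature])
    a = 100.0 * Js / Js.max()
    t = 100.0 * times.min() / times
    rows = []
    for i, f in enumerate(J_per_feature):
        for w in w_values:
            rows.append(
                {
                    "feature_id": f,
                    "J": Js[i],
                    "time": times[i],
                    "a": a[i],
                    "t": t[i],
                    "w": w,
                    "index": (1.0 - w) * a[i] + w * t[i],
                }
            )
    return pd.DataFrame(rows)


def rank_agreement(J_by_subject: dict, feature_ids: list[str] | None = None) -> pd.DataFrame:
    """Pairwise Spearman rank correlation of per-subject J rankings.

    ``J_by_subject`` maps subject → {feature_id → J}.  Returns one row per
    subject pair plus an ``average`` row; identical rankings give 1.0, exactly
    reversed rankings −1.0.
    """
    subjects = sorted(J_by_subject)
    if len(subjects) < 2:
        raise ValueError("need at least 2 subjects")
    if feature_ids is None:
        feature_ids = sorted(J_by_subject[subjects[0]])
    if len(feature_ids) < 3:
        raise ValueError("need at least 3 features for a meaningful rank correlation")
    rows = []
    vals = []
    for i, s1 in enumerate(subjects):
        for s2 in subjects[i + 1:]:
            r1 = [J_by_subject[s1][f] for f in feature_ids]
            r2 = [J_by_subject[s2][f] for f in feature_ids]
            rho = float(spearmanr(r1, r2).statistic)
            rows.append({"subject_a": s1, "subject_b": s2, "spearman": rho})
            vals.append(rho)
    rows.append({"subject_a": "average", "subject_b": "", "spearman": float(np.mean(vals))})
    return pd.DataFrame(rows)
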