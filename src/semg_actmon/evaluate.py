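"""Five-fold cross-validated benchmarking of feature × classifier pairs.

Two experiments are provided: 8-class activity recognition and binary fall
detection (the seven activities of daily living against the trip-fall).  Each
(feature type, classifier) cell is scored by stratified five-fold CV with
hyperparameters chosen by a nested search on the training folds only, and
reported as mean ± std accuracy, the pooled confusion matrix, and — for fall
detection — sensitivity (falls identified correctly) and specificity (ADLs
identified correctly).  By default each subject is evaluated separately and
cell metrics are averaged across subjects, matching a per-individual training
protocol; pooled evaluation is available with ``per_subject=False``.

Wall-clock extraction and recognition times are measured and reported for
context; they depend on the host and are never part of any assertion.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold

from .classifiers import default_grid, hyperparam_search, make_classifier
from .features import FeatureSpec, extract, feature_registry
from .synth import LabeledDataset

__all__ = ["CVPlan", "EvalResult", "make_folds", "run_recognition", "run_fall_detection",
           "timing_report", "results_to_frame", "FALL_LABEL", "ADL_LABEL"]

ADL_LABEL = "ADL"
FALL_LABEL = "fall"


@dataclass
class CVPlan:
    """Stratified five-fold assignment: fold index per epoch."""

    n_folds: int
    assignment: np.ndarray
    stratified: bool
    seed: int

    def split(self):
        for f in range(self.n_folds):
            te = self.assignment == f
            yield np.flatnonzero(~te), np.flatnonzero(te)


def make_folds(labels: np.ndarray, seed: int = 0, n_folds: int = 5) -> CVPlan:
    """Deterministic stratified fold assignment.

    Per-class fold sizes differ by at most one; every epoch lands in exactly
    one test fold.  Classes with fewer than ``n_folds`` samples are rejected.
    """
    y = np.asarray(labels)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < n_folds:
        raise ValueError(f"every class needs >= {n_folds} samples, min is {counts.min()}")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    assignment = np.empty(len(y), dtype=int)
    for f, (_, te) in enumerate(skf.split(np.zeros(len(y)), y)):
        assignment[te] = f
    return CVPlan(n_folds=n_folds, assignment=assignment, stratified=True, seed=seed)


@dataclass
class EvalResult:
    """One (feature type, classifier) cell of the benchmark."""

    feature_id: str
    method: str
    fold_accuracies: list[float]
    acc_mean: float
    acc_std: float
    confusion: np.ndarray
    class_order: list
    sensitivity: float | None = None
    specificity: float | None = None
    extract_ms_per_epoch: float = 0.0
    predict_ms_per_epoch: float = 0.0
    best_hyperparams: list = field(default_factory=list)


def _evaluate_cell(
    X: np.ndarray,
    y: np.ndarray,
    method: str,
    seed: int,
    grids: dict[str, list[dict]] | None = None,
    inner_folds: int = 3,
) -> tuple[list[float], np.ndarray, np.ndarray, float, list]:
    """Outer 5-fold CV with nested hyperparameter selection for one cell."""
    plan = make_folds(y, seed=seed)
    grid = (grids or {}).get(method, default_grid(method))
    classes = np.unique(y)
    conf = np.zeros((classes.size, classes.size), dtype=int)
    accs: list[float] = []
    chosen: list = []
    predict_time = 0.0
    n_pred = 0

    def factory(**params):
        if method == "FCM":
            return make_classifier(method, seed=seed, **params)
        return make_classifier(method, **params)

    for tr, te in plan.split():
        best, _ = hyperparam_search(factory, X[tr], y[tr], grid,
                                    inner_folds=inner_folds, seed=seed)
        model = factory(**best).fit(X[tr], y[tr])
        t0 = time.perf_counter()
        pred = model.predict(X[te])
        predict_time += time.perf_counter() - t0
        n_pred += len(te)
        accs.append(float(np.mean(pred == y[te])))
        conf += confusion_matrix(y[te], pred, labels=classes)
        chosen.append(best)
    return accs, conf, classes, 1000.0 * predict_time / max(n_pred, 1), chosen


def _sen_spe(conf: np.ndarray, classes: np.ndarray) -> tuple[float, float]:
    """Sensitivity = TP/(TP+FN) over fall epochs; specificity = TN/(TN+FP)."""
    fall_idx = int(np.flatnonzero(classes == FALL_LABEL)[0])
    adl_idx = 1 - fall_idx
    tp = conf[fall_idx, fall_idx]
    fn = conf[fall_idx, adl_idx]
    tn = conf[adl_idx, adl_idx]
    fp = conf[adl_idx, fall_idx]
    sen = 100.0 * tp / (tp + fn) if tp + fn else float("nan")
    spe = 100.0 * tn / (tn + fp) if tn + fp else float("nan")
    return sen, spe


def run_recognition(
    dataset: LabeledDataset,
    feature_ids: list[str],
    methods: list[str],
    seed: int = 0,
    per_subject: bool = True,
    grids: dict[str, list[dict]] | None = None,
    registry: dict[str, FeatureSpec] | None = None,
) -> list[EvalResult]:
    """8-class activity recognition benchmark."""
    return _run_table(dataset, feature_ids, methods, seed, binary=False,
                      per_subject=per_subject, grids=grids, registry=registry)


def run_fall_detection(
    dataset: LabeledDataset,
    feature_ids: list[str],
    methods: list[str],
    seed: int = 0,
    per_subject: bool = True,
    grids: dict[str, list[dict]] | None = None,
    registry: dict[str, FeatureSpec] | None = None,
) -> list[EvalResult]:
    """Binary fall detection: the seven ADLs vs the trip-fall."""
    if not dataset.fall_flag.any():
        raise ValueError("dataset contains no fall epochs")
    return _run_table(dataset, feature_ids, methods, seed, binary=True,
                      per_subject=per_subject, grids=grids, registry=registry)


def _run_table(dataset, feature_ids, methods, seed, binary, per_subject, grids, registry):
    registry = registry or feature_registry(dataset.epochs[0].fs)
    subjects = list(np.unique(dataset.subject_ids)) if per_subject else [None]

    # extract features once per (subject, feature type)
    cache: dict[tuple, tuple[np.ndarray, np.ndarray, float, int]] = {}
    for fid in feature_ids:
        if fid not in registry:
            raise KeyError(f"unregistered feature {fid!r}; valid: {sorted(registry)}")
        for subj in subjects:
            sub = dataset if subj is None else dataset.subset(dataset.subject_ids == subj)
            fm = extract(sub, registry[fid])
            y = np.where(sub.fall_flag, FALL_LABEL, ADL_LABEL) if binary else np.asarray(sub.labels)
            cache[(fid, subj)] = (fm.values, y, 1000.0 * fm.extraction_time_s / len(sub), len(sub))

    results: list[EvalResult] = []
    for fid in feature_ids:
        for method in methods:
            accs_all: list[float] = []
            conf_total = None
            classes_ref = None
            pred_ms_all, ext_ms_all, hp_all = [], [], []
            for subj in subjects:
                X, y, ext_ms, _ = cache[(fid, subj)]
                accs, conf, classes, pred_ms, chosen = _evaluate_cell(
                    X, y, method, seed, grids
                )
                accs_all.extend(accs)
                conf_total = conf if conf_total is None else conf_total + conf
                classes_ref = classes
                pred_ms_all.append(pred_ms)
                ext_ms_all.append(ext_ms)
                hp_all.extend(chosen)
            sen = spe = None
            if binary:
                sen, spe = _sen_spe(conf_total, classes_ref)
            results.append(
                EvalResult(
                    feature_id=fid,
                    method=method,
                    fold_accuracies=accs_all,
                    acc_mean=100.0 * float(np.mean(accs_all)),
                    acc_std=100.0 * float(np.std(accs_all)),
                    confusion=conf_total,
                    class_order=list(classes_ref),
                    sensitivity=sen,
                    specificity=spe,
                    extract_ms_per_epoch=float(np.mean(ext_ms_all)),
                    predict_ms_per_epoch=float(np.mean(pred_ms_all)),
                    best_hyperparams=hp_all,
                )
            )
    return results


def timing_report(results: list[EvalResult]) -> pd.DataFrame:
    """Measured per-epoch wall-clock times (informational only)."""
    return pd.DataFrame(
        [
            {
                "feature_id": r.feature_id,
                "method": r.method,
                "extract_ms_per_epoch": r.extract_ms_per_epoch,
                "predict_ms_per_epoch": r.predict_ms_per_epoch,
                "total_ms_per_epoch": r.extract_ms_per_epoch + r.predict_ms_per_epoch,
            }
            for r in results
        ]
    )


def results_to_frame(results: list[EvalResult]) -> pd.DataFrame:
    """Tidy table of the benchmark (one row per feature × classifier cell)."""
    rows = []
    for r in results:
        rows.append(
            {
                "feature_id": r.feature_id,
                "method": r.method,
                "acc_mean": r.acc_mean,
                "acc_std": r.acc_std,
                "sensitivity": r.sensitivity,
                "specificity": r.specificity,
                "extract_ms_per_epoch": r.extract_ms_per_epoch,
                "predict_ms_per_epoch": r.predict_ms_per_epoch,
            }
        )
    return pd.DataFrame(rows)
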