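"""Five classifiers behind one train/predict contract.

FDA — linear Fisher discriminant, nearest class mean in discriminant space.
FMMNN — fuzzy min–max neural network over hyperbox fuzzy sets.
GK-FDA — kernel Fisher discriminant with a Gaussian kernel.
GK-SVM — Gaussian-kernel soft-margin SVM (one-vs-one).
FCM — fuzzy c-means clustering mapped to labels by majority vote.
"""

from .base import Classifier, save_model, load_model
from .fda import FDAClassifier
from .fmmnn import FMMNNClassifier
from .kernel_fda import KernelFDAClassifier
from .svm import GKSVMClassifier
from .fcm import FCMClassifier
from .search import default_grid, hyperparam_search

METHODS = ("FDA", "FMMNN", "GK-FDA", "GK-SVM", "FCM")

_CLASSES = {
    "FDA": FDAClassifier,
    "FMMNN": FMMNNClassifier,
    "GK-FDA": KernelFDAClassifier,
    "GK-SVM": GKSVMClassifier,
    "FCM": FCMClassifier,
}


def make_classifier_class(method: str):
    """Classifier class for a method acronym."""
    if method not in _CLASSES:
        raise KeyError(f"unknown method {method!r}; valid: {', '.join(METHODS)}")
    return _CLASSES[method]


def make_classifier(method: str, **hyperparams) -> Classifier:
    """Instantiate an unfitted classifier for a method acronym."""
    return make_classifier_class(method)(**hyperparams)


__all__ = [
    "Classifier",
    "FDAClassifier",
    "FMMNNClassifier",
    "KernelFDAClassifier",
    "GKSVMClassifier",
    "FCMClassifier",
    "METHODS",
    "make_classifier",
    "make_classifier_class",
    "default_grid",
    "hyperparam_search",
    "save_model",
    "load_model",
]
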