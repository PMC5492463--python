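"""Behavioural tests for the five classifiers and the hyperparameter search."""

import json

import numpy as np
import pytest

from semg_actmon.classifiers import (
    METHODS,
    default_grid,
    hyperparam_search,
    load_model,
    make_classifier,
    save_model,
)
from semg_actmon.classifiers.fcm import fcm_cluster


def _make(method, **kw):
    defaults = {
        "GK-FDA": {"sigma": 2.0},
        "GK-SVM": {"sigma": 2.0},
        "FMMNN": {"theta": 0.3},
    }
    return make_classifier(method, **{**defaults.get(method, {}), **kw})


def _blobs(rng, k=8, npc=40, d=4, spread=1.0, sep=10.0):
    centers = rng.normal(0, sep, (k, d))
    X = np.vstack([c + rng.normal(0, spread, (npc, d)) for c in centers])
    y = np.repeat([f"c{i}" for i in range(k)], npc)
    perm = rng.permutation(len(y))
    return X[perm], y[perm]


def _split(X, y, frac=0.75):
    n = int(frac * len(y))
    return X[:n], y[:n], X[n:], y[n:]


# ---------------------------------------------------------------------------
# shared contract
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("method", METHODS)
def test_easy_blobs_and_permuted_labels(method, rng):
    """Each classifier is near-perfect on well-separated 8-class blobs and at
    chance (12.5% ± 10%) once the training labels are permuted."""
    X, y = _blobs(rng)
    Xtr, ytr, Xte, yte = _split(X, y)
    clf = _make(method).fit(Xtr, ytr)
    assert np.mean(clf.predict(Xte) == yte) >= 0.95

    yperm = rng.permutation(ytr)
    clf2 = _make(method).fit(Xtr, yperm)
    acc = np.mean(clf2.predict(Xte) == yte)
    assert abs(acc - 0.125) <= 0.10


@pytest.mark.parametrize("method", METHODS)
def test_predict_is_pure_and_roundtrip_stable(method, rng, tmp_path):
    X, y = _blobs(rng, k=3, npc=20)
    clf = _make(method).fit(X, y)
    p1 = clf.predict(X)
    p2 = clf.predict(X)
    np.testing.assert_array_equal(p1, p2)

    path = tmp_path / "model.json"
    save_model(clf, path)
    json.loads(path.read_text())  # plain JSON on disk
    np.testing.assert_array_equal(load_model(path).predict(X), p1)


@pytest.mark.parametrize("method", ["GK-FDA", "GK-SVM"])
def test_kernel_methods_invariant_to_sample_order(method, rng):
    X, y = _blobs(rng, k=4, npc=25)
    ref = _make(method).fit(X, y).predict(X)
    for seed in (1, 2, 3):
        perm = np.random.default_rng(seed).permutation(len(y))
        pred = _make(method).fit(X[perm], y[perm]).predict(X)
        np.testing.assert_array_equal(pred, ref)


def test_fmmnn_order_dependence_is_bounded(rng):
    """Single-pass hyperbox learning depends on presentation order; on the
    easy set the spread in accuracy over shuffles stays within 10%."""
    X, y = _blobs(rng)
    Xtr, ytr, Xte, yte = _split(X, y)
    accs = []
    for seed in (1, 2, 3):
        perm = np.random.default_rng(seed).permutation(len(ytr))
        clf = _make("FMMNN").fit(Xtr[perm], ytr[perm])
        accs.append(np.mean(clf.predict(Xte) == yte))
    assert max(accs) - min(accs) <= 0.10


@pytest.mark.parametrize("method", METHODS)
def test_single_class_rejected(method):
    with pytest.raises(ValueError):
        _make(method).fit(np.zeros((10, 2)), np.repeat("a", 10))


# ---------------------------------------------------------------------------
# FDA
# ---------------------------------------------------------------------------

def test_fda_duplicate_training_point(rng):
    X, y = _blobs(rng, k=2, npc=30, d=3)
    clf = _make("FDA").fit(X, y)
    assert clf.predict(X[:1])[0] == y[0]


def test_fda_chance_when_means_equal(rng):
    Xtr = rng.normal(0, 1, (400, 4))
    ytr = np.repeat(["a", "b"], 200)
    Xte = rng.normal(0, 1, (4000, 4))
    clf = _make("FDA").fit(Xtr, ytr)
    pred = clf.predict(Xte)
    assert abs(np.mean(pred == "a") - 0.5) < 0.05


# ---------------------------------------------------------------------------
# FMMNN
# ---------------------------------------------------------------------------

def test_fmmnn_membership_inside_own_box(rng):
    X, y = _blobs(rng, k=2, npc=10, d=2)
    clf = _make("FMMNN").fit(X, y)
    Z = clf.scaler_.transform(X)
    memb = clf._membership(Z)
    for i, z in enumerate(Z):
        inside = (clf.V_ <= z + 1e-12).all(axis=1) & (z - 1e-12 <= clf.W_).all(axis=1)
        assert memb[i][inside].max() == pytest.approx(1.0)


def test_fmmnn_postconditions(rng):
    X, y = _blobs(rng, k=4, npc=25, d=3)
    theta = 0.25
    clf = make_classifier("FMMNN", theta=theta).fit(X, y)
    assert len(clf.box_class_) <= len(y)
    assert np.all(clf.W_ - clf.V_ <= theta + 1e-12)
    # no different-class pair overlaps in the strict all-dimensions sense
    for j in range(len(clf.V_)):
        for k in range(len(clf.V_)):
            if clf.box_class_[j] == clf.box_class_[k]:
                continue
            lo = np.maximum(clf.V_[j], clf.V_[k])
            hi = np.minimum(clf.W_[j], clf.W_[k])
            assert not np.all(hi - lo > 1e-12)


def test_fmmnn_hand_traceable_squares():
    X = np.array([[0.1, 0.1], [0.2, 0.15], [0.15, 0.25], [0.05, 0.2],
                  [0.8, 0.8], [0.9, 0.85], [0.85, 0.75], [0.75, 0.9]])
    y = np.array(["a"] * 4 + ["b"] * 4)
    clf = make_classifier("FMMNN", theta=0.3).fit(X, y)
    assert np.all(clf.predict(X) == y)
    assert len(clf.box_class_) == 2  # one box per square

    with pytest.raises(ValueError):
        make_classifier("FMMNN", theta=0.0)


# ---------------------------------------------------------------------------
# GK-FDA
# ---------------------------------------------------------------------------

def test_gkfda_solves_concentric_circles(rng):
    n = 200
    th = rng.uniform(0, 2 * np.pi, n)
    r = np.where(np.arange(n) < n // 2, 1.0, 3.0)
    X = np.c_[r * np.cos(th), r * np.sin(th)] + rng.normal(0, 0.1, (n, 2))
    y = np.where(np.arange(n) < n // 2, "inner", "outer")
    perm = rng.permutation(n)
    X, y = X[perm], y[perm]
    Xtr, ytr, Xte, yte = _split(X, y)
    assert np.mean(make_classifier("GK-FDA", sigma=1.0).fit(Xtr, ytr)
                   .predict(Xte) == yte) >= 0.95
    # the linear discriminant cannot separate the radii
    assert np.mean(_make("FDA").fit(Xtr, ytr).predict(Xte) == yte) < 0.7


def test_gkfda_large_sigma_approaches_linear_fda(rng):
    X, y = _blobs(rng, k=3, npc=40, d=3)
    Xtr, ytr, Xte, yte = _split(X, y)
    acc_lin = np.mean(_make("FDA").fit(Xtr, ytr).predict(Xte) == yte)
    acc_ker = np.mean(make_classifier("GK-FDA", sigma=200.0).fit(Xtr, ytr)
                      .predict(Xte) == yte)
    assert abs(acc_lin - acc_ker) <= 0.02


def test_gkfda_agrees_with_sklearn_lda_on_linear_data(rng):
    """Independent cross-check: on linearly separable data the Gaussian-kernel
    discriminant at large width reproduces sklearn's LDA decisions."""
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    X, y = _blobs(rng, k=3, npc=30, d=3)
    Xtr, ytr, Xte, yte = _split(X, y)
    skl = LinearDiscriminantAnalysis().fit(Xtr, ytr).predict(Xte)
    ours = make_classifier("GK-FDA", sigma=100.0).fit(Xtr, ytr).predict(Xte)
    assert np.mean(skl == ours) >= 0.98


# ---------------------------------------------------------------------------
# GK-SVM
# ---------------------------------------------------------------------------

def test_gksvm_xor_and_separable(rng):
    corners = np.array([[1, 1], [1, -1], [-1, 1], [-1, -1]])
    X = rng.normal(0, 0.3, (200, 2)) + corners[np.arange(200) % 4]
    y = np.where((X[:, 0] > 0) == (X[:, 1] > 0), "same", "diff")
    Xtr, ytr, Xte, yte = _split(X, y)
    clf = make_classifier("GK-SVM", sigma=0.5, C=10.0).fit(Xtr, ytr)
    assert np.mean(clf.predict(Xte) == yte) >= 0.95

    Xb, yb = _blobs(rng, k=2, npc=50, d=2)
    big_c = make_classifier("GK-SVM", sigma=2.0, C=1000.0).fit(Xb, yb)
    assert np.mean(big_c.predict(Xb) == yb) == 1.0

    with pytest.raises(ValueError):
        make_classifier("GK-SVM", sigma=-1.0)
    with pytest.raises(ValueError):
        make_classifier("GK-SVM", C=0.0)


# ---------------------------------------------------------------------------
# FCM
# ---------------------------------------------------------------------------

def test_fcm_membership_constraint_and_objective(rng):
    X = rng.normal(0, 1, (60, 3)) + np.repeat(rng.normal(0, 8, (3, 3)), 20, axis=0)
    centers, U, trace = fcm_cluster(X, 3, rng=np.random.default_rng(0))
    np.testing.assert_allclose(U.sum(axis=1), 1.0, atol=1e-9)
    diffs = np.diff(trace)
    assert np.all(diffs <= 1e-9)  # alternating optimisation never increases J


def test_fcm_classifier_on_three_blobs():
    for seed in range(5):
        r = np.random.default_rng(seed)
        X = r.normal(0, 1, (120, 2)) + np.repeat(r.normal(0, 10, (3, 2)), 40, axis=0)
        y = np.repeat(list("abc"), 40)
        clf = make_classifier("FCM", seed=seed).fit(X, y)
        assert np.mean(clf.predict(X) == y) >= 0.95


def test_fcm_rejects_bad_fuzzifier():
    with pytest.raises(ValueError):
        make_classifier("FCM", fuzzifier=1.0)


# ---------------------------------------------------------------------------
# hyperparameter search
# ---------------------------------------------------------------------------

def test_search_grid_of_one_and_defaults():
    best, score = hyperparam_search(lambda **p: _make("FDA"), np.zeros((4, 2)),
                                    np.array(["a", "a", "b", "b"]), [{}])
    assert best == {}
    assert [g["sigma"] for g in default_grid("GK-SVM")][:3] == [0.5, 0.6, 0.7]
    assert len(default_grid("GK-SVM")) == 46
    assert len(default_grid("FMMNN")) == 10


def test_search_finds_known_scale(rng):
    """Blobs built at unit scale select a kernel width near 1."""
    X, y = _blobs(rng, k=3, npc=30, d=2, spread=1.0, sep=3.0)
    grid = [{"sigma": s} for s in (0.1, 1.0, 50.0)]
    best, score = hyperparam_search(
        lambda **p: make_classifier("GK-SVM", **p), X, y, grid, seed=0
    )
    assert best["sigma"] == 1.0


def test_search_propagates_degenerate_data_error():
    X = np.zeros((6, 2))
    y = np.repeat("a", 6)
    with pytest.raises(ValueError):
        hyperparam_search(lambda **p: _make("FDA"), X, y, [{}, {}], seed=0)
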