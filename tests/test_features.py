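"""Unit and property tests for the feature extractors and extraction driver."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from semg_actmon import features as ft
from semg_actmon.features import FeatureSpec, extract, feature_registry


# ---------------------------------------------------------------------------
# closed-form / stated examples
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "fn,x,expected",
    [
        (ft.iav, [2, 2, 2, 2], 2.0),
        (ft.iav, [1, -1, 1, -1], 1.0),
        (ft.var_raw, [1, 1, 1, 1], 4.0 / 3.0),
        (ft.var_raw, [0, 0, 0], 0.0),
        (ft.zc, [1, -1, 1, -1], 3),
        (ft.zc, [0, 0, 0, 0], 0),
        (ft.nt, [0, 1, 2, 3, 4], 0),
        (ft.nt, [0, 1, 0, 1, 0], 3),
        (ft.ma, [5, 5, 5], 0.0),
        (ft.ma, [0, 1, 0, 1], 3.0),
    ],
)
def test_scalar_feature_examples(fn, x, expected):
    assert fn(np.asarray(x, dtype=float)) == pytest.approx(expected)


def test_wamp_threshold_examples():
    assert ft.wamp(np.full(10, 3.0), 0.01) == 0
    # differences: 0.1, 0.0, 0.2 -> two strict exceedances of 0.05
    assert ft.wamp(np.array([0.0, 0.1, 0.1, 0.3]), 0.05) == 2
    x = np.array([0.0, 0.0, 1.0, 1.0, 0.5])
    assert ft.wamp(x, 0.0) == np.count_nonzero(np.diff(x))


def test_mean_frequency_of_tones():
    fs, n = 1024.0, 1536
    t = np.arange(n) / fs
    bin_hz = fs / n
    assert ft.mf(np.sin(2 * np.pi * 100 * t), fs) == pytest.approx(100.0, abs=bin_hz)
    two = np.sin(2 * np.pi * 100 * t) + np.sin(2 * np.pi * 300 * t)
    assert ft.mf(two, fs) == pytest.approx(200.0, abs=2 * bin_hz)
    with pytest.raises(ValueError):
        ft.mf(np.zeros(64), fs)


def test_mean_frequency_of_white_noise_is_quarter_fs(rng):
    x = rng.standard_normal(200_000)
    assert ft.mf(x, 1024.0) == pytest.approx(256.0, rel=0.05)


def test_histogram_conservation_and_center(rng):
    assert ft.hist_feat(np.zeros(50), -5, 5, 21)[10] == 50
    x = rng.normal(0, 10, 500)  # many samples outside [-5, 5]
    counts = ft.hist_feat(x, -5, 5, 21)
    assert counts.sum() == 500  # clipped into edge bins, nothing dropped
    assert counts[0] > 0 and counts[-1] > 0


def _simulate_ar(a, n, innov):
    p = len(a)
    x = np.zeros(n + 200)
    for i in range(p, len(x)):
        x[i] = np.dot(a, x[i - p : i][::-1]) + innov[i]
    return x[200:]


def test_ar_recovers_known_process(rng):
    a = np.array([0.55, -0.2, 0.1, -0.05])
    x = _simulate_ar(a, 4096, rng.standard_normal(4296))
    assert np.max(np.abs(ft.ar_coeffs(x, 4) - a)) < 0.05


def test_ar_white_noise_coefficients_near_zero(rng):
    x = rng.standard_normal(4096)
    assert np.all(np.abs(ft.ar_coeffs(x, 4)) < 0.1)


def test_ar1_closed_form(rng):
    x = _simulate_ar(np.array([0.5]), 20_000, rng.standard_normal(20_200))
    assert ft.ar_coeffs(x, 1)[0] == pytest.approx(0.5, abs=0.03)


def test_arcu_recovers_skew_driven_process(rng):
    a = np.array([0.55, -0.2, 0.1, -0.05])
    x = _simulate_ar(a, 8192, rng.exponential(1.0, 8392))
    est = ft.arcu_coeffs(x, 4)
    assert est.shape == (4,)
    assert np.max(np.abs(est - a)) < 0.15


def test_arcu_on_symmetric_noise_is_finite(rng):
    # zero-skew innovations make the cumulant system nearly singular; the
    # regularised solve must still return finite coefficients
    est = ft.arcu_coeffs(rng.standard_normal(8192), 4)
    assert np.all(np.isfinite(est))


def test_wavelet_energy_zero_signal():
    assert np.all(ft.ewt(np.zeros(1536)) == 0)
    assert np.all(ft.ewp(np.zeros(1536)) == 0)
    assert np.all(ft.zcwt(np.zeros(1536)) == 0)


def test_wavelet_parseval(rng):
    """Layer energies of the orthogonal transforms partition the signal energy."""
    import pywt

    x = rng.standard_normal(1536)
    total = np.sum(x**2)
    coeffs = pywt.wavedec(x, "db8", mode="periodization", level=5)
    details = coeffs[1:][::-1]
    ewt_energy = sum(f * d.size for f, d in zip(ft.ewt(x), details))
    assert ewt_energy + np.sum(coeffs[0] ** 2) == pytest.approx(total, rel=1e-6)

    node_len = 1536 // 8
    assert np.sum(ft.ewp(x) * node_len) == pytest.approx(total, rel=1e-6)


def test_zcwt_equals_zc_on_coefficients(rng):
    import pywt

    x = rng.standard_normal(1536)
    details = pywt.wavedec(x, "db8", mode="periodization", level=5)[1:][::-1]
    np.testing.assert_array_equal(ft.zcwt(x), [ft.zc(d) for d in details])


def test_fuzzy_entropy_limits(rng):
    assert ft.fuzzy_entropy(np.full(64, 3.0)) == 0.0
    assert ft.fuzzy_entropy(rng.standard_normal(200)) >= -1e-12


def test_permutation_entropy_limits(rng):
    assert ft.permutation_entropy(np.arange(100.0), 4) == 0.0
    assert ft.permutation_entropy(np.zeros(100), 4) == 0.0
    x = rng.standard_normal(100_000)
    assert ft.permutation_entropy(x, 4) == pytest.approx(np.log(24), abs=0.05)


# ---------------------------------------------------------------------------
# scaling behaviour (property tests)
# ---------------------------------------------------------------------------

signals = arrays(
    float,
    st.integers(32, 96),
    elements=st.floats(-10, 10, allow_nan=False, width=32),
).filter(lambda x: np.std(x) > 1e-3)


@settings(max_examples=40, derandomize=True, deadline=None)
@given(x=signals, s=st.floats(0.1, 50.0))
def test_scale_invariance_and_homogeneity(x, s):
    """ZC/NT/PE ignore positive scaling; IAV is linear, VAR quadratic."""
    assert ft.zc(s * x) == ft.zc(x)
    assert ft.nt(s * x) == ft.nt(x)
    assert ft.permutation_entropy(s * x, 3) == pytest.approx(
        ft.permutation_entropy(x, 3), abs=1e-9
    )
    assert ft.iav(s * x) == pytest.approx(s * ft.iav(x), rel=1e-9)
    assert ft.var_raw(s * x) == pytest.approx(s**2 * ft.var_raw(x), rel=1e-9)


@settings(max_examples=40, derandomize=True, deadline=None)
@given(x=signals, t1=st.floats(0.0, 2.0), t2=st.floats(0.0, 2.0))
def test_wamp_non_increasing_in_threshold(x, t1, t2):
    lo, hi = sorted((t1, t2))
    assert ft.wamp(x, hi) <= ft.wamp(x, lo)


# ---------------------------------------------------------------------------
# registry and extraction driver
# ---------------------------------------------------------------------------

def test_registry_dimensions_match_convention():
    reg = feature_registry()
    dims = {fid: spec.expected_dim(4) for fid, spec in reg.items()}
    expected = {
        "IAV": 4, "VAR": 4, "WAMP": 4, "ZC": 4, "NT": 4, "MA": 4, "MF": 4,
        "HIST": 84, "EWT": 20, "EWP": 32, "ZCWT": 20, "FE": 4, "PE": 4,
    }
    for fid, d in expected.items():
        assert dims[fid] == d
    # order-4 AR models keep all 4 coefficients per channel, flagged as a
    # deviation from the conventional 12
    assert dims["AR"] == dims["ARCU"] == 16
    assert reg["AR"].deviates_from_table and reg["ARCU"].deviates_from_table


@pytest.mark.parametrize("fid,dim", [("IAV", 4), ("HIST", 84), ("EWP", 32), ("ZCWT", 20)])
def test_extract_dimensions(small_dataset, fid, dim):
    fm = extract(small_dataset, feature_registry()[fid])
    assert fm.values.shape == (len(small_dataset), dim)
    assert np.isfinite(fm.values).all()
    assert fm.extraction_time_s > 0
    assert len(fm.column_names) == dim


def test_extract_reports_failing_epoch_and_channel(small_dataset):
    bad = FeatureSpec("MF", {"fs": 1024.0})
    ds = small_dataset.subset(np.arange(len(small_dataset)) < 3)
    ds.epochs[1] = type(ds.epochs[1])(
        np.zeros_like(ds.epochs[1].samples), fs=ds.epochs[1].fs
    )
    with pytest.raises(RuntimeError, match="epoch 1, channel 0"):
        extract(ds, bad)


def test_unknown_feature_id_lists_valid_names():
    with pytest.raises(KeyError, match="IAV"):
        ft.apply_feature(np.zeros(16), FeatureSpec("BOGUS"))


@pytest.mark.parametrize(
    "fn,args",
    [
        (ft.iav, (np.array([]),)),
        (ft.var_raw, (np.array([1.0]),)),
        (ft.wamp, (np.array([1.0]), 0.1)),
        (ft.zc, (np.array([1.0]),)),
        (ft.nt, (np.array([1.0, 2.0]),)),
        (ft.hist_feat, (np.zeros(4), 5.0, -5.0, 21)),
        (ft.ar_coeffs, (np.zeros(100), 4)),
        (ft.permutation_entropy, (np.zeros(2), 4)),
    ],
)
def test_precondition_errors(fn, args):
    with pytest.raises(ValueError):
        fn(*args)
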