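"""Trimming, windowing, time-domain features and normalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emgpr.errors import ConfigurationError, DataError
from emgpr.features import (
    FeatureMatrix,
    WindowSpec,
    apply_normalization,
    extract_features,
    extract_td_features,
    fit_normalization,
    slice_windows,
    trim_recording,
    window_count,
)


# -- oracles ----------------------------------------------------------------

def td_features_loop(x, zc_thr=0.0, ssc_thr=0.0):
    """Brute-force loop implementation of MAV/WL/ZC/SSC."""
    x = np.asarray(x, dtype=float)
    mav = sum(abs(v) for v in x) / len(x)
    wl = sum(abs(x[k + 1] - x[k]) for k in range(len(x) - 1))
    zc = 0
    for k in range(len(x) - 1):
        if x[k] * x[k + 1] < 0 and abs(x[k + 1] - x[k]) > zc_thr:
            zc += 1
    ssc = 0
    for k in range(1, len(x) - 1):
        b, f = x[k] - x[k - 1], x[k] - x[k + 1]
        if b * f > 0 and abs(b) > ssc_thr and abs(f) > ssc_thr:
            ssc += 1
    return np.array([mav, wl, zc, ssc])


def count_windows_loop(L, w, i):
    count, start = 0, 0
    while start + w <= L:
        count += 1
        start += i
    return count


# -- trimming ---------------------------------------------------------------

def test_trim_keeps_central_portion():
    x = np.arange(1000)
    out = trim_recording(x, 0.15)
    assert out[0] == 150 and out[-1] == 849 and len(out) == 700


def test_trim_zero_is_identity():
    x = np.arange(10)
    assert np.array_equal(trim_recording(x, 0.0), x)


def test_trim_half_forbidden():
    with pytest.raises(ConfigurationError):
        trim_recording(np.arange(10), 0.5)


# -- windowing --------------------------------------------------------------

def test_window_count_examples():
    assert window_count(1000, 200, 50) == 17
    assert window_count(200, 200, 50) == 1
    assert window_count(700, 200, 50) == 11  # 1000 samples trimmed at 15 %


@given(
    L=st.integers(min_value=1, max_value=500),
    w=st.integers(min_value=1, max_value=500),
    i=st.integers(min_value=1, max_value=500),
)
@settings(deadline=None, max_examples=200)
def test_window_count_matches_enumeration(L, w, i):
    if i > w:
        i = w
    assert window_count(L, w, i) == count_windows_loop(L, w, i)


def test_slice_windows_shape_and_content():
    x = np.arange(1000, dtype=float)[:, None]
    wins = slice_windows(x, WindowSpec(0.2, 0.05, 0.0), 1000.0)
    assert wins.shape == (17, 200, 1)
    assert np.array_equal(wins[0, :, 0], np.arange(200))
    assert np.array_equal(wins[1, :, 0], np.arange(50, 250))  # half-open step


def test_slice_windows_too_short():
    with pytest.raises(ConfigurationError):
        slice_windows(np.zeros((100, 1)), WindowSpec(0.2, 0.05, 0.0), 1000.0)


def test_window_spec_validation():
    with pytest.raises(ConfigurationError):
        WindowSpec(window_length=-1)
    with pytest.raises(ConfigurationError):
        WindowSpec(increment=0.3, window_length=0.2)
    with pytest.raises(ConfigurationError):
        WindowSpec(trim_fraction=0.6)


# -- time-domain features ---------------------------------------------------

def test_constant_window_features():
    assert np.array_equal(extract_td_features([5, 5, 5, 5]), [5, 0, 0, 0])


def test_alternating_window_features():
    assert np.array_equal(extract_td_features([1, -1, 1, -1]), [1, 6, 3, 2])


def test_window_too_short():
    with pytest.raises(DataError):
        extract_td_features([1, 2])


@given(st.lists(st.floats(min_value=-10, max_value=10,
                          allow_nan=False), min_size=3, max_size=40),
       st.floats(min_value=0, max_value=1))
@settings(deadline=None, max_examples=100)
def test_features_match_loop_oracle(values, thr):
    got = extract_td_features(values, zc_threshold=thr, ssc_threshold=thr)
    expected = td_features_loop(values, thr, thr)
    assert np.allclose(got, expected)


@given(st.lists(st.floats(min_value=-10, max_value=10, allow_nan=False),
                min_size=3, max_size=40))
@settings(deadline=None, max_examples=50)
def test_features_invariant_under_negation(values):
    a = extract_td_features(values)
    b = extract_td_features([-v for v in values])
    assert np.allclose(a, b)


def test_session_features_are_32_dimensional(small_session, small_features):
    assert small_session.channel_count == 8
    assert small_features.values.shape[1] == 32
    assert small_features.feature_names[:4] == [
        "ch1_mav", "ch1_wl", "ch1_zc", "ch1_ssc"
    ]
    # windows never span repetition boundaries: per-segment count x reps
    per_class = small_features.windows_per_class()
    assert set(per_class.values()) == {3 * window_count(1050, 200, 50)}


def test_feature_matrix_tsv_round_trip(tmp_path, small_features):
    path = tmp_path / "features.tsv"
    small_features.to_tsv(path)
    back = FeatureMatrix.from_tsv(path)
    assert np.array_equal(back.values, small_features.values)
    assert np.array_equal(back.class_indices, small_features.class_indices)
    assert back.feature_names == small_features.feature_names


# -- normalization ----------------------------------------------------------

def test_zscore_two_point_column():
    spec = fit_normalization(np.array([[0.0], [2.0]]), "zscore")
    out = apply_normalization(np.array([[0.0], [2.0]]), spec)
    assert np.allclose(out.ravel(), [-1 / np.sqrt(2), 1 / np.sqrt(2)])


def test_midrange_two_point_column():
    spec = fit_normalization(np.array([[0.0], [2.0]]), "midrange0range2")
    out = apply_normalization(np.array([[0.0], [2.0]]), spec)
    assert np.allclose(out.ravel(), [-1.0, 1.0])


@pytest.mark.parametrize("kind", ["zscore", "midrange0range2"])
def test_fitted_spec_gives_stated_column_statistics(rng, kind):
    X = rng.standard_normal((200, 7)) * rng.uniform(0.5, 3, 7) + rng.normal(0, 5, 7)
    out = apply_normalization(X, fit_normalization(X, kind))
    if kind == "zscore":
        assert np.allclose(out.mean(axis=0), 0, atol=1e-10)
        assert np.allclose(out.std(axis=0, ddof=1), 1, atol=1e-10)
    else:
        assert np.allclose(out.min(axis=0), -1, atol=1e-10)
        assert np.allclose(out.max(axis=0), 1, atol=1e-10)


def test_degenerate_column_scale_forced_to_one(caplog):
    X = np.column_stack([np.arange(4.0), np.full(4, 3.0)])
    with caplog.at_level("WARNING"):
        spec = fit_normalization(X, "zscore")
    assert spec.scale[1] == 1.0
    assert "zero-variance" in caplog.text
    out = apply_normalization(X, spec)
    assert np.isfinite(out).all()
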