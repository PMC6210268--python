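import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import grazeclass as gc
from grazeclass.preprocess import Window
from oracles import direct_dft_power, direct_moments, direct_quantile

FS = 16.0
N = 112


def make_window(arrays):
    return Window(channels=dict(zip(("A", "AD", "G", "GD"), arrays)),
                  label="grazing", is_mixed=False, start_index=0)


def test_basic_stats_simple_sequence():
    mean, std, kurt, mn, mx, iqr = gc.basic_stats([1, 2, 3, 4, 5])
    assert (mean, mn, mx) == (3.0, 1.0, 5.0)
    assert std == pytest.approx(math.sqrt(2.5))


def test_basic_stats_constant_sequence_warns_on_kurtosis():
    with pytest.warns(UserWarning, match="kurtosis"):
        mean, std, kurt, mn, mx, iqr = gc.basic_stats([4.0] * 10)
    assert std == 0.0 and iqr == 0.0 and kurt == 0.0


def test_moments_match_direct_sum_oracle(rng):
    """Mean/std/kurtosis/iqr agree with naive defining-sum recomputation."""
    for _ in range(50):
        x = rng.standard_normal(N)
        mean, std, kurt, mn, mx, iqr = gc.basic_stats(x)
        omean, ostd, okurt = direct_moments(x.tolist())
        assert mean == pytest.approx(omean, abs=1e-12)
        assert std == pytest.approx(ostd, abs=1e-12)
        assert kurt == pytest.approx(okurt, abs=1e-9)
        oiqr = direct_quantile(x.tolist(), 0.75) - direct_quantile(x.tolist(), 0.25)
        assert iqr == pytest.approx(oiqr, abs=1e-9)


def test_signal_areas_constant_and_alternating():
    area, abs_area = gc.signal_areas(np.ones(N), FS)
    assert area == pytest.approx(7.0)
    alt = np.tile([1.0, -1.0], N // 2)
    area, abs_area = gc.signal_areas(alt, FS)
    assert area == pytest.approx(0.0)
    assert abs_area == pytest.approx(7.0)


@given(st.lists(st.floats(-50, 50), min_size=1, max_size=200))
@settings(derandomize=True, deadline=None)
def test_abs_area_dominates_signed_area(xs):
    area, abs_area = gc.signal_areas(xs, FS)
    assert abs_area >= abs(area) - 1e-9


def test_zero_crossings_conventions():
    assert gc.zero_crossings([3.0] * 10) == 0
    n = 21
    alt = [1.0 if i % 2 == 0 else -1.0 for i in range(n)]
    assert gc.zero_crossings(alt) == n - 1


def test_zero_crossings_four_period_sinusoid():
    t = np.arange(N) / FS
    # exactly 4 periods in the 7 s window; phase keeps samples off the axis
    x = 5.0 + np.sin(2 * np.pi * (4 / 7.0) * t + 0.3)
    assert gc.zero_crossings(x) == 8


def test_zero_crossings_ignores_on_mean_samples():
    # samples exactly at the centring mean must not break a sign run
    x = [1.0, 0.0, 1.0, -1.0, 0.0, -1.0]  # mean 0
    assert gc.zero_crossings(x) == 1


def test_spectrum_matches_direct_dft(rng):
    x = rng.standard_normal(40)
    freqs, power = gc.spectrum(x, FS)
    np.testing.assert_allclose(power, direct_dft_power(x.tolist()),
                               rtol=1e-9, atol=1e-6)
    assert freqs[1] == pytest.approx(FS / 40)


def test_spectrum_concentrates_tone_power():
    t = np.arange(N) / FS
    freqs, power = gc.spectrum(np.sin(2 * np.pi * 2.0 * t), FS)
    peak = np.argmax(power[1:]) + 1
    assert freqs[peak] == pytest.approx(2.0)
    assert power[peak] / power[1:].sum() > 0.99


def test_white_noise_spreads_power():
    for seed in range(20):
        x = np.random.default_rng(seed).standard_normal(N)
        _, power = gc.spectrum(x, FS)
        assert power[1:].max() / power[1:].sum() < 0.5


def test_dominant_frequency_exact_bin():
    t = np.arange(N) / FS
    # 2 Hz sits exactly on bin 14 (df = 16/112 = 1/7 Hz)
    assert gc.dominant_frequency(np.sin(2 * np.pi * 2.0 * t), FS) == 2.0


def test_dominant_frequency_degenerate_and_amplitude_dominance():
    assert gc.dominant_frequency(np.full(N, 3.0), FS) == 0.0
    t = np.arange(N) / FS
    x = np.sin(2 * np.pi * 1.0 * t) + 2.0 * np.sin(2 * np.pi * 3.0 * t)
    assert gc.dominant_frequency(x, FS) == pytest.approx(3.0)


def test_spectral_entropy_pure_tone_and_bounds(rng):
    t = np.arange(N) / FS
    assert gc.spectral_entropy(np.sin(2 * np.pi * 2.0 * t), FS) < 1e-8
    n_bins = N // 2  # non-DC one-sided bins
    for _ in range(10):
        h = gc.spectral_entropy(rng.standard_normal(N), FS)
        assert 0.0 <= h <= math.log(n_bins)


def test_spectral_entropy_flat_spectrum_is_ln_k():
    # build a signal whose non-DC magnitude spectrum is exactly flat
    bins = N // 2 + 1
    X = np.ones(bins, dtype=complex)
    X[0] = 0.0
    x = np.fft.irfft(X, n=N)
    k = bins - 1
    assert gc.spectral_entropy(x, FS) == pytest.approx(math.log(k), abs=1e-9)


def test_spectral_area_linearity_and_noise_growth():
    t = np.arange(N) / FS
    x = np.sin(2 * np.pi * 2.0 * t)
    assert gc.spectral_area(np.full(N, 5.0), FS) == pytest.approx(0.0, abs=1e-9)
    assert gc.spectral_area(2 * x, FS) == pytest.approx(
        2 * gc.spectral_area(x, FS))
    base = gc.spectral_area(x, FS)
    for seed in range(20):
        noisy = x + 0.3 * np.random.default_rng(seed).standard_normal(N)
        assert gc.spectral_area(noisy, FS) > base


def test_extract_features_yields_exactly_44(rng):
    w = make_window(rng.standard_normal((4, N)))
    feats = gc.extract_features(w, FS)
    assert len(feats) == 44
    assert list(feats) == gc.feature_names("table3")
    feats25 = gc.extract_features(w, FS, "section25")
    assert len(feats25) == 44
    assert "A.abs_signal_area" in feats25 and "A.spectral_area" not in feats25


def test_identical_channels_give_identical_features(rng):
    x = rng.standard_normal(N)
    w = make_window([x, x.copy(), x.copy(), x.copy()])
    feats = gc.extract_features(w, FS)
    for c in ("mean", "std", "dominant_frequency", "spectral_entropy"):
        assert feats[f"A.{c}"] == feats[f"G.{c}"]


def test_all_zero_window_features():
    w = make_window(np.zeros((4, N)))
    with pytest.warns(UserWarning):
        feats = gc.extract_features(w, FS)
    for s in ("A", "AD", "G", "GD"):
        assert feats[f"{s}.mean"] == 0.0
        assert feats[f"{s}.signal_area"] == 0.0
        assert feats[f"{s}.zero_crossings"] == 0.0
        assert feats[f"{s}.dominant_frequency"] == 0.0


def test_shift_invariance_and_mean_shift(rng):
    x = rng.standard_normal(N)
    w1 = make_window([x, x, x, x])
    w2 = make_window([x + 10.0, x, x, x])
    f1, f2 = gc.extract_features(w1, FS), gc.extract_features(w2, FS)
    for c in ("std", "iqr", "kurtosis", "zero_crossings",
              "dominant_frequency", "spectral_entropy", "spectral_area"):
        assert f2[f"A.{c}"] == pytest.approx(f1[f"A.{c}"], abs=1e-6)
    assert f2["A.mean"] == pytest.approx(f1["A.mean"] + 10.0)
    assert f2["A.signal_area"] == pytest.approx(f1["A.signal_area"] + 10.0 * 7.0)


def test_scale_equivariance(rng):
    x = rng.standard_normal(N)
    c = 3.0
    f1 = gc.extract_features(make_window([x, x, x, x]), FS)
    f2 = gc.extract_features(make_window([c * x, x, x, x]), FS)
    for name in ("mean", "std", "min", "max", "iqr", "signal_area"):
        assert f2[f"A.{name}"] == pytest.approx(c * f1[f"A.{name}"])
    for name in ("zero_crossings", "dominant_frequency", "spectral_entropy"):
        assert f2[f"A.{name}"] == pytest.approx(f1[f"A.{name}"], abs=1e-9)


def test_feature_matrix_shape_and_columns(small_windows):
    df = gc.extract_feature_matrix(small_windows)
    assert df.shape == (len(small_windows), 46)
    assert list(df.columns[:44]) == gc.feature_names("table3")
    assert set(df["label"]).issubset(set(gc.BEHAVIOURS))


def test_window_feature_extractor_transformer(rng):
    stack = rng.standard_normal((5, 4, N))
    ext = gc.WindowFeatureExtractor()
    out = ext.fit_transform(stack)
    assert out.shape == (5, 44)
    assert list(ext.get_feature_names_out()) == gc.feature_names("table3")
    assert ext.get_params()["characteristic_set"] == "table3"
    ext.set_params(characteristic_set="section25")
    assert ext.fit_transform(stack).shape == (5, 44)


def test_extract_rejects_short_window():
    w = make_window(np.ones((4, 3)))
    with pytest.raises(ValueError):
        gc.extract_features(w, FS)
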