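"""Per-window feature characteristics.

Eleven characteristics are computed on each of the four derived channels
(A, AD, G, GD) of a window, giving the 44-dimensional vector used for
behaviour classification. Two characteristic sets are supported:

* ``table3`` (default): mean, standard deviation, kurtosis, minimum,
  maximum, interquartile range, signal area, zero crossings, dominant
  frequency, spectral entropy, spectral area.
* ``section25``: as above but with absolute signal area in place of
  spectral area.

Conventions (documented so results are bit-for-bit reproducible): the
standard deviation is the sample (ddof = 1) estimate; kurtosis is the
standardised fourth central moment without excess-3 subtraction or bias
correction; zero crossings are strict sign changes of the mean-centred
signal (samples exactly on the mean do not break a sign run); spectra are
plain one-sided periodograms of the mean-removed signal with no taper, and
all spectral features exclude the DC bin.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.fft import rfft, rfftfreq

from .preprocess import ChannelSet, Window, WindowSet

_BASE_CHARACTERISTICS = (
    "mean", "std", "kurtosis", "min", "max", "iqr",
    "signal_area", "zero_crossings", "dominant_frequency", "spectral_entropy",
)

CHARACTERISTIC_SETS = {
    "table3": _BASE_CHARACTERISTICS + ("spectral_area",),
    "section25": _BASE_CHARACTERISTICS + ("abs_signal_area",),
}

_POWER_TOL = 1e-12  # relative non-DC power below which a spectrum is degenerate


def feature_names(characteristic_set: str = "table3") -> list[str]:
    """The ordered ``<stream>.<characteristic>`` names (44 at either default set)."""
    chars = CHARACTERISTIC_SETS[characteristic_set]
    return [f"{s}.{c}" for s in ChannelSet.STREAMS for c in chars]


def basic_stats(x) -> tuple[float, float, float, float, float, float]:
    """(mean, sample std, kurtosis, min, max, interquartile range).

    Kurtosis of a constant sequence is undefined and returned as 0 with a
    warning.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("basic_stats requires at least 2 samples")
    mean = x.mean()
    std = x.std(ddof=1)
    centred = x - mean
    m2 = np.mean(centred ** 2)
    if m2 == 0.0:
        warnings.warn("kurtosis undefined for constant input; returning 0")
        kurt = 0.0
    else:
        kurt = np.mean(centred ** 4) / m2 ** 2
    q25, q75 = np.percentile(x, [25, 75])
    return mean, std, kurt, x.min(), x.max(), q75 - q25


def signal_areas(x, sampling_rate_hz: float) -> tuple[float, float]:
    """(signal area, absolute signal area): sums of x and |x| times dt."""
    x = np.asarray(x, dtype=float)
    dt = 1.0 / sampling_rate_hz
    return x.sum() * dt, np.abs(x).sum() * dt


def zero_crossings(x) -> int:
    """Count strict sign changes of the mean-centred signal.

    The magnitude channels are non-negative, so crossings are counted
    about the window mean rather than about zero; samples exactly equal to
    the mean are treated as on-the-boundary and skipped.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("zero_crossings requires at least 2 samples")
    signs = np.sign(x - x.mean())
    signs = signs[signs != 0]
    if signs.size < 2:
        return 0
    return int(np.count_nonzero(np.diff(signs)))


def spectrum(x, sampling_rate_hz: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided periodogram of the mean-removed signal, DC bin included.

    Frequency spacing is ``fs / N``. Downstream features drop the DC bin
    themselves; it is kept here so bin indices match the raw rfft layout.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ValueError("spectrum requires at least 4 samples")
    X = rfft(x - x.mean())
    freqs = rfftfreq(x.size, 1.0 / sampling_rate_hz)
    power = np.abs(X) ** 2
    return freqs, power


def dominant_frequency(x, fs: float) -> float:
    """Frequency (Hz) of the maximum-power non-DC bin; 0 for degenerate input."""
    freqs, power = spectrum(x, fs)
    p = power[1:]
    total = p.sum()
    if total <= _POWER_TOL * max(1.0, float(np.abs(x).max()) ** 2 * len(p)):
        return 0.0
    return float(freqs[1:][np.argmax(p)])


def spectral_entropy(x, fs: float) -> float:
    """Shannon entropy (nats) of the normalised non-DC power distribution.

    0 for a one-bin (pure tone on an exact bin) or degenerate spectrum;
    bounded above by ln of the number of non-DC bins.
    """
    _, power = spectrum(x, fs)
    p = power[1:]
    total = p.sum()
    if total <= _POWER_TOL * max(1.0, float(np.abs(x).max()) ** 2 * len(p)):
        return 0.0
    p = p / total
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def spectral_area(x, fs: float) -> float:
    """Sum of the non-DC magnitude-spectrum bins times the bin width fs/N."""
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ValueError("spectral_area requires at least 4 samples")
    X = rfft(x - x.mean())
    df = fs / x.size
    return float(np.abs(X[1:]).sum() * df)


def _characteristics(x: np.ndarray, fs: float, chars) -> dict[str, float]:
    mean, std, kurt, mn, mx, iqr = basic_stats(x)
    area, abs_area = signal_areas(x, fs)
    out = {
        "mean": mean, "std": std, "kurtosis": kurt, "min": mn, "max": mx,
        "iqr": iqr, "signal_area": area, "abs_signal_area": abs_area,
        "zero_crossings": float(zero_crossings(x)),
        "dominant_frequency": dominant_frequency(x, fs),
        "spectral_entropy": spectral_entropy(x, fs),
        "spectral_area": spectral_area(x, fs),
    }
    return {c: out[c] for c in chars}


def extract_features(w: Window, fs: float,
                     characteristic_set: str = "table3") -> dict[str, float]:
    """The 44 named features of one window (11 characteristics x 4 streams)."""
    if characteristic_set not in CHARACTERISTIC_SETS:
        raise ValueError(f"unknown characteristic set {characteristic_set!r}")
    chars = CHARACTERISTIC_SETS[characteristic_set]
    first = next(iter(w.channels.values()))
    if len(first) < 4:
        raise ValueError("window must contain at least 4 samples")
    values: dict[str, float] = {}
    for stream in ChannelSet.STREAMS:
        for name, v in _characteristics(w.channels[stream], fs, chars).items():
            values[f"{stream}.{name}"] = v
    return values


def extract_feature_matrix(ws: WindowSet, fs: float = 16.0,
                           characteristic_set: str = "table3") -> pd.DataFrame:
    """Feature matrix for a window set: one row per window.

    Columns are the 44 features in documented order plus ``label`` and
    ``is_mixed``.
    """
    names = feature_names(characteristic_set)
    rows = [extract_features(w, fs, characteristic_set) for w in ws]
    df = pd.DataFrame(rows, columns=names)
    df["label"] = [w.label for w in ws]
    df["is_mixed"] = [w.is_mixed for w in ws]
    return df


class WindowFeatureExtractor:
    """Transformer mapping stacked window channels to the 44-feature matrix.

    Accepts an array of shape ``(n_windows, 4, window_len)`` with the
    channel axis ordered (A, AD, G, GD), or an iterable of
    :class:`~grazeclass.preprocess.Window`. Stateless; ``fit`` only
    records the output feature names so the class composes with
    scikit-learn pipelines.
    """

    def __init__(self, sampling_rate_hz: float = 16.0,
                 characteristic_set: str = "table3"):
        self.sampling_rate_hz = sampling_rate_hz
        self.characteristic_set = characteristic_set

    def get_params(self, deep: bool = True) -> dict:
        return {
            "sampling_rate_hz": self.sampling_rate_hz,
            "characteristic_set": self.characteristic_set,
        }

    def set_params(self, **params) -> "WindowFeatureExtractor":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X=None, y=None) -> "WindowFeatureExtractor":
        self.feature_names_out_ = feature_names(self.characteristic_set)
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "feature_names_out_"):
            self.fit()
        rows = []
        for w in X:
            if not isinstance(w, Window):
                w = Window(
                    channels=dict(zip(ChannelSet.STREAMS, np.asarray(w))),
                    label="", is_mixed=False, start_index=0,
                )
            feats = extract_features(w, self.sampling_rate_hz,
                                     self.characteristic_set)
            rows.append([feats[n] for n in self.feature_names_out_])
        return np.asarray(rows)

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X, y).transform(X)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.feature_names_out_, dtype=object)
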