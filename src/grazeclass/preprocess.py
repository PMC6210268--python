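"""Derived-channel construction and window discretisation.

Raw tri-axial accelerometer/gyroscope streams are reduced to four
orientation-invariant channels — accelerometer magnitude ``A``, gyroscope
magnitude ``G`` and their rates of change ``AD``/``GD`` — and cut into
fixed-length windows (7 s, 50 % overlap at the 16 Hz defaults) labelled
from a behaviour-interval track.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BEHAVIOURS = ("grazing", "non-eating", "ruminating")

STREAM_COLUMNS = ["timestamp", "ax", "ay", "az", "gx", "gy", "gz"]
LABEL_COLUMNS = ["start_s", "end_s", "behaviour"]


@dataclass
class SensorStream:
    """Uniformly sampled 6-axis IMU record with a placement tag.

    All seven arrays have equal length; timestamps are uniform at
    ``1/sampling_rate_hz`` within tolerance.
    """

    timestamps: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    gx: np.ndarray
    gy: np.ndarray
    gz: np.ndarray
    sampling_rate_hz: float = 16.0
    placement: str = "collar"

    def __post_init__(self) -> None:
        arrays = [self.timestamps, self.ax, self.ay, self.az,
                  self.gx, self.gy, self.gz]
        arrays = [np.asarray(a, dtype=float) for a in arrays]
        (self.timestamps, self.ax, self.ay, self.az,
         self.gx, self.gy, self.gz) = arrays
        n = len(self.timestamps)
        if any(len(a) != n for a in arrays):
            raise ValueError("all seven stream columns must have equal length")
        if n >= 2:
            dt = np.diff(self.timestamps)
            expected = 1.0 / self.sampling_rate_hz
            if not np.allclose(dt, expected, rtol=1e-6, atol=1e-9):
                raise ValueError(
                    "timestamps are not uniform at the stated sampling rate"
                )
        if self.placement not in ("ear", "collar"):
            raise ValueError(f"unknown placement {self.placement!r}")

    def __len__(self) -> int:
        return len(self.timestamps)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "timestamp": self.timestamps,
                "ax": self.ax, "ay": self.ay, "az": self.az,
                "gx": self.gx, "gy": self.gy, "gz": self.gz,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, sampling_rate_hz: float = 16.0,
                 placement: str = "collar") -> "SensorStream":
        df = pd.read_csv(path)
        missing = set(STREAM_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"stream CSV missing columns: {sorted(missing)}")
        return cls(
            timestamps=df["timestamp"].to_numpy(),
            ax=df["ax"].to_numpy(), ay=df["ay"].to_numpy(),
            az=df["az"].to_numpy(),
            gx=df["gx"].to_numpy(), gy=df["gy"].to_numpy(),
            gz=df["gz"].to_numpy(),
            sampling_rate_hz=sampling_rate_hz, placement=placement,
        )


@dataclass
class LabelTrack:
    """Behaviour intervals ``[start_s, end_s)`` over the stream clock."""

    starts: np.ndarray
    ends: np.ndarray
    behaviours: list[str]

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=float)
        self.ends = np.asarray(self.ends, dtype=float)
        self.behaviours = list(self.behaviours)
        if not (len(self.starts) == len(self.ends) == len(self.behaviours)):
            raise ValueError("starts, ends and behaviours must have equal length")
        if np.any(self.ends <= self.starts):
            raise ValueError("every interval must satisfy start < end")
        unknown = set(self.behaviours) - set(BEHAVIOURS)
        if unknown:
            raise ValueError(f"unknown behaviours: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.starts)

    def validate_tiling(self, duration_s: float, tol: float = 1e-9) -> None:
        """Raise unless the intervals tile [0, duration_s] without gaps or overlaps."""
        order = np.argsort(self.starts, kind="stable")
        starts, ends = self.starts[order], self.ends[order]
        if abs(starts[0]) > tol or abs(ends[-1] - duration_s) > tol:
            raise ValueError("intervals do not span [0, duration]")
        gaps = starts[1:] - ends[:-1]
        if np.any(np.abs(gaps) > tol):
            raise ValueError("intervals have gaps or overlaps")

    def label_at(self, times: np.ndarray) -> np.ndarray:
        """Behaviour label for each time under the half-open [start, end) rule."""
        times = np.asarray(times, dtype=float)
        order = np.argsort(self.starts, kind="stable")
        starts = self.starts[order]
        ends = self.ends[order]
        labels = np.asarray(self.behaviours, dtype=object)[order]
        idx = np.searchsorted(starts, times, side="right") - 1
        if np.any(idx < 0) or np.any(times >= ends[np.clip(idx, 0, None)]):
            raise ValueError("some times fall outside every labelled interval")
        return labels[idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"start_s": self.starts, "end_s": self.ends,
             "behaviour": self.behaviours}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "LabelTrack":
        df = pd.read_csv(path)
        missing = set(LABEL_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"label CSV missing columns: {sorted(missing)}")
        return cls(df["start_s"].to_numpy(), df["end_s"].to_numpy(),
                   df["behaviour"].tolist())


@dataclass
class ChannelSet:
    """The four derived channels: magnitudes and their rates of change."""

    A: np.ndarray
    G: np.ndarray
    AD: np.ndarray
    GD: np.ndarray
    sampling_rate_hz: float = 16.0

    STREAMS = ("A", "AD", "G", "GD")

    def __post_init__(self) -> None:
        n = len(self.A)
        if any(len(getattr(self, s)) != n for s in self.STREAMS):
            raise ValueError("all four channels must have equal length")

    def __len__(self) -> int:
        return len(self.A)


@dataclass
class Window:
    """One fixed-length labelled slice of the four channels."""

    channels: dict  # stream name -> 1-d array of window length
    label: str
    is_mixed: bool
    start_index: int


@dataclass
class WindowSet:
    windows: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)

    @property
    def mixed_ratio(self) -> float:
        if not self.windows:
            raise ValueError("empty WindowSet has no mixed ratio")
        return sum(w.is_mixed for w in self.windows) / len(self.windows)

    @property
    def labels(self) -> list[str]:
        return [w.label for w in self.windows]

    def metadata_frame(self, sampling_rate_hz: float = 16.0) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "window": range(len(self.windows)),
                "start_s": [w.start_index / sampling_rate_hz for w in self.windows],
                "label": [w.label for w in self.windows],
                "is_mixed": [w.is_mixed for w in self.windows],
            }
        )


def magnitude(x, y, z):
    """Euclidean norm sqrt(x^2 + y^2 + z^2), elementwise on arrays."""
    return np.sqrt(np.square(x) + np.square(y) + np.square(z))


def rate_of_change(series, sampling_rate_hz: float):
    """Time derivative of a uniformly sampled series, same length as the input.

    Central differences on interior points, one-sided at the two ends
    (``numpy.gradient`` semantics), scaled by the sampling rate so values
    are in units-per-second.
    """
    series = np.asarray(series, dtype=float)
    if series.size < 2:
        raise ValueError("rate_of_change requires at least 2 samples")
    return np.gradient(series, 1.0 / sampling_rate_hz)


def build_channels(stream: SensorStream) -> ChannelSet:
    """Compute A, G magnitudes and their rates of change AD, GD."""
    A = magnitude(stream.ax, stream.ay, stream.az)
    G = magnitude(stream.gx, stream.gy, stream.gz)
    return ChannelSet(
        A=A, G=G,
        AD=rate_of_change(A, stream.sampling_rate_hz),
        GD=rate_of_change(G, stream.sampling_rate_hz),
        sampling_rate_hz=stream.sampling_rate_hz,
    )


def window_count(n_samples: int, length: int, hop: int) -> int:
    """Number of full windows of `length` at stride `hop` in `n_samples`."""
    if n_samples < length:
        return 0
    return (n_samples - length) // hop + 1


def _majority_label(sample_labels: np.ndarray) -> tuple[str, bool]:
    """Predominant label of a window; ties go to the first sample's label."""
    uniq, counts = np.unique(sample_labels, return_counts=True)
    if len(uniq) == 1:
        return str(uniq[0]), False
    best = counts.max()
    winners = set(uniq[counts == best])
    if len(winners) > 1:
        for lab in sample_labels:
            if lab in winners:
                return str(lab), True
    return str(uniq[np.argmax(counts)]), True


def discretise(channels: ChannelSet, track: LabelTrack,
               window_s: float = 7.0, overlap: float = 0.5,
               timestamps: np.ndarray | None = None) -> WindowSet:
    """Cut the four channels into labelled fixed-length overlapping windows.

    Window length is ``round(window_s * fs)`` samples and the hop
    ``round(length * (1 - overlap))``; trailing samples that do not fill a
    window are dropped. A window whose samples all carry one behaviour gets
    that label; otherwise it is flagged mixed and labelled by its
    predominant sample label.
    """
    fs = channels.sampling_rate_hz
    length = int(round(window_s * fs))
    if length < 2:
        raise ValueError("window length must be at least 2 samples")
    if not (0 <= overlap < 1):
        raise ValueError("overlap must lie in [0, 1)")
    hop = int(round(length * (1 - overlap)))
    if hop < 1:
        raise ValueError("overlap leaves an empty hop")

    n = len(channels)
    if timestamps is None:
        timestamps = np.arange(n) / fs
    sample_labels = track.label_at(timestamps)

    windows = []
    for k in range(window_count(n, length, hop)):
        start = k * hop
        sl = slice(start, start + length)
        label, mixed = _majority_label(sample_labels[sl])
        windows.append(
            Window(
                channels={s: getattr(channels, s)[sl] for s in ChannelSet.STREAMS},
                label=label, is_mixed=mixed, start_index=start,
            )
        )
    return WindowSet(windows)


def mixed_ratio_report(ws: WindowSet) -> dict:
    """Percentages of mixed and non-mixed windows; the two sum to 100."""
    r = ws.mixed_ratio  # raises on empty
    return {"mixed": 100.0 * r, "non_mixed": 100.0 * (1.0 - r)}
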