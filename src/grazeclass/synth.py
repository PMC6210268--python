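"""Synthetic labelled IMU streams for sheep eating-behaviour analysis.

Generates 16 Hz tri-axial accelerometer + gyroscope streams in which each
behaviour bout follows a simple regime: a bout-constant orientation offset
plus a behaviour-specific sinusoid plus white noise, on both sensors. The
defaults encode the qualitative structure reported for grazing sheep —
ruminating has the lowest overall accelerometer magnitude, non-eating
activities the highest, and each behaviour has a distinct rhythm (grazing
~1.5 Hz biting, ruminating ~1.0 Hz chewing, non-eating broadband) — so that
magnitude, frequency and entropy features are all behaviourally informative.

Units are arbitrary (g-like for acceleration, rad/s-like for angular rate);
the downstream pipeline is unit-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .preprocess import BEHAVIOURS, LabelTrack, SensorStream

NYQUIST_HZ = 8.0  # at the 16 Hz default sampling rate


@dataclass
class BehaviourRegime:
    """Signal regime for one behaviour.

    Parameters
    ----------
    behaviour : one of ``grazing``, ``ruminating``, ``non-eating``.
    base_magnitude : bout-constant accelerometer magnitude offset (>= 0).
    oscillation_freq_hz : rhythm frequency in (0, Nyquist).
    oscillation_amp : sinusoid amplitude (>= 0).
    noise_sd : white-noise standard deviation (>= 0).
    gyro_scale : angular-rate analogue scaling of the oscillation/noise.
    """

    behaviour: str
    base_magnitude: float
    oscillation_freq_hz: float
    oscillation_amp: float
    noise_sd: float
    gyro_scale: float

    def __post_init__(self) -> None:
        if self.behaviour not in BEHAVIOURS:
            raise ValueError(f"invalid field 'behaviour': {self.behaviour!r}")
        for name in ("base_magnitude", "oscillation_amp", "noise_sd", "gyro_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"invalid field {name!r}: must be >= 0")
        if not (0 < self.oscillation_freq_hz < NYQUIST_HZ):
            raise ValueError(
                "invalid field 'oscillation_freq_hz': must lie in "
                f"(0, {NYQUIST_HZ}) Hz"
            )


def default_regimes(placement: str = "collar") -> dict[str, BehaviourRegime]:
    """Shipped regimes satisfying the accelerometer-magnitude ordering
    ruminating < grazing < non-eating.

    Ear placement is more rotational than collar, so it only raises the
    gyroscope scale; nothing else differs between placements.
    """
    gyro_boost = 1.5 if placement == "ear" else 1.0
    return {
        "ruminating": BehaviourRegime(
            "ruminating", base_magnitude=0.9, oscillation_freq_hz=1.0,
            oscillation_amp=0.15, noise_sd=0.05, gyro_scale=0.5 * gyro_boost),
        "grazing": BehaviourRegime(
            "grazing", base_magnitude=1.4, oscillation_freq_hz=1.5,
            oscillation_amp=0.40, noise_sd=0.10, gyro_scale=1.0 * gyro_boost),
        "non-eating": BehaviourRegime(
            "non-eating", base_magnitude=2.1, oscillation_freq_hz=3.0,
            oscillation_amp=0.20, noise_sd=0.35, gyro_scale=0.7 * gyro_boost),
    }


@dataclass
class TrialConfig:
    """One synthetic recording trial."""

    duration_s: float = 600.0
    sampling_rate_hz: float = 16.0
    bout_length_s: tuple[float, float] = (20.0, 40.0)
    regimes: dict = field(default_factory=default_regimes)
    placement: str = "collar"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("invalid field 'duration_s': must be > 0")
        lo, hi = self.bout_length_s
        if not (0 < lo <= hi):
            raise ValueError("invalid field 'bout_length_s': need 0 < min <= max")
        if lo < 7.0:
            raise ValueError(
                "invalid field 'bout_length_s': minimum bout must be >= the "
                "7 s window so non-mixed windows dominate"
            )
        if set(self.regimes) != set(BEHAVIOURS):
            raise ValueError(
                "invalid field 'regimes': need exactly one regime per behaviour"
            )
        if self.placement not in ("ear", "collar"):
            raise ValueError(f"invalid field 'placement': {self.placement!r}")

    def to_yaml(self, path) -> None:
        doc = asdict(self)
        doc["bout_length_s"] = list(self.bout_length_s)
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "TrialConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        regimes = {
            k: BehaviourRegime(**v) for k, v in doc.get("regimes", {}).items()
        } or default_regimes(doc.get("placement", "collar"))
        return cls(
            duration_s=doc.get("duration_s", 600.0),
            sampling_rate_hz=doc.get("sampling_rate_hz", 16.0),
            bout_length_s=tuple(doc.get("bout_length_s", (20.0, 40.0))),
            regimes=regimes,
            placement=doc.get("placement", "collar"),
            seed=doc.get("seed", 0),
        )


def _bout_schedule(cfg: TrialConfig, rng: np.random.Generator):
    """Tile [0, duration] with behaviour bouts.

    Behaviours follow shuffled round-robin triples (adjacent bouts always
    differ) so the three classes stay roughly balanced over long trials.
    """
    starts, ends, labels = [], [], []
    t = 0.0
    lo, hi = cfg.bout_length_s
    cycle: list[str] = []
    while t < cfg.duration_s - 1e-12:
        if not cycle:
            cycle = list(BEHAVIOURS)
            rng.shuffle(cycle)
            if labels and cycle[0] == labels[-1]:
                cycle[0], cycle[-1] = cycle[-1], cycle[0]
        length = rng.uniform(lo, hi)
        end = min(t + length, cfg.duration_s)
        # never leave a terminal sliver shorter than the minimum bout
        if cfg.duration_s - end < lo:
            end = cfg.duration_s
        starts.append(t)
        ends.append(end)
        labels.append(cycle.pop(0))
        t = end
    return np.array(starts), np.array(ends), labels


def generate_trial(config: TrialConfig) -> tuple[SensorStream, LabelTrack]:
    """Generate one labelled trial; identical config+seed gives identical output.

    Per axis and bout: a fixed orientation offset (a random unit vector
    scaled by the regime's base magnitude for the accelerometer), a
    sinusoid along a random bout-constant direction, and white noise. The
    gyroscope carries the same oscillation/noise structure scaled by
    ``gyro_scale``, with no gravity-like offset.
    """
    rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate_hz
    n = int(round(config.duration_s * fs))
    t = np.arange(n) / fs

    starts, ends, labels = _bout_schedule(config, rng)
    track = LabelTrack(starts, ends, labels)

    acc = np.zeros((3, n))
    gyr = np.zeros((3, n))
    for s, e, lab in zip(starts, ends, labels):
        reg = config.regimes[lab]
        mask = (t >= s) & (t < e)
        m = int(mask.sum())
        if m == 0:
            continue
        ori = rng.normal(size=3)
        ori /= np.linalg.norm(ori)
        osc_dir = rng.normal(size=3)
        osc_dir /= np.linalg.norm(osc_dir)
        phase = rng.uniform(0, 2 * np.pi)
        osc = np.sin(2 * np.pi * reg.oscillation_freq_hz * t[mask] + phase)
        for ax in range(3):
            acc[ax, mask] = (
                reg.base_magnitude * ori[ax]
                + reg.oscillation_amp * osc_dir[ax] * osc
                + rng.normal(0.0, reg.noise_sd, m)
            )
            gyr[ax, mask] = reg.gyro_scale * (
                osc_dir[ax] * osc + rng.normal(0.0, reg.noise_sd, m)
            )

    stream = SensorStream(
        timestamps=t, ax=acc[0], ay=acc[1], az=acc[2],
        gx=gyr[0], gy=gyr[1], gz=gyr[2],
        sampling_rate_hz=fs, placement=config.placement,
    )
    return stream, track


def label_coverage(track: LabelTrack, duration_s: float) -> dict[str, float]:
    """Fraction of the trial spent in each behaviour; fractions sum to 1."""
    track.validate_tiling(duration_s)
    cover: dict[str, float] = {}
    for s, e, lab in zip(track.starts, track.ends, track.behaviours):
        cover[lab] = cover.get(lab, 0.0) + (e - s) / duration_s
    return cover
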