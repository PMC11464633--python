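"""Shared domain types for session-based electrophysiology analysis.

A recording session consists of three consecutive periods — a resting
baseline (PRE), the music-therapy intervention (MTI), and a
post-intervention reincorporation (POST) — during which up to three
modalities are acquired simultaneously: an 8-channel 10-20 EEG (Fp1,
Fp2, T3, T4, C3, C4, O1, O2 referenced to Cz), a single bipolar ECG
lead, and a bipolar facial EMG over the corrugator supercilii.

Time is represented in seconds with half-open intervals ``[start, end)``.
Sample indices are 0-based; an interval maps to the sample range
``[floor(start * fs), floor(end * fs))``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

__all__ = [
    "Modality",
    "Recording",
    "Interval",
    "PeriodSegmentation",
    "BandScheme",
    "EpochSet",
    "SpectralEstimate",
    "SessionRecord",
    "central_window",
    "make_epochs",
    "EEG_CHANNELS",
    "DEFAULT_BANDS",
    "PERIODS",
    "InvalidSegmentationError",
    "TooShortError",
]

#: canonical EEG montage of the study (10-20 subset, reference Cz)
EEG_CHANNELS = ("Fp1", "Fp2", "T3", "T4", "C3", "C4", "O1", "O2")

#: period labels in temporal order
PERIODS = ("PRE", "MTI", "POST")


class Modality(str, Enum):
    EEG = "EEG"
    ECG = "ECG"
    EMG = "EMG"


class InvalidSegmentationError(ValueError):
    """Period annotations missing, empty, unordered, or out of range."""


class TooShortError(ValueError):
    """Segment shorter than a single epoch."""


Interval = tuple[float, float]


def _check_interval(iv: Interval, name: str = "interval") -> None:
    start, end = iv
    if not (math.isfinite(start) and math.isfinite(end)):
        raise InvalidSegmentationError(f"{name} has non-finite bounds: {iv}")
    if not end > start:
        raise InvalidSegmentationError(f"{name} is empty: {iv}")


@dataclass(frozen=True)
class Recording:
    """One modality's uniformly sampled multichannel signal.

    ``data`` is channels x samples, in microvolts for EEG/EMG and
    millivolts for ECG.  ``annotations`` is a list of
    ``(onset_s, duration_s, label)`` tuples; period boundaries are read
    from annotations labelled PRE/MTI/POST (case-insensitive).
    """

    modality: Modality
    channel_labels: tuple[str, ...]
    sampling_rate: float
    data: np.ndarray
    annotations: tuple[tuple[float, float, str], ...] = ()

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "channel_labels", tuple(self.channel_labels))
        object.__setattr__(self, "annotations", tuple(self.annotations))
        object.__setattr__(self, "modality", Modality(self.modality))
        if data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if data.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"{data.shape[0]} data rows but {len(self.channel_labels)} channel labels"
            )
        if not np.all(np.isfinite(data)):
            raise ValueError("data contains NaN/inf")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.modality in (Modality.EEG, Modality.ECG) and self.sampling_rate < 256:
            raise ValueError(
                f"{self.modality.value} requires sampling_rate >= 256 Hz, "
                f"got {self.sampling_rate}"
            )
        if self.modality is Modality.EEG:
            unknown = set(self.channel_labels) - set(EEG_CHANNELS)
            if unknown:
                raise ValueError(f"unknown EEG channels: {sorted(unknown)}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def emg_analysis_eligible(self) -> bool:
        """EMG frequency analysis needs fs >= 512 Hz (200 Hz content, Nyquist)."""
        return self.modality is not Modality.EMG or self.sampling_rate >= 512

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.channel_labels.index(label)]

    def sample_slice(self, interval: Interval) -> slice:
        """Sample range of a half-open time interval (floor both edges)."""
        start, end = interval
        return slice(int(math.floor(start * self.sampling_rate)),
                     int(math.floor(end * self.sampling_rate)))

    def extract(self, interval: Interval) -> np.ndarray:
        return self.data[:, self.sample_slice(interval)]


@dataclass(frozen=True)
class PeriodSegmentation:
    """PRE/MTI/POST boundaries of a session as half-open intervals [s, s)."""

    pre: Interval
    mti: Interval
    post: Interval

    def __post_init__(self):
        for name, iv in zip(PERIODS, (self.pre, self.mti, self.post)):
            _check_interval(iv, name)
        if not (self.pre[1] <= self.mti[0] and self.mti[1] <= self.post[0]):
            raise InvalidSegmentationError(
                f"periods must be ordered and non-overlapping: "
                f"PRE={self.pre}, MTI={self.mti}, POST={self.post}"
            )

    def __getitem__(self, period: str) -> Interval:
        return {"PRE": self.pre, "MTI": self.mti, "POST": self.post}[period.upper()]

    @property
    def end(self) -> float:
        return self.post[1]

    def check_within(self, duration: float) -> None:
        if self.post[1] > duration + 1e-9:
            raise InvalidSegmentationError(
                f"segmentation extends to {self.post[1]:.3f} s but recording "
                f"lasts {duration:.3f} s"
            )

    @classmethod
    def from_annotations(
        cls,
        annotations: Sequence[tuple[float, float, str]],
        label_map: dict[str, str] | None = None,
    ) -> "PeriodSegmentation":
        """Build from (onset, duration, label) annotations.

        ``label_map`` maps dataset-specific labels to PRE/MTI/POST;
        matching is case-insensitive.  Absent labels are an error rather
        than being inferred.
        """
        mapping = {k.upper(): v.upper() for k, v in (label_map or {}).items()}
        found: dict[str, Interval] = {}
        for onset, dur, label in annotations:
            key = mapping.get(str(label).upper(), str(label).upper())
            if key in PERIODS:
                found[key] = (float(onset), float(onset) + float(dur))
        missing = [p for p in PERIODS if p not in found]
        if missing:
            raise InvalidSegmentationError(f"missing period annotations: {missing}")
        return cls(pre=found["PRE"], mti=found["MTI"], post=found["POST"])


@dataclass(frozen=True)
class BandScheme:
    """Ordered, contiguous, non-overlapping frequency bands covering 1-30 Hz."""

    bands: tuple[tuple[str, float, float], ...] = (
        ("Delta", 1.0, 4.0),
        ("Theta", 4.0, 8.0),
        ("Alpha", 8.0, 12.0),
        ("SlowBeta", 12.0, 18.0),
        ("FastBeta", 18.0, 30.0),
    )

    def __post_init__(self):
        object.__setattr__(self, "bands", tuple(tuple(b) for b in self.bands))
        prev_high = None
        for name, low, high in self.bands:
            if not low < high:
                raise ValueError(f"band {name}: low must be < high")
            if prev_high is not None and low != prev_high:
                raise ValueError(f"bands must be contiguous; gap/overlap before {name}")
            prev_high = high

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(b[0] for b in self.bands)

    @property
    def full_range(self) -> Interval:
        return (self.bands[0][1], self.bands[-1][2])

    def limits(self, name: str) -> Interval:
        for n, lo, hi in self.bands:
            if n == name:
                return (lo, hi)
        raise KeyError(name)


DEFAULT_BANDS = BandScheme()


@dataclass(frozen=True)
class EpochSet:
    """Sliding-window epoching of a source segment (offsets in seconds)."""

    epoch_length: float
    overlap: float
    offsets: tuple[float, ...]

    def __post_init__(self):
        if not self.epoch_length > self.overlap >= 0:
            raise ValueError("need epoch_length > overlap >= 0")
        offs = np.asarray(self.offsets, float)
        if len(offs) and np.any(np.diff(offs) <= 0):
            raise ValueError("offsets must be strictly increasing")
        object.__setattr__(self, "offsets", tuple(float(o) for o in offs))

    @property
    def step(self) -> float:
        return self.epoch_length - self.overlap

    def __len__(self) -> int:
        return len(self.offsets)


def central_window(interval: Interval, target_minutes: float) -> Interval:
    """Centered sub-interval of ``target_minutes``; shorter periods pass whole.

    Periods shorter than the target are used in their entirety (the
    session schedule in an ICU is dynamic and periods frequently run
    short); longer periods are trimmed symmetrically, any sub-sample
    remainder going to the right edge.
    """
    _check_interval(interval)
    if target_minutes <= 0:
        raise ValueError("target_minutes must be > 0")
    start, end = float(interval[0]), float(interval[1])
    target = target_minutes * 60.0
    duration = end - start
    if duration <= target:
        return (start, end)
    new_start = start + (duration - target) / 2.0
    return (new_start, new_start + target)


def make_epochs(segment_duration: float, epoch_length: float, overlap: float) -> EpochSet:
    """Sliding-window offsets 0, step, 2*step, ... fully inside the segment.

    A trailing remainder shorter than one epoch is discarded.
    """
    if not epoch_length > overlap >= 0:
        raise ValueError("need epoch_length > overlap >= 0")
    if segment_duration < epoch_length:
        raise TooShortError(
            f"segment of {segment_duration} s shorter than one {epoch_length}-s epoch"
        )
    step = epoch_length - overlap
    # 1e-9 slack so an epoch landing exactly on the segment end is kept
    n = int(math.floor((segment_duration - epoch_length) / step + 1e-9)) + 1
    offsets = tuple(i * step for i in range(n))
    return EpochSet(epoch_length=epoch_length, overlap=overlap, offsets=offsets)


@dataclass(frozen=True)
class SpectralEstimate:
    """One-sided power spectral density on a uniform frequency grid."""

    frequencies: np.ndarray
    density: np.ndarray

    def __post_init__(self):
        f = np.asarray(self.frequencies, float)
        d = np.asarray(self.density, float)
        if f.shape != d.shape or f.ndim != 1:
            raise ValueError("frequencies and density must be 1-D of equal length")
        if len(f) >= 2:
            df = np.diff(f)
            if np.any(df <= 0):
                raise ValueError("frequency grid must be strictly increasing")
            if not np.allclose(df, df[0], rtol=1e-6):
                raise ValueError("frequency grid must be uniform")
        if np.any(d < 0) or not np.all(np.isfinite(d)):
            raise ValueError("density must be finite and non-negative")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "density", d)


@dataclass
class SessionRecord:
    """One patient-session: recordings by modality plus its segmentation."""

    patient_id: str
    session: int
    recordings: dict[Modality, Recording]
    segmentation: PeriodSegmentation
    clinical: object | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        self.recordings = {Modality(k): v for k, v in self.recordings.items()}
        if not self.recordings:
            raise ValueError("session must contain at least one modality")
        for rec in self.recordings.values():
            self.segmentation.check_within(rec.duration)

    def get(self, modality: Modality | str) -> Recording | None:
        return self.recordings.get(Modality(modality))
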