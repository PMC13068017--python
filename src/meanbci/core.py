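"""Core in-memory containers: single-channel signals, multichannel recordings,
state markers and per-state segment sets.

These are deliberately thin: heavy lifting lives in the processing modules, and
persistent storage is handled by :mod:`meanbci.container`.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

STATE_ORDER: tuple[str, ...] = ("high", "medium", "low")

#: Fixed channel order of the fused feature map: 11 EEG, vertical EOG,
#: horizontal EOG, ECG, pulse.  EEG names follow the 10-10 montage used for
#: frontal/central/temporal/parietal coverage.
EEG_CHANNEL_NAMES: tuple[str, ...] = (
    "F3", "Fz", "F4", "C3", "Cz", "C4", "T7", "T8", "P3", "Pz", "P4",
)
FUSED_CHANNEL_NAMES: tuple[str, ...] = EEG_CHANNEL_NAMES + ("vEOG", "hEOG", "ECG", "Pulse")


class MeanBciError(Exception):
    """Base class for package errors."""


class ConfigError(MeanBciError):
    """Invalid configuration or parameters."""


class DataError(MeanBciError):
    """Structurally invalid or degenerate input data."""


@dataclass
class Signal:
    """A single-channel, uniformly sampled real signal."""

    samples: np.ndarray
    fs: float
    channel_name: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise DataError("Signal requires a non-empty 1-D sample array")
        if not np.all(np.isfinite(self.samples)):
            raise DataError(f"Signal {self.channel_name!r} contains non-finite samples")
        if self.fs <= 0:
            raise ConfigError("sampling rate must be positive")

    @property
    def n(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.n / self.fs

    def copy_with(self, samples: np.ndarray, **kw) -> "Signal":
        return replace(self, samples=np.asarray(samples, dtype=float), **kw)


@dataclass
class StateMarker:
    """Labels one contiguous span of a recording with an attention state."""

    label: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.label not in STATE_ORDER:
            raise DataError(f"unknown state label {self.label!r}")
        if not self.end_s > self.start_s:
            raise DataError(f"marker for {self.label!r} has non-positive duration")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class Modality:
    """One recorded modality: channels x samples at a single rate."""

    data: np.ndarray  # (n_channels, n_samples)
    fs: float
    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.shape[0] != len(self.channel_names):
            raise DataError(
                f"{self.data.shape[0]} rows but {len(self.channel_names)} channel names"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel(self, name: str) -> Signal:
        idx = self.channel_names.index(name)
        return Signal(self.data[idx], self.fs, name)


@dataclass
class Recording:
    """A labeled multimodal recording for one subject/session.

    ``modalities`` maps a modality key (``eeg``, ``eog_raw`` or ``eog``,
    ``ecg``, ``pulse``, ``spo2``, ``hr``) to a :class:`Modality`; each modality
    keeps its native sampling rate.  ``markers`` delimit the high / medium /
    low attention spans in seconds (rate independent).
    """

    modalities: dict[str, Modality]
    markers: list[StateMarker]
    subject_id: str = "synthetic"
    meta: dict = field(default_factory=dict)

    def require(self, key: str) -> Modality:
        if key not in self.modalities:
            raise DataError(f"recording is missing modality {key!r}")
        return self.modalities[key]


@dataclass
class Segment:
    """One trimmed, single-state slice of a recording."""

    label: str
    modalities: dict[str, Modality]
    start_s: float
    duration_s: float


@dataclass
class SegmentSet:
    """One segment per attention state, non-overlapping in source time."""

    segments: list[Segment]
    nominal_duration_s: float

    def __post_init__(self) -> None:
        labels = [s.label for s in self.segments]
        if sorted(labels) != sorted(set(labels)):
            raise DataError("duplicate state labels in segment set")
        # pairwise non-overlap in source time
        spans = sorted((s.start_s, s.start_s + s.duration_s) for s in self.segments)
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            if b0 < a1:
                raise DataError("segments overlap in source time")

    def labels(self) -> list[str]:
        return [s.label for s in self.segments]

    def __getitem__(self, label: str) -> Segment:
        for s in self.segments:
            if s.label == label:
                return s
        raise KeyError(label)
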