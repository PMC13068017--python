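"""Time-frequency features: Blackman-window STFT log-power spectrograms,
1/3 Hz frequency compression below 30 Hz, temporal smoothing, band-power
ratios and assembly into fused per-frame feature instances.

With the defaults (9 s window, 1 s step at 200 Hz) each channel yields 90
compressed frequency bins per frame plus three engagement ratios
(beta/alpha, beta/theta, beta/(alpha+theta)); 15 channels give a 15 x 93
map, and the two auxiliary scalars (SpO2, heart rate) bring each instance to
15 x 93 + 2 = 1397 features.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .bands import BAND_EDGES_HZ
from .core import ConfigError, DataError, FUSED_CHANNEL_NAMES, SegmentSet, Signal

__all__ = [
    "WindowSpec",
    "SpectrogramTensor",
    "FeatureSet",
    "blackman",
    "stft_logpower",
    "bin_and_smooth",
    "band_ratios",
    "assemble_instances",
    "featurize_segments",
]

EPS = 1e-12


def blackman(width: int) -> np.ndarray:
    """Blackman taper w(t) = 0.42 - 0.5 cos(2πt/(W-1)) + 0.08 cos(4πt/(W-1))."""
    if width < 3:
        raise ConfigError("Blackman window needs width >= 3")
    t = np.arange(width)
    return 0.42 - 0.5 * np.cos(2 * np.pi * t / (width - 1)) + 0.08 * np.cos(
        4 * np.pi * t / (width - 1)
    )


@dataclass(frozen=True)
class WindowSpec:
    """STFT framing: window width, hop, and the implied raw bin spacing."""

    width_s: float = 9.0
    step_s: float = 1.0

    def __post_init__(self) -> None:
        if not self.width_s > self.step_s > 0:
            raise ConfigError("require width_s > step_s > 0")

    @property
    def overlap_fraction(self) -> float:
        return (self.width_s - self.step_s) / self.width_s

    def width_samples(self, fs: float) -> int:
        return int(round(self.width_s * fs))

    def step_samples(self, fs: float) -> int:
        return int(round(self.step_s * fs))


def stft_logpower(
    data: np.ndarray | Signal,
    fs: float | None = None,
    win: WindowSpec | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Log power spectrogram of one or more channels.

    Returns ``(logpower, frame_times, raw_freqs)`` where ``logpower`` has
    shape (frames, raw_bins, channels); ``frame_times`` are window-start
    times.  Frames = floor((N - width) / step) + 1.
    """
    win = win or WindowSpec()
    if isinstance(data, Signal):
        fs = data.fs
        x = data.samples[np.newaxis, :]
    else:
        if fs is None:
            raise ConfigError("fs is required for array input")
        x = np.atleast_2d(np.asarray(data, dtype=float))
    width = win.width_samples(fs)
    step = win.step_samples(fs)
    if x.shape[-1] < width:
        raise DataError(
            f"signal of {x.shape[-1]} samples is shorter than the {width}-sample window"
        )
    taper = blackman(width)
    frames = sliding_window_view(x, width, axis=-1)[:, ::step, :]  # (ch, frames, width)
    spec = np.fft.rfft(frames * taper, axis=-1)
    logp = np.log(np.abs(spec) ** 2 + EPS)
    n_frames = logp.shape[1]
    frame_times = np.arange(n_frames) * step / fs
    raw_freqs = np.fft.rfftfreq(width, d=1.0 / fs)
    return np.transpose(logp, (1, 2, 0)), frame_times, raw_freqs


@dataclass
class SpectrogramTensor:
    """Compressed log-power tensor [time frame, frequency bin, channel]."""

    values: np.ndarray
    bin_centers_hz: np.ndarray
    frame_times: np.ndarray
    channel_names: tuple[str, ...]
    bin_width_hz: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise DataError("spectrogram contains non-finite values")

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]


def bin_and_smooth(
    logpower: np.ndarray,
    raw_freqs: np.ndarray,
    frame_times: np.ndarray,
    channel_names: tuple[str, ...],
    bin_width_hz: float = 1.0 / 3.0,
    f_max_hz: float = 30.0,
    smooth_frames: int = 3,
) -> SpectrogramTensor:
    """Compress raw bins into ``bin_width_hz`` groups below ``f_max_hz`` and
    smooth along time.

    Grouping sums adjacent *linear* power bins (the log is re-applied after
    summation); the DC bin is excluded, so bin centers lie in (0, f_max).
    Temporal smoothing is a centered moving average with edge truncation.
    """
    raw_df = raw_freqs[1] - raw_freqs[0]
    group = bin_width_hz / raw_df
    group_n = int(round(group))
    if abs(group - group_n) > 1e-6 or group_n < 1:
        nearest = max(group_n, 1) * raw_df
        raise ConfigError(
            f"bin width {bin_width_hz:g} Hz is not a multiple of the raw spacing "
            f"{raw_df:g} Hz; nearest compatible width is {nearest:g} Hz"
        )
    power = np.exp(logpower)  # undo log for physically meaningful summation
    n_groups_avail = (power.shape[1] - 1) // group_n
    centers = np.array(
        [(raw_freqs[1 + g * group_n] + raw_freqs[(g + 1) * group_n]) / 2.0
         for g in range(n_groups_avail)]
    )
    keep = centers < f_max_hz
    n_groups = int(np.sum(keep))
    if n_groups == 0:
        raise ConfigError("no frequency bins below f_max_hz")
    grouped = power[:, 1 : 1 + n_groups * group_n, :]
    grouped = grouped.reshape(power.shape[0], n_groups, group_n, power.shape[2]).sum(axis=2)
    out = np.log(grouped + EPS)

    if smooth_frames > 1:
        kernel = np.ones(smooth_frames)
        # centered moving average with edge truncation
        num = np.apply_along_axis(
            lambda v: np.convolve(v, kernel, mode="same"), 0, out
        )
        den = np.convolve(np.ones(out.shape[0]), kernel, mode="same")
        out = num / den[:, np.newaxis, np.newaxis]

    return SpectrogramTensor(
        values=out,
        bin_centers_hz=centers[keep],
        frame_times=frame_times,
        channel_names=channel_names,
        bin_width_hz=bin_width_hz,
    )


def band_ratios(
    tensor: SpectrogramTensor,
    band_edges: dict[str, tuple[float, float]] | None = None,
) -> np.ndarray:
    """Per-frame, per-channel (beta/alpha, beta/theta, beta/(alpha+theta)).

    Band power is the sum of linear-power bins whose centers fall inside the
    band.  Returns an array of shape (frames, channels, 3).
    """
    edges = band_edges or BAND_EDGES_HZ
    power = np.exp(tensor.values)  # (frames, bins, channels)
    bp = {}
    for name, (lo, hi) in edges.items():
        sel = (tensor.bin_centers_hz >= lo) & (tensor.bin_centers_hz < hi)
        if not np.any(sel):
            raise ConfigError(f"band {name!r} [{lo}, {hi}) Hz contains no bins")
        bp[name] = power[:, sel, :].sum(axis=1)  # (frames, channels)
    b, a, t = bp["beta"], bp["alpha"], bp["theta"]
    ratios = np.stack(
        [b / (a + EPS), b / (t + EPS), b / (a + t + EPS)], axis=-1
    )
    return ratios


RATIO_NAMES = ("beta/alpha", "beta/theta", "beta/(alpha+theta)")


@dataclass
class FeatureSet:
    """Per-frame classification instances for one subject.

    ``freq_maps`` holds the channel x (bins + ratios) matrices, ``scalars``
    the (SpO2, HR) pair; flattened width is n_channels x 93 + 2 (1397 at the
    default 15-channel layout).
    """

    freq_maps: np.ndarray  # (n, channels, 93)
    scalars: np.ndarray  # (n, 2)
    labels: np.ndarray  # (n,) strings
    frame_times: np.ndarray  # (n,) seconds in source time
    channel_names: tuple[str, ...]
    column_names: tuple[str, ...]
    subject_id: str = "synthetic"

    def __post_init__(self) -> None:
        n = self.freq_maps.shape[0]
        if not (self.scalars.shape == (n, 2) and self.labels.shape[0] == n):
            raise DataError("inconsistent instance counts across fields")

    @property
    def n_instances(self) -> int:
        return self.freq_maps.shape[0]

    @property
    def n_features(self) -> int:
        return self.freq_maps.shape[1] * self.freq_maps.shape[2] + self.scalars.shape[1]

    def flattened(self) -> np.ndarray:
        return np.concatenate(
            [self.freq_maps.reshape(self.n_instances, -1), self.scalars], axis=1
        )

    def select_channels(self, names: list[str], keep_scalars: bool = True) -> "FeatureSet":
        """Reduced copy with only the named channels (modality ablation)."""
        idx = [self.channel_names.index(n) for n in names]
        scal = self.scalars if keep_scalars else np.zeros((self.n_instances, 0))
        fs = FeatureSet.__new__(FeatureSet)
        fs.freq_maps = self.freq_maps[:, idx, :]
        fs.scalars = scal
        fs.labels = self.labels
        fs.frame_times = self.frame_times
        fs.channel_names = tuple(names)
        fs.column_names = self.column_names
        fs.subject_id = self.subject_id
        return fs


def assemble_instances(
    tensors: dict[str, SpectrogramTensor],
    ratios: dict[str, np.ndarray],
    spo2: Signal,
    hr: Signal,
    label: str,
    frame_offset_s: float = 0.0,
    win: WindowSpec | None = None,
    expected_channel_order: tuple[str, ...] | None = None,
    subject_id: str = "synthetic",
) -> FeatureSet:
    """Fuse per-modality spectrogram tensors into labeled instances.

    ``tensors``/``ratios`` are keyed by modality in the fixed order
    eeg, eog, ecg, pulse; channel concatenation must reproduce the canonical
    fused order (11 EEG, vEOG, hEOG, ECG, pulse) or an error is raised rather
    than silently reordering.  Scalars are window means of SpO2 and HR.
    """
    win = win or WindowSpec()
    required = ("eeg", "eog", "ecg", "pulse")
    for key in required:
        if key not in tensors:
            raise DataError(f"missing modality {key!r} in feature assembly")
        if key not in ratios:
            raise DataError(f"missing ratios for modality {key!r}")

    ref_times = tensors[required[0]].frame_times
    for key in required[1:]:
        if tensors[key].values.shape[0] != ref_times.shape[0] or not np.allclose(
            tensors[key].frame_times, ref_times
        ):
            raise DataError(f"modality {key!r} is not on the shared frame grid")

    channel_names = tuple(
        name for key in required for name in tensors[key].channel_names
    )
    expected = expected_channel_order or (
        FUSED_CHANNEL_NAMES if len(channel_names) == len(FUSED_CHANNEL_NAMES) else None
    )
    if expected is not None and channel_names != tuple(expected):
        raise DataError(
            f"channel order {channel_names} does not match the expected order {tuple(expected)}"
        )

    # (frames, channels, bins) per modality, concatenated along channels
    spectra = np.concatenate(
        [np.transpose(tensors[k].values, (0, 2, 1)) for k in required], axis=1
    )
    ratio_block = np.concatenate([ratios[k] for k in required], axis=1)
    freq_maps = np.concatenate([spectra, ratio_block], axis=2)

    n = freq_maps.shape[0]
    scalars = np.empty((n, 2))
    for i, t0 in enumerate(ref_times):
        w0, w1 = t0, t0 + win.width_s
        s0, s1 = int(round(w0 * spo2.fs)), int(round(w1 * spo2.fs))
        scalars[i, 0] = float(np.mean(spo2.samples[s0:max(s1, s0 + 1)]))
        h0, h1 = int(np.floor(w0 * hr.fs)), int(np.ceil(w1 * hr.fs))
        scalars[i, 1] = float(np.mean(hr.samples[h0:max(h1, h0 + 1)]))

    bins = tensors["eeg"].bin_centers_hz
    column_names = tuple(f"bin_{f:.2f}Hz" for f in bins) + RATIO_NAMES
    return FeatureSet(
        freq_maps=freq_maps,
        scalars=scalars,
        labels=np.array([label] * n, dtype=object),
        frame_times=ref_times + frame_offset_s,
        channel_names=channel_names,
        column_names=column_names,
        subject_id=subject_id,
    )


def featurize_segments(
    segset: SegmentSet,
    win: WindowSpec | None = None,
    bin_width_hz: float = 1.0 / 3.0,
    f_max_hz: float = 30.0,
    smooth_frames: int = 3,
    subject_id: str = "synthetic",
) -> FeatureSet:
    """Run the full feature chain on every state segment and stack the
    resulting instances (in state order, time-ordered within state)."""
    win = win or WindowSpec()
    parts: list[FeatureSet] = []
    for seg in segset.segments:
        tensors: dict[str, SpectrogramTensor] = {}
        ratio_map: dict[str, np.ndarray] = {}
        for key in ("eeg", "eog", "ecg", "pulse"):
            mod = seg.modalities.get(key)
            if mod is None:
                raise DataError(f"segment {seg.label!r} is missing modality {key!r}")
            logp, times, freqs = stft_logpower(mod.data, mod.fs, win)
            tensor = bin_and_smooth(
                logp, freqs, times, mod.channel_names, bin_width_hz, f_max_hz, smooth_frames
            )
            tensors[key] = tensor
            ratio_map[key] = band_ratios(tensor)
        spo2_mod = seg.modalities["spo2"]
        hr_mod = seg.modalities["hr"]
        parts.append(
            assemble_instances(
                tensors, ratio_map,
                Signal(spo2_mod.data[0], spo2_mod.fs, "SpO2"),
                Signal(hr_mod.data[0], hr_mod.fs, "HR"),
                seg.label, frame_offset_s=seg.start_s, win=win, subject_id=subject_id,
            )
        )
    return FeatureSet(
        freq_maps=np.concatenate([p.freq_maps for p in parts], axis=0),
        scalars=np.concatenate([p.scalars for p in parts], axis=0),
        labels=np.concatenate([p.labels for p in parts], axis=0),
        frame_times=np.concatenate([p.frame_times for p in parts], axis=0),
        channel_names=parts[0].channel_names,
        column_names=parts[0].column_names,
        subject_id=subject_id,
    )
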