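"""Signal conditioning: Fourier-domain resampling, zero-phase FIR filtering,
EOG derivation, heart-rate extraction and marker-based segmentation.

All channels are brought to a common 200 Hz grid (the auxiliary SpO2 channel
is upsampled from its native 80 Hz), power-line interference is notched out,
and a 2–50 Hz band-pass retains the neural oscillations of interest.  FIR
filters are windowed-sinc (Hamming) designs applied forward-backward, so the
chain is zero-phase.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal as sps

from .core import ConfigError, DataError, Modality, Recording, Segment, SegmentSet, Signal
from .morphology import StructuringElement, default_element, estimate_baseline

__all__ = [
    "FilterSpec",
    "resample_to",
    "apply_filters",
    "derive_eog",
    "heart_rate_from_ecg",
    "segment_by_markers",
    "preprocess_recording",
]

FS_TARGET = 200.0


@dataclass(frozen=True)
class FilterSpec:
    """Notch + band-pass design shared by all raw channels."""

    notch_hz: float = 50.0  # power-line frequency; set 60 for 60 Hz mains
    band_low_hz: float = 2.0
    band_high_hz: float = 50.0
    notch_halfwidth_hz: float = 1.0
    transition_hz: float = 1.0  # windowed-sinc transition width

    def numtaps(self, fs: float) -> int:
        n = int(round(3.3 * fs / self.transition_hz))
        return n + 1 if n % 2 == 0 else n  # odd length -> integer group delay


def resample_to(signal: Signal, fs_out: float) -> Signal:
    """Fourier-domain resampling; anti-aliasing is implicit in the spectral
    truncation.  Output length is round(N * fs_out / fs_in)."""
    if fs_out <= 0:
        raise ConfigError("fs_out must be positive")
    if signal.n < 2:
        raise DataError("cannot resample a signal with fewer than 2 samples")
    if fs_out == signal.fs:
        return signal
    n_out = int(round(signal.n * fs_out / signal.fs))
    out = sps.resample(signal.samples, n_out)
    return Signal(out, fs_out, signal.channel_name)


def _resample_array(data: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    if fs_out == fs_in:
        return data
    n_out = int(round(data.shape[-1] * fs_out / fs_in))
    return sps.resample(data, n_out, axis=-1)


def _firwin_filters(fs: float, spec: FilterSpec) -> list[np.ndarray]:
    nyq = fs / 2.0
    if not 0 < spec.band_low_hz < spec.band_high_hz < nyq:
        raise ConfigError("band edges must satisfy 0 < low < high < fs/2")
    if spec.notch_hz >= nyq:
        raise ConfigError("notch frequency must lie below fs/2")
    taps = spec.numtaps(fs)
    notch = sps.firwin(
        taps,
        [spec.notch_hz - spec.notch_halfwidth_hz, spec.notch_hz + spec.notch_halfwidth_hz],
        pass_zero="bandstop", window="hamming", fs=fs,
    )
    band = sps.firwin(
        taps, [spec.band_low_hz, spec.band_high_hz],
        pass_zero="bandpass", window="hamming", fs=fs,
    )
    return [notch, band]


def _filtfilt(x: np.ndarray, taps: np.ndarray) -> np.ndarray:
    padlen = 3 * len(taps)
    if x.shape[-1] <= padlen:
        raise DataError(
            f"signal length {x.shape[-1]} is too short for a {len(taps)}-tap "
            f"zero-phase filter (needs > {padlen} samples); pad the signal or "
            "use a shorter filter"
        )
    return sps.filtfilt(taps, [1.0], x, axis=-1, padlen=padlen)


def apply_filters(signal: Signal, spec: FilterSpec | None = None) -> Signal:
    """Notch then band-pass, both zero-phase (forward-backward FIR)."""
    spec = spec or FilterSpec()
    out = signal.samples
    for taps in _firwin_filters(signal.fs, spec):
        out = _filtfilt(out, taps)
    return signal.copy_with(out)


def _apply_filters_array(data: np.ndarray, fs: float, spec: FilterSpec) -> np.ndarray:
    for taps in _firwin_filters(fs, spec):
        data = _filtfilt(data, taps)
    return data


def derive_eog(upper: Signal, lower: Signal, left: Signal, right: Signal) -> tuple[Signal, Signal]:
    """Vertical = upper - lower; horizontal = left - right.

    Differencing rejects common-mode activity, leaving blink and saccade
    components on the vertical and horizontal traces respectively.
    """
    sigs = [upper, lower, left, right]
    if len({s.fs for s in sigs}) != 1 or len({s.n for s in sigs}) != 1:
        raise DataError("EOG electrodes must share sampling rate and length")
    vertical = Signal(upper.samples - lower.samples, upper.fs, "vEOG")
    horizontal = Signal(left.samples - right.samples, left.fs, "hEOG")
    return vertical, horizontal


def detect_r_peaks(ecg: Signal) -> np.ndarray:
    """R-peak sample indices via adaptive-threshold local-maximum search on
    the 5–30 Hz band-passed ECG."""
    fs = ecg.fs
    taps = sps.firwin(201, [5.0, 30.0], pass_zero="bandpass", window="hamming", fs=fs)
    x = _filtfilt(ecg.samples, taps) if ecg.n > 3 * 201 else ecg.samples
    ref = np.percentile(np.abs(x), 99)
    if ref <= 0 or not np.any(np.abs(x) > 1e-12):
        raise DataError("no QRS activity detected (flat or invalid ECG)")
    peaks, _ = sps.find_peaks(x, height=0.4 * ref, distance=int(0.33 * fs))
    if peaks.size == 0:
        raise DataError("no R peaks found (flat or invalid ECG)")
    return peaks


def heart_rate_from_ecg(ecg: Signal, window_s: float = 5.0) -> Signal:
    """Heart rate in beats/min, one value per non-overlapping window.

    HR per window is 60 / mean(RR) over the R peaks inside it; windows with
    fewer than two peaks carry the previous window's value.
    """
    if ecg.duration_s < 2 * window_s:
        raise DataError("ECG must be at least twice the HR window")
    peak_t = detect_r_peaks(ecg) / ecg.fs
    n_win = int(ecg.duration_s // window_s)
    hr = np.empty(n_win)
    last = np.nan
    for w in range(n_win):
        t0, t1 = w * window_s, (w + 1) * window_s
        pk = peak_t[(peak_t >= t0) & (peak_t < t1)]
        if pk.size >= 2:
            last = 60.0 / float(np.mean(np.diff(pk)))
        hr[w] = last
    if np.isnan(hr).all():
        raise DataError("no window contained two R peaks")
    # backfill leading windows that preceded the first valid estimate
    first_valid = int(np.flatnonzero(~np.isnan(hr))[0])
    hr[:first_valid] = hr[first_valid]
    return Signal(hr, 1.0 / window_s, "HR")


def segment_by_markers(
    recording: Recording,
    target_duration_s: float = 600.0,
) -> SegmentSet:
    """Cut one segment per state, symmetrically trimmed to the target length.

    Equal amounts are discarded from both ends of each marked interval so
    transition periods around state boundaries are excluded.
    """
    if target_duration_s <= 0:
        raise ConfigError("target_duration_s must be positive")
    segments = []
    for marker in recording.markers:
        avail = marker.duration_s
        if avail + 1e-9 < target_duration_s:
            raise DataError(
                f"interval for state {marker.label!r} lasts {avail:.1f} s, "
                f"shorter than the {target_duration_s:.1f} s target"
            )
        start = marker.start_s + (avail - target_duration_s) / 2.0
        mods = {}
        for key, mod in recording.modalities.items():
            i0 = int(round(start * mod.fs))
            i1 = i0 + int(round(target_duration_s * mod.fs))
            i1 = min(i1, mod.n_samples)
            mods[key] = Modality(mod.data[:, i0:i1], mod.fs, mod.channel_names)
        segments.append(Segment(marker.label, mods, start, target_duration_s))
    return SegmentSet(segments=segments, nominal_duration_s=target_duration_s)


def preprocess_recording(
    recording: Recording,
    fs_target: float = FS_TARGET,
    filter_spec: FilterSpec | None = None,
    morph_element: StructuringElement | None = None,
    hr_window_s: float = 5.0,
) -> Recording:
    """Full conditioning chain on a raw recording.

    Resample every channel to ``fs_target`` (SpO2 is upsampled from its
    auxiliary rate), notch + band-pass the electrophysiological channels,
    derive vertical/horizontal EOG by electrode differencing, remove ECG
    baseline wander morphologically, and extract the heart-rate series from
    the corrected ECG.  Markers (in seconds) carry over unchanged.
    """
    spec = filter_spec or FilterSpec()
    provenance: list[str] = [f"resample:{fs_target:g}Hz"]

    out: dict[str, Modality] = {}
    for key in ("eeg", "eog_raw", "ecg", "pulse"):
        mod = recording.require(key)
        data = _resample_array(mod.data, mod.fs, fs_target)
        data = _apply_filters_array(data, fs_target, spec)
        out[key] = Modality(data, fs_target, mod.channel_names)
    provenance.append(
        f"filter:notch{spec.notch_hz:g}+band{spec.band_low_hz:g}-{spec.band_high_hz:g}Hz"
    )

    # EOG derivation from the filtered raw electrodes
    eog_raw = out.pop("eog_raw")
    v, h = derive_eog(*(eog_raw.channel(n) for n in ("VEOU", "VEOL", "HEOL", "HEOR")))
    out["eog"] = Modality(np.stack([v.samples, h.samples]), fs_target, ("vEOG", "hEOG"))
    provenance.append("eog:differencing")

    # morphological baseline removal on ECG
    element = morph_element or default_element(fs_target)
    ecg_sig = Signal(out["ecg"].data[0], fs_target, "ECG")
    decomp = estimate_baseline(ecg_sig, element)
    out["ecg"] = Modality(decomp.corrected.samples[np.newaxis, :], fs_target, ("ECG",))
    provenance.append(f"ecg:morph-baseline(M={element.m})")

    # auxiliary channels
    spo2 = recording.require("spo2")
    out["spo2"] = Modality(
        _resample_array(spo2.data, spo2.fs, fs_target), fs_target, spo2.channel_names
    )
    provenance.append(f"spo2:resample{spo2.fs:g}->{fs_target:g}Hz")

    hr = heart_rate_from_ecg(decomp.corrected, hr_window_s)
    out["hr"] = Modality(hr.samples[np.newaxis, :], hr.fs, ("HR",))
    provenance.append(f"hr:from-ecg(window={hr_window_s:g}s)")

    meta = dict(recording.meta)
    meta["applied_operations"] = provenance
    return Recording(
        modalities=out,
        markers=list(recording.markers),
        subject_id=recording.subject_id,
        meta=meta,
    )
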