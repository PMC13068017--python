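"""Seeded synthetic multimodal recordings with attention-state structure.

The generator emulates the class-conditional structure the classification
method relies on, so the whole pipeline can be exercised without access to
human recordings:

* EEG — per-channel sum of band-limited theta/alpha/beta oscillations over a
  1/f background.  The three shipped state profiles order the
  beta/(alpha+theta) amplitude ratio strictly high > medium > low, the
  classical engagement-index direction.  Channels flagged non-informative
  carry background noise only.
* ECG — template P-QRS-T beats (Gaussian bumps) at jittered RR intervals,
  summed with a sinusoid-plus-slow-noise baseline wander whose ground truth
  is returned separately for oracle tests.
* EOG — four raw electrodes; the vertical pair differs by stereotyped blink
  bumps (Poisson arrivals), the horizontal pair by step-like saccades.
* Pulse — smoothed pulse waves locked to the ECG beat times.
* SpO2 — slow random walk around 97% at the auxiliary rate.

Everything is fully determined by integer seeds.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bands import BAND_EDGES_HZ
from .core import (
    ConfigError,
    DataError,
    EEG_CHANNEL_NAMES,
    Modality,
    Recording,
    Signal,
    StateMarker,
    STATE_ORDER,
)

__all__ = [
    "StateProfile",
    "SyntheticConfig",
    "ECGSynthesis",
    "default_profiles",
    "generate_eeg",
    "generate_ecg",
    "generate_eog",
    "generate_recording",
]


@dataclass(frozen=True)
class StateProfile:
    """Generator parameters for one attention state."""

    state_label: str
    band_power_map: dict[str, float]  # relative oscillation amplitude per band
    noise_exponent: float = 1.0  # spectral slope of the 1/f background
    blink_rate: float = 15.0  # blinks per minute
    hr_mean_bpm: float = 70.0
    hr_sd_bpm: float = 2.5
    wander_amp: float = 0.3  # mV of ECG baseline drift
    wander_freq_hz: float = 0.25

    def __post_init__(self) -> None:
        if self.state_label not in STATE_ORDER:
            raise ConfigError(f"unknown state label {self.state_label!r}")
        for name, amp in self.band_power_map.items():
            if name not in BAND_EDGES_HZ:
                raise ConfigError(f"unknown band {name!r}")
            if amp < 0:
                raise ConfigError(f"negative amplitude for band {name!r}")
        if not 30.0 <= self.hr_mean_bpm <= 200.0:
            raise ConfigError("hr_mean_bpm must lie in [30, 200]")
        if min(self.hr_sd_bpm, self.blink_rate, self.wander_amp, self.wander_freq_hz) < 0:
            raise ConfigError("rates and amplitudes must be non-negative")

    def engagement_ratio(self) -> float:
        """beta/(alpha+theta) amplitude ratio implied by the profile."""
        b = self.band_power_map.get("beta", 0.0)
        a = self.band_power_map.get("alpha", 0.0)
        t = self.band_power_map.get("theta", 0.0)
        return b / (a + t) if (a + t) > 0 else np.inf


def default_profiles() -> dict[str, StateProfile]:
    """Shipped per-state defaults.

    Beta dominance rises with attention while alpha/theta and blink rate
    fall; heart rate is mildly elevated under load.  The implied
    beta/(alpha+theta) ratios are 1.0 (high) > 0.5 (medium) > ~0.23 (low).
    """
    return {
        "high": StateProfile(
            "high", {"theta": 0.5, "alpha": 0.7, "beta": 1.2},
            blink_rate=8.0, hr_mean_bpm=76.0,
        ),
        "medium": StateProfile(
            "medium", {"theta": 0.8, "alpha": 1.0, "beta": 0.9},
            blink_rate=14.0, hr_mean_bpm=70.0,
        ),
        "low": StateProfile(
            "low", {"theta": 1.2, "alpha": 1.4, "beta": 0.6},
            blink_rate=22.0, hr_mean_bpm=62.0,
        ),
    }


@dataclass(frozen=True)
class SyntheticConfig:
    """Layout and rates of a synthetic session (three consecutive states)."""

    n_eeg_channels: int = 11
    n_eog_electrodes: int = 4
    fs_raw: float = 1000.0  # EEG/EOG/ECG/pulse acquisition rate
    fs_aux: float = 80.0  # SpO2 finger-clip rate
    segment_duration_s: float = 600.0
    seed: int = 0
    informative_channel_mask: tuple[bool, ...] | None = None

    def __post_init__(self) -> None:
        if self.segment_duration_s <= 0:
            raise ConfigError("segment_duration_s must be positive")
        highest = max(hi for _, hi in BAND_EDGES_HZ.values())
        if self.fs_raw <= 2 * highest:
            raise ConfigError("fs_raw must exceed twice the highest synthesized frequency")
        if self.n_eeg_channels < 1 or self.n_eog_electrodes != 4:
            raise ConfigError("need >=1 EEG channel and exactly 4 EOG electrodes")
        mask = self.informative_channel_mask
        if mask is None:
            # last three EEG channels are noise-only controls by default
            mask = tuple(i < max(1, self.n_eeg_channels - 3) for i in range(self.n_eeg_channels))
            object.__setattr__(self, "informative_channel_mask", mask)
        elif len(mask) != self.n_eeg_channels:
            raise ConfigError("informative_channel_mask length must equal n_eeg_channels")


# ---------------------------------------------------------------------------
# noise primitives

_EEG_OSC_UV = 10.0  # microvolts per unit of profile band amplitude
_EEG_NOISE_UV = 10.0  # RMS of the 1/f background


def _one_over_f(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS noise with amplitude spectrum ~ f^(-exponent/2)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0)
    shape = np.zeros_like(f)
    shape[1:] = f[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * shape, n=n)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _band_noise(n: int, fs: float, lo: float, hi: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS noise band-limited to [lo, hi) Hz via spectral masking."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[(f < lo) | (f >= hi)] = 0.0
    x = np.fft.irfft(spec, n=n)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _slow_noise(n: int, fs: float, cutoff_hz: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS slowly varying noise: coarse samples linearly interpolated."""
    n_coarse = max(int(np.ceil(n / fs * cutoff_hz * 4)), 4)
    coarse = rng.standard_normal(n_coarse + 1)
    t = np.linspace(0.0, n_coarse, n)
    x = np.interp(t, np.arange(n_coarse + 1), coarse)
    x -= x.mean()
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


# ---------------------------------------------------------------------------
# EEG


def generate_eeg(
    duration_s: float,
    fs: float,
    profile: StateProfile,
    n_channels: int,
    informative_channel_mask: tuple[bool, ...] | None,
    seed: int,
) -> np.ndarray:
    """Multichannel EEG (channels x samples, microvolts).

    Informative channels carry band-limited theta/alpha/beta oscillations at
    the profile's relative amplitudes over a 1/f background; the rest carry
    background only (degenerate all-noise masks are allowed as controls).
    """
    if n_channels < 1:
        raise ConfigError("n_channels must be >= 1")
    if informative_channel_mask is None:
        informative_channel_mask = (True,) * n_channels
    if len(informative_channel_mask) != n_channels:
        raise ConfigError("mask length must equal n_channels")
    n = int(round(duration_s * fs))
    rng = np.random.default_rng(seed)
    out = np.empty((n_channels, n))
    for c in range(n_channels):
        x = _EEG_NOISE_UV * _one_over_f(n, profile.noise_exponent, rng)
        if informative_channel_mask[c]:
            for band, (lo, hi) in BAND_EDGES_HZ.items():
                amp = profile.band_power_map.get(band, 0.0)
                if amp > 0:
                    x = x + amp * _EEG_OSC_UV * _band_noise(n, fs, lo, hi, rng)
        out[c] = x
    return out


# ---------------------------------------------------------------------------
# ECG

# Gaussian bump parameters per wave: (amplitude mV, center offset s from R, width s)
_ECG_WAVES = (
    (0.12, -0.20, 0.040),  # P
    (-0.15, -0.035, 0.012),  # Q
    (1.00, 0.0, 0.012),  # R
    (-0.20, 0.035, 0.014),  # S
    (0.30, 0.28, 0.060),  # T
)


@dataclass
class ECGSynthesis:
    """Generated ECG and its exact additive decomposition."""

    signal: Signal  # beats + measurement noise + wander
    wander: Signal  # ground-truth baseline wander (same length)
    r_peak_times: np.ndarray  # seconds
    rr_intervals: np.ndarray  # seconds, one per emitted beat

    def clean(self) -> np.ndarray:
        return self.signal.samples - self.wander.samples


def generate_ecg(
    duration_s: float,
    fs: float,
    hr_mean_bpm: float,
    hr_sd_bpm: float = 0.0,
    wander_amp: float = 0.3,
    wander_freq_hz: float = 0.25,
    seed: int = 0,
    noise_mv: float = 0.02,
) -> ECGSynthesis:
    """Template-based ECG (mV) plus ground-truth baseline wander.

    Beats are Gaussian-bump P-QRS-T complexes placed at RR intervals drawn
    from a per-beat heart rate ~ N(hr_mean_bpm, hr_sd_bpm).  The wander is a
    sinusoid at ``wander_freq_hz`` plus a slow noise component, both scaled by
    ``wander_amp``; it is returned separately so baseline-removal stages can
    be scored against it.
    """
    if duration_s <= 0:
        raise ConfigError("duration_s must be positive")
    if fs < 100:
        raise ConfigError("fs must be at least 100 Hz for ECG synthesis")
    if not 30.0 <= hr_mean_bpm <= 200.0:
        raise ConfigError("hr_mean_bpm must lie in [30, 200]")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs

    # beat times
    r_times = []
    rr = []
    t_beat = float(rng.uniform(0.1, 0.5))
    while t_beat < duration_s:
        r_times.append(t_beat)
        hr = hr_mean_bpm + hr_sd_bpm * rng.standard_normal()
        hr = float(np.clip(hr, 30.0, 200.0))
        rr_i = 60.0 / hr
        rr.append(rr_i)
        t_beat += rr_i
    r_times_arr = np.asarray(r_times)
    rr_arr = np.asarray(rr)

    clean = np.zeros(n)
    for tr in r_times_arr:
        for amp, off, width in _ECG_WAVES:
            c = tr + off
            lo = max(int((c - 5 * width) * fs), 0)
            hi = min(int((c + 5 * width) * fs) + 1, n)
            if hi > lo:
                tt = t[lo:hi]
                clean[lo:hi] += amp * np.exp(-0.5 * ((tt - c) / width) ** 2)
    clean += noise_mv * rng.standard_normal(n)

    if wander_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        wander = wander_amp * np.sin(2 * np.pi * wander_freq_hz * t + phase)
        wander = wander + 0.4 * wander_amp * _slow_noise(n, fs, wander_freq_hz, rng)
    else:
        wander = np.zeros(n)

    return ECGSynthesis(
        signal=Signal(clean + wander, fs, "ECG"),
        wander=Signal(wander if wander_amp > 0 else np.zeros(n), fs, "ECG-wander"),
        r_peak_times=r_times_arr,
        rr_intervals=rr_arr,
    )


# ---------------------------------------------------------------------------
# EOG, pulse, SpO2


def generate_eog(
    duration_s: float,
    fs: float,
    blink_rate_per_min: float,
    seed: int,
) -> np.ndarray:
    """Four raw EOG electrodes (upper, lower, left, right; microvolts).

    The vertical pair shares a common-mode background and differs by blink
    bumps (Poisson arrivals); the horizontal pair differs by step-like
    saccades.  Differencing the pairs therefore yields blink/saccade traces.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs

    def background() -> np.ndarray:
        return 15.0 * _slow_noise(n, fs, 8.0, rng) + 3.0 * rng.standard_normal(n)

    common_v = background()
    common_h = background()
    blinks = np.zeros(n)
    n_blinks = rng.poisson(blink_rate_per_min * duration_s / 60.0)
    for tc in np.sort(rng.uniform(0, duration_s, n_blinks)):
        width = rng.uniform(0.10, 0.18)
        amp = rng.uniform(80.0, 140.0)
        lo = max(int((tc - 4 * width) * fs), 0)
        hi = min(int((tc + 4 * width) * fs) + 1, n)
        blinks[lo:hi] += amp * np.exp(-0.5 * ((t[lo:hi] - tc) / width) ** 2)

    saccades = np.zeros(n)
    n_sacc = rng.poisson(duration_s / 60.0 * 20.0)  # ~20 gaze shifts/min
    level = 0.0
    edges = np.sort(rng.uniform(0, duration_s, n_sacc))
    prev = 0
    for te in edges:
        idx = int(te * fs)
        saccades[prev:idx] = level
        level = float(np.clip(level + rng.normal(0, 40.0), -120, 120))
        prev = idx
    saccades[prev:] = level

    upper = common_v + blinks + 2.0 * rng.standard_normal(n)
    lower = common_v - 0.3 * blinks + 2.0 * rng.standard_normal(n)
    left = common_h + 0.5 * saccades + 2.0 * rng.standard_normal(n)
    right = common_h - 0.5 * saccades + 2.0 * rng.standard_normal(n)
    return np.stack([upper, lower, left, right])


def _generate_pulse(n: int, fs: float, r_peak_times: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Smooth pulse waves delayed ~0.25 s after each R peak (arbitrary units)."""
    t = np.arange(n) / fs
    pulse = np.zeros(n)
    for tr in r_peak_times:
        c = tr + 0.25
        width = 0.12
        lo = max(int((c - 4 * width) * fs), 0)
        hi = min(int((c + 4 * width) * fs) + 1, n)
        if hi > lo:
            pulse[lo:hi] += np.exp(-0.5 * ((t[lo:hi] - c) / width) ** 2)
    return pulse + 0.02 * rng.standard_normal(n)


def _generate_spo2(duration_s: float, fs_aux: float, rng: np.random.Generator) -> np.ndarray:
    n = int(round(duration_s * fs_aux))
    walk = _slow_noise(n, fs_aux, 0.05, rng)
    return np.clip(97.0 + 1.0 * walk, 90.0, 100.0)


# ---------------------------------------------------------------------------
# full recording


def generate_recording(
    config: SyntheticConfig,
    profiles: dict[str, StateProfile] | None = None,
) -> Recording:
    """One synthetic session: consecutive high, medium, low segments.

    All modalities are emitted at their native rates (raw channels at
    ``fs_raw``, SpO2 at ``fs_aux``) with state-boundary markers.  The output
    is fully determined by ``config.seed``.
    """
    if profiles is None:
        profiles = default_profiles()
    labels = sorted(profiles.keys())
    if labels != sorted(STATE_ORDER) or len(profiles) != 3:
        raise ConfigError(
            f"profiles must cover exactly the states {set(STATE_ORDER)}, got {set(profiles)}"
        )
    for label, p in profiles.items():
        if p.state_label != label:
            raise ConfigError(f"profile keyed {label!r} is labeled {p.state_label!r}")

    dur = config.segment_duration_s
    fs = config.fs_raw
    n_seg = int(round(dur * fs))
    n_aux_seg = int(round(dur * config.fs_aux))

    eeg_parts, eog_parts, ecg_parts, pulse_parts, spo2_parts, hr_parts = [], [], [], [], [], []
    markers: list[StateMarker] = []
    true_hr_mean: dict[str, float] = {}
    for i, state in enumerate(STATE_ORDER):
        prof = profiles[state]
        base = (config.seed * 1000003 + 7919 * i) % (2**31 - 1)
        eeg_parts.append(
            generate_eeg(dur, fs, prof, config.n_eeg_channels,
                         config.informative_channel_mask, base)
        )
        eog_parts.append(generate_eog(dur, fs, prof.blink_rate, base + 1))
        ecg = generate_ecg(dur, fs, prof.hr_mean_bpm, prof.hr_sd_bpm,
                           prof.wander_amp, prof.wander_freq_hz, base + 2)
        ecg_parts.append(ecg.signal.samples[np.newaxis, :])
        rng = np.random.default_rng(base + 3)
        pulse_parts.append(_generate_pulse(n_seg, fs, ecg.r_peak_times, rng)[np.newaxis, :])
        spo2_parts.append(_generate_spo2(dur, config.fs_aux, rng)[np.newaxis, :])
        # per-second instantaneous HR ground truth from the RR series
        sec_edges = np.arange(int(dur) + 1, dtype=float)
        inst_hr = np.interp(
            sec_edges[:-1] + 0.5, ecg.r_peak_times, 60.0 / np.maximum(ecg.rr_intervals, 1e-6)
        )
        hr_parts.append(inst_hr[np.newaxis, :])
        markers.append(StateMarker(state, i * dur, (i + 1) * dur))
        true_hr_mean[state] = float(prof.hr_mean_bpm)

    eeg_names = tuple(EEG_CHANNEL_NAMES[: config.n_eeg_channels]) if (
        config.n_eeg_channels <= len(EEG_CHANNEL_NAMES)
    ) else tuple(f"EEG{i}" for i in range(config.n_eeg_channels))

    modalities = {
        "eeg": Modality(np.concatenate(eeg_parts, axis=1), fs, eeg_names),
        "eog_raw": Modality(
            np.concatenate(eog_parts, axis=1), fs, ("VEOU", "VEOL", "HEOL", "HEOR")
        ),
        "ecg": Modality(np.concatenate(ecg_parts, axis=1), fs, ("ECG",)),
        "pulse": Modality(np.concatenate(pulse_parts, axis=1), fs, ("Pulse",)),
        "spo2": Modality(np.concatenate(spo2_parts, axis=1), config.fs_aux, ("SpO2",)),
        "hr": Modality(np.concatenate(hr_parts, axis=1), 1.0, ("HR",)),
    }
    return Recording(
        modalities=modalities,
        markers=markers,
        subject_id=f"synthetic-seed{config.seed}",
        meta={
            "seed": config.seed,
            "informative_channel_mask": list(config.informative_channel_mask),
            "true_hr_mean_bpm": true_hr_mean,
        },
    )
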