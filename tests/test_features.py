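"""Feature-stage tests: Blackman taper values, STFT framing, frequency
compression, band ratios and instance assembly."""
from __future__ import annotations

import numpy as np
import pytest

from meanbci.core import ConfigError, DataError, Signal
from meanbci.features import (
    EPS,
    SpectrogramTensor,
    WindowSpec,
    assemble_instances,
    band_ratios,
    bin_and_smooth,
    blackman,
    stft_logpower,
)


class TestBlackman:
    def test_endpoint_is_zero(self):
        for width in (3, 10, 101):
            assert blackman(width)[0] == pytest.approx(0.42 - 0.5 + 0.08, abs=1e-12)

    def test_center_is_one_for_odd_width(self):
        w = blackman(101)
        assert w[50] == pytest.approx(1.0, abs=1e-12)

    def test_width4_hand_value(self):
        # 0.42 - 0.5 cos(2π/3) + 0.08 cos(4π/3) = 0.63
        assert blackman(4)[1] == pytest.approx(0.63, abs=1e-10)

    def test_matches_numpy_reference(self):
        np.testing.assert_allclose(blackman(64), np.blackman(64), atol=1e-12)

    def test_too_narrow_rejected(self):
        with pytest.raises(ConfigError):
            blackman(2)


class TestStft:
    def test_frame_count_arithmetic(self):
        fs = 200.0
        x = np.zeros(int(30 * fs))
        logp, times, freqs = stft_logpower(x, fs)
        assert logp.shape[0] == (30 - 9) // 1 + 1 == 22
        assert freqs[1] - freqs[0] == pytest.approx(1.0 / 9.0)

    def test_overlap_fraction(self):
        assert WindowSpec().overlap_fraction == pytest.approx(8.0 / 9.0)

    def test_pure_sine_peak_location(self):
        fs = 200.0
        t = np.arange(int(20 * fs)) / fs
        x = np.sin(2 * np.pi * 10.0 * t)
        logp, _, freqs = stft_logpower(x, fs)
        for frame in range(logp.shape[0]):
            assert freqs[np.argmax(logp[frame, :, 0])] == pytest.approx(10.0)

    def test_too_short_rejected(self):
        with pytest.raises(DataError):
            stft_logpower(np.zeros(100), 200.0)


def _spec_for(x: np.ndarray, fs: float = 200.0):
    return stft_logpower(x, fs)


class TestBinAndSmooth:
    def test_ninety_bins_at_defaults(self):
        fs = 200.0
        logp, times, freqs = _spec_for(np.random.default_rng(0).standard_normal(int(20 * fs)))
        tensor = bin_and_smooth(logp, freqs, times, ("x",))
        assert tensor.n_bins == 90
        assert np.all(tensor.bin_centers_hz > 0)
        assert np.all(tensor.bin_centers_hz < 30)

    def test_smooth_one_is_identity(self):
        fs = 200.0
        logp, times, freqs = _spec_for(np.random.default_rng(1).standard_normal(int(15 * fs)))
        a = bin_and_smooth(logp, freqs, times, ("x",), smooth_frames=1)
        b = bin_and_smooth(logp, freqs, times, ("x",), smooth_frames=3)
        assert not np.allclose(a.values, b.values)
        raw_grouped = bin_and_smooth(logp, freqs, times, ("x",), smooth_frames=1)
        np.testing.assert_allclose(a.values, raw_grouped.values)

    def test_constant_input_invariant_under_smoothing(self):
        logp = np.zeros((10, 901, 1))
        freqs = np.fft.rfftfreq(1800, d=1 / 200.0)
        a = bin_and_smooth(logp, freqs, np.arange(10.0), ("x",), smooth_frames=1)
        b = bin_and_smooth(logp, freqs, np.arange(10.0), ("x",), smooth_frames=3)
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)

    def test_incompatible_spacing_proposes_alternative(self):
        logp = np.zeros((4, 51, 1))
        freqs = np.fft.rfftfreq(100, d=1 / 20.0)  # 0.2 Hz spacing
        with pytest.raises(ConfigError, match="nearest compatible"):
            bin_and_smooth(logp, freqs, np.arange(4.0), ("x",), bin_width_hz=0.5)

    def test_smoothing_reduces_frame_to_frame_variance(self):
        fs = 200.0
        logp, times, freqs = _spec_for(np.random.default_rng(2).standard_normal(int(30 * fs)))
        raw = bin_and_smooth(logp, freqs, times, ("x",), smooth_frames=1).values
        smooth = bin_and_smooth(logp, freqs, times, ("x",), smooth_frames=3).values
        assert np.var(np.diff(smooth, axis=0)) <= np.var(np.diff(raw, axis=0))

    def test_unit_sine_power_concentrates(self):
        """>= 90% of the binned linear power of a bin-centered unit sine
        lies in that bin."""
        fs = 200.0
        t = np.arange(int(20 * fs)) / fs
        f0 = 92.0 / 9.0  # center of a compressed 1/3 Hz bin
        logp, times, freqs = _spec_for(np.sin(2 * np.pi * f0 * t))
        tensor = bin_and_smooth(logp, freqs, times, ("x",), smooth_frames=1)
        power = np.exp(tensor.values[5, :, 0])
        assert power.max() / power.sum() >= 0.90


def _tensor_with_band_powers(alpha: float, beta: float, theta: float) -> SpectrogramTensor:
    """One frame, one channel; a single bin per band carries the band power."""
    centers = np.array([6.0, 10.0, 20.0])  # theta, alpha, beta
    values = np.log(np.array([[theta, alpha, beta]]).reshape(1, 3, 1) + EPS)
    return SpectrogramTensor(values, centers, np.array([0.0]), ("x",), 1.0)


class TestBandRatios:
    def test_hand_arithmetic(self):
        t = _tensor_with_band_powers(alpha=2.0, beta=4.0, theta=2.0)
        np.testing.assert_allclose(band_ratios(t)[0, 0], [2.0, 2.0, 1.0], rtol=1e-9)

    def test_zero_beta_gives_zero_ratios(self):
        t = _tensor_with_band_powers(alpha=2.0, beta=0.0, theta=2.0)
        np.testing.assert_allclose(band_ratios(t)[0, 0], [0.0, 0.0, 0.0], atol=1e-9)

    def test_empty_band_rejected(self):
        t = _tensor_with_band_powers(2.0, 4.0, 2.0)
        with pytest.raises(ConfigError, match="gamma"):
            band_ratios(t, {"theta": (4, 8), "alpha": (8, 13), "beta": (13, 30),
                            "gamma": (40, 50)})

    def test_state_ordering_on_informative_channel(self, small_features):
        """beta/(alpha+theta) column is on average higher for the high state
        than the low state on an informative EEG channel."""
        ratio_col = small_features.freq_maps[:, 0, 92]  # channel F3, third ratio
        high = ratio_col[small_features.labels == "high"].mean()
        low = ratio_col[small_features.labels == "low"].mean()
        assert high > low


class TestAssembly:
    def test_full_feature_width(self, small_features):
        assert small_features.freq_maps.shape[1:] == (15, 93)
        assert small_features.n_features == 1397
        assert small_features.flattened().shape[1] == 1397

    def test_instance_count_arithmetic(self, small_features):
        # three 60 s segments, 9 s / 1 s framing: 3 * (floor((60-9)/1)+1)
        assert small_features.n_instances == 3 * 52

    def test_channel_order_enforced(self, small_features):
        fs = 200.0
        rng = np.random.default_rng(3)
        logp, times, freqs = stft_logpower(rng.standard_normal((1, int(15 * fs))), fs)
        tensors, ratios = {}, {}
        for key, names in (("eeg", ("F3",)), ("eog", ("vEOG",)),
                           ("ecg", ("Pulse",)), ("pulse", ("ECG",))):  # swapped!
            t = bin_and_smooth(logp, freqs, times, names)
            tensors[key], ratios[key] = t, band_ratios(t)
        spo2 = Signal(np.full(int(15 * fs), 97.0), fs)
        hr = Signal(np.full(15, 70.0), 1.0)
        with pytest.raises(DataError, match="order"):
            assemble_instances(
                tensors, ratios, spo2, hr, "high",
                expected_channel_order=("F3", "vEOG", "ECG", "Pulse"),
            )

    def test_missing_modality_named(self):
        with pytest.raises(DataError, match="ecg"):
            assemble_instances(
                {"eeg": None, "eog": None, "pulse": None},
                {"eeg": None, "eog": None, "pulse": None},
                Signal(np.ones(10), 1.0), Signal(np.ones(10), 1.0), "high",
            )
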