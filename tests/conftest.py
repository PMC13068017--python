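"""Shared fixtures: small synthetic recordings/feature sets generated at test
time (no stored data)."""
from __future__ import annotations

import numpy as np
import pytest

from meanbci.features import FeatureSet, featurize_segments
from meanbci.preprocess import preprocess_recording, segment_by_markers
from meanbci.synth import SyntheticConfig, generate_recording


@pytest.fixture(scope="session")
def small_recording():
    """60 s per state at the native rates — enough frames for CV tests."""
    return generate_recording(SyntheticConfig(segment_duration_s=60.0, seed=7))


@pytest.fixture(scope="session")
def small_preprocessed(small_recording):
    return preprocess_recording(small_recording)


@pytest.fixture(scope="session")
def small_features(small_preprocessed) -> FeatureSet:
    return featurize_segments(segment_by_markers(small_preprocessed, 60.0))


def make_blob_features(
    n_per_class: int = 30,
    n_channels: int = 4,
    n_cols: int = 7,
    separation: float = 3.0,
    seed: int = 0,
) -> FeatureSet:
    """Fast, well-separated Gaussian-blob feature set for model/CV unit tests."""
    rng = np.random.default_rng(seed)
    labels, maps, scalars, times = [], [], [], []
    for ci, label in enumerate(("high", "medium", "low")):
        center = rng.standard_normal((n_channels, n_cols)) * separation
        for t in range(n_per_class):
            maps.append(center + rng.standard_normal((n_channels, n_cols)))
            scalars.append(rng.standard_normal(2))
            labels.append(label)
            times.append(ci * 1000.0 + t)
    return FeatureSet(
        freq_maps=np.asarray(maps),
        scalars=np.asarray(scalars),
        labels=np.asarray(labels, dtype=object),
        frame_times=np.asarray(times),
        channel_names=tuple(f"ch{i}" for i in range(n_channels)),
        column_names=tuple(f"col{i}" for i in range(n_cols)),
    )


@pytest.fixture()
def blob_features() -> FeatureSet:
    return make_blob_features()
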