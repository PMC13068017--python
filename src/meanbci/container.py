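"""Persistent container for recordings and features.

Primary format is HDF5 (`/raw/<modality>`, `/preprocessed/<modality>`,
`/features` groups; channels x samples datasets with ``fs`` and
``channel_names`` attributes, state markers as sample indices + labels at
the raw rate) with an NPZ fallback using the same keys, plus a sidecar JSON
metadata file.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .core import DataError, Modality, Recording, StateMarker
from .features import FeatureSet

__all__ = [
    "save_recording",
    "load_recording",
    "save_features",
    "load_features",
    "validate_container",
]

_MARKER_FS = 1000.0  # markers stored as sample indices at this reference rate


def _use_npz(path: Path) -> bool:
    return path.suffix == ".npz"


def save_recording(recording: Recording, path: str | Path, group: str = "raw") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {
        "subject_id": recording.subject_id,
        "group": group,
        **{k: v for k, v in recording.meta.items()},
    }
    starts = [int(round(m.start_s * _MARKER_FS)) for m in recording.markers]
    ends = [int(round(m.end_s * _MARKER_FS)) for m in recording.markers]
    labels = [m.label for m in recording.markers]

    if _use_npz(path):
        payload: dict[str, np.ndarray] = {
            "marker_starts": np.array(starts),
            "marker_ends": np.array(ends),
            "marker_labels": np.array(labels, dtype="U16"),
            "marker_fs": np.array(_MARKER_FS),
        }
        for key, mod in recording.modalities.items():
            payload[f"{group}/{key}/data"] = mod.data
            payload[f"{group}/{key}/fs"] = np.array(mod.fs)
            payload[f"{group}/{key}/channel_names"] = np.array(mod.channel_names, dtype="U16")
        np.savez_compressed(path, **payload)
    else:
        import h5py

        mode = "a" if path.exists() else "w"
        with h5py.File(path, mode) as f:
            if group in f:
                del f[group]
            g = f.create_group(group)
            for key, mod in recording.modalities.items():
                d = g.create_dataset(key, data=mod.data)
                d.attrs["fs"] = mod.fs
                d.attrs["channel_names"] = list(mod.channel_names)
            f.attrs["marker_starts"] = starts
            f.attrs["marker_ends"] = ends
            f.attrs["marker_labels"] = labels
            f.attrs["marker_fs"] = _MARKER_FS
            f.attrs["subject_id"] = recording.subject_id
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(meta, indent=2, default=str)
    )


def load_recording(path: str | Path, group: str = "raw") -> Recording:
    path = Path(path)
    if not path.exists():
        raise DataError(f"container {path} does not exist")
    meta_path = path.with_suffix(path.suffix + ".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}

    modalities: dict[str, Modality] = {}
    if _use_npz(path):
        with np.load(path, allow_pickle=False) as z:
            prefix = f"{group}/"
            keys = {k.split("/")[1] for k in z.files if k.startswith(prefix)}
            if not keys:
                raise DataError(f"container has no group {group!r}")
            for key in sorted(keys):
                modalities[key] = Modality(
                    z[f"{prefix}{key}/data"],
                    float(z[f"{prefix}{key}/fs"]),
                    tuple(str(n) for n in z[f"{prefix}{key}/channel_names"]),
                )
            starts, ends = z["marker_starts"], z["marker_ends"]
            labels = [str(l) for l in z["marker_labels"]]
            mfs = float(z["marker_fs"])
    else:
        import h5py

        with h5py.File(path, "r") as f:
            if group not in f:
                raise DataError(f"container has no group {group!r}")
            for key in f[group]:
                d = f[group][key]
                modalities[key] = Modality(
                    d[()], float(d.attrs["fs"]),
                    tuple(str(n) for n in d.attrs["channel_names"]),
                )
            starts = f.attrs["marker_starts"]
            ends = f.attrs["marker_ends"]
            labels = [
                l.decode() if isinstance(l, bytes) else str(l)
                for l in f.attrs["marker_labels"]
            ]
            mfs = float(f.attrs["marker_fs"])
            meta.setdefault("subject_id", str(f.attrs.get("subject_id", "unknown")))

    markers = [
        StateMarker(lab, s / mfs, e / mfs) for lab, s, e in zip(labels, starts, ends)
    ]
    subject = meta.get("subject_id", "unknown")
    return Recording(modalities=modalities, markers=markers, subject_id=subject, meta=meta)


def save_features(fs: FeatureSet, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if _use_npz(path):
        np.savez_compressed(
            path.with_name(path.stem + "-features.npz"),
            freq_maps=fs.freq_maps, scalars=fs.scalars,
            labels=fs.labels.astype("U16"), frame_times=fs.frame_times,
            channel_names=np.array(fs.channel_names, dtype="U16"),
            column_names=np.array(fs.column_names, dtype="U32"),
            subject_id=np.array(fs.subject_id, dtype="U64"),
        )
    else:
        import h5py

        with h5py.File(path, "a") as f:
            if "features" in f:
                del f["features"]
            g = f.create_group("features")
            g.create_dataset("freq_maps", data=fs.freq_maps)
            g.create_dataset("scalars", data=fs.scalars)
            g.create_dataset("labels", data=fs.labels.astype("U16").tolist())
            g.create_dataset("frame_times", data=fs.frame_times)
            g.attrs["channel_names"] = list(fs.channel_names)
            g.attrs["column_names"] = list(fs.column_names)
            g.attrs["subject_id"] = fs.subject_id


def load_features(path: str | Path) -> FeatureSet:
    path = Path(path)
    if _use_npz(path):
        fpath = path.with_name(path.stem + "-features.npz")
        if not fpath.exists():
            raise DataError(f"no features stored next to {path}; run featurize first")
        with np.load(fpath, allow_pickle=False) as z:
            return FeatureSet(
                freq_maps=z["freq_maps"], scalars=z["scalars"],
                labels=z["labels"].astype(object), frame_times=z["frame_times"],
                channel_names=tuple(str(n) for n in z["channel_names"]),
                column_names=tuple(str(n) for n in z["column_names"]),
                subject_id=str(z["subject_id"]),
            )
    import h5py

    with h5py.File(path, "r") as f:
        if "features" not in f:
            raise DataError(f"container {path} has no features group; run featurize first")
        g = f["features"]
        labels = np.array([
            l.decode() if isinstance(l, bytes) else str(l) for l in g["labels"][()]
        ], dtype=object)
        return FeatureSet(
            freq_maps=g["freq_maps"][()], scalars=g["scalars"][()],
            labels=labels, frame_times=g["frame_times"][()],
            channel_names=tuple(str(n) for n in g.attrs["channel_names"]),
            column_names=tuple(str(n) for n in g.attrs["column_names"]),
            subject_id=str(g.attrs["subject_id"]),
        )


def validate_container(path: str | Path, expect_features_width: int = 1397) -> list[str]:
    """Structural checks; returns a list of problems (empty = valid)."""
    problems: list[str] = []
    path = Path(path)
    if not path.exists():
        return [f"container {path} does not exist"]
    try:
        rec = load_recording(path, group="raw")
    except DataError as e:
        return [str(e)]
    expected_counts = {"eeg": 11, "ecg": 1, "pulse": 1, "spo2": 1}
    for key, n in expected_counts.items():
        if key not in rec.modalities:
            problems.append(f"missing modality {key!r}")
        elif rec.modalities[key].n_channels != n:
            problems.append(
                f"modality {key!r} has {rec.modalities[key].n_channels} channels, expected {n}"
            )
    if "eog_raw" in rec.modalities:
        if rec.modalities["eog_raw"].n_channels != 4:
            problems.append("eog_raw must have 4 electrodes")
    elif "eog" in rec.modalities:
        if rec.modalities["eog"].n_channels != 2:
            problems.append("eog must have 2 derived channels")
    else:
        problems.append("missing EOG modality")
    for mod in rec.modalities.values():
        if mod.fs <= 0:
            problems.append("non-positive sampling rate attribute")
    starts = [m.start_s for m in rec.markers]
    if sorted(starts) != starts:
        problems.append("state markers are not monotone in time")
    try:
        feats = load_features(path)
        if feats.n_features != expect_features_width:
            problems.append(
                f"feature width {feats.n_features}, expected {expect_features_width}"
            )
    except DataError:
        pass  # features are optional until the featurize stage has run
    return problems
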