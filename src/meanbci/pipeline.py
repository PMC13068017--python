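"""Stage functions tying the modules into one reproducible pipeline.

Each stage reads/writes the HDF5 container under ``config.outdir`` and is
callable from the CLI or directly from Python.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import container as cio
from .config import PipelineConfig
from .core import DataError
from .evaluate import CVReport, run_cv
from .features import WindowSpec, featurize_segments
from .model import AttentionClassifier, TrainConfig
from .morphology import flat_element
from .preprocess import FilterSpec, preprocess_recording, segment_by_markers
from .synth import SyntheticConfig, generate_recording

__all__ = [
    "stage_simulate",
    "stage_preprocess",
    "stage_featurize",
    "stage_train",
    "stage_evaluate",
    "stage_ablate",
    "stage_report",
]


def _train_config(cfg: PipelineConfig, seed: int | None = None) -> TrainConfig:
    m = cfg.model
    return TrainConfig(
        lr=m.lr, weight_decay=m.weight_decay, batch_size=m.batch_size,
        epochs=m.epochs, seed=cfg.seed if seed is None else seed,
    )


def stage_simulate(cfg: PipelineConfig) -> Path:
    cfg.write_resolved()
    s = cfg.synthgen
    mask = tuple(i < s.n_informative for i in range(s.n_eeg_channels))
    rec = generate_recording(
        SyntheticConfig(
            n_eeg_channels=s.n_eeg_channels, fs_raw=s.fs_raw, fs_aux=s.fs_aux,
            segment_duration_s=s.segment_duration_s, seed=cfg.seed,
            informative_channel_mask=mask,
        )
    )
    path = cfg.container_path()
    cio.save_recording(rec, path, group="raw")
    return path


def stage_preprocess(cfg: PipelineConfig) -> Path:
    path = cfg.container_path()
    if not path.exists():
        raise DataError(f"no container at {path}; run the simulate command first")
    rec = cio.load_recording(path, group="raw")
    p = cfg.preprocess
    out = preprocess_recording(
        rec,
        fs_target=p.fs_target,
        filter_spec=FilterSpec(
            notch_hz=p.notch_hz, band_low_hz=p.band_low_hz, band_high_hz=p.band_high_hz
        ),
        morph_element=flat_element(max(int(round(cfg.ecg_morph.element_s * p.fs_target)), 1)),
        hr_window_s=p.hr_window_s,
    )
    cio.save_recording(out, path, group="preprocessed")
    return path


def stage_featurize(cfg: PipelineConfig) -> Path:
    path = cfg.container_path()
    try:
        rec = cio.load_recording(path, group="preprocessed")
    except DataError as e:
        raise DataError(f"{e}; run the preprocess command first") from e
    target = cfg.preprocess.target_segment_s or cfg.synthgen.segment_duration_s
    segset = segment_by_markers(rec, target_duration_s=target)
    f = cfg.features
    fs = featurize_segments(
        segset,
        win=WindowSpec(width_s=f.width_s, step_s=f.step_s),
        bin_width_hz=f.bin_width_hz, f_max_hz=f.f_max_hz,
        smooth_frames=f.smooth_frames, subject_id=rec.subject_id,
    )
    cio.save_features(fs, path)
    pd.DataFrame({"column": fs.column_names}).to_csv(
        Path(cfg.outdir) / "feature-columns.csv", index=False
    )
    return path


def stage_train(cfg: PipelineConfig) -> Path:
    fs = cio.load_features(cfg.container_path())
    clf = AttentionClassifier(fs, arch=cfg.model.arch, config=_train_config(cfg))
    res = clf.fit()
    out = Path(cfg.outdir)
    res.save(out / "model.npz")
    (out / "training-history.json").write_text(json.dumps(res.history))
    (out / "model-summary.txt").write_text(res.summary() + "\n")
    return out / "model.npz"


def _write_cv(report: CVReport, outdir: Path, tag: str) -> None:
    report.records.to_csv(outdir / f"cv-records-{tag}.csv", index=False)
    report.per_class_table().to_csv(outdir / f"per-class-metrics-{tag}.csv", index=False)
    counts = report.confusion()
    (outdir / f"confusion-{tag}.json").write_text(
        json.dumps(
            {
                "class_order": list(counts.class_order),
                "matrix": counts.matrix.tolist(),
                "accuracy": report.metrics().accuracy,
                "accuracy_fold_std": report.accuracy_std,
            },
            indent=2,
        )
    )


def stage_evaluate(cfg: PipelineConfig) -> dict[str, CVReport]:
    fs = cio.load_features(cfg.container_path())
    out = Path(cfg.outdir)
    reports = {}
    for spec in cfg.eval.models:
        report = run_cv(
            fs, model_spec=spec, k=cfg.eval.k, reps=cfg.eval.reps,
            proportion=cfg.eval.proportion, seed=cfg.seed,
            train_config=_train_config(cfg),
        )
        _write_cv(report, out, spec)
        reports[spec] = report
    return reports


def stage_ablate(cfg: PipelineConfig) -> pd.DataFrame:
    fs = cio.load_features(cfg.container_path())
    rows = []
    for groups in cfg.eval.ablations:
        report = run_cv(
            fs, model_spec="svm", k=cfg.eval.k, reps=cfg.eval.reps,
            proportion=cfg.eval.proportion, modality_groups=groups, seed=cfg.seed,
        )
        rows.append({"modalities": "+".join(groups),
                     "accuracy_pct": round(100 * report.metrics().accuracy, 2)})
    frame = pd.DataFrame(rows)
    frame.to_csv(Path(cfg.outdir) / "ablation.csv", index=False)
    return frame


def stage_report(cfg: PipelineConfig) -> list[Path]:
    """Render figures/tables from stored artifacts (evaluate/train outputs)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(cfg.outdir)
    written: list[Path] = []
    for conf_file in sorted(out.glob("confusion-*.json")):
        payload = json.loads(conf_file.read_text())
        matrix = np.asarray(payload["matrix"], float)
        order = payload["class_order"]
        fig, ax = plt.subplots(figsize=(4, 3.5))
        im = ax.imshow(matrix, cmap="Blues")
        ax.set_xticks(range(len(order)), order)
        ax.set_yticks(range(len(order)), order)
        ax.set_xlabel("predicted")
        ax.set_ylabel("true")
        for i in range(len(order)):
            for j in range(len(order)):
                ax.text(j, i, int(matrix[i, j]), ha="center", va="center", fontsize=9)
        fig.colorbar(im)
        fig.tight_layout()
        png = conf_file.with_suffix(".png")
        fig.savefig(png, dpi=120)
        plt.close(fig)
        written.append(png)

    model_path = out / "model.npz"
    if model_path.exists():
        from .model import AttentionClassifierResults

        res = AttentionClassifierResults.load(model_path)
        fs = cio.load_features(cfg.container_path())
        weights = res.extract_channel_weights(fs)
        weights.to_csv(out / "channel-weights.csv")
        fig, ax = plt.subplots(figsize=(8, 3.5))
        ax.boxplot(
            [
                [weights.loc[name, q] for q in ("min", "q1", "median", "q3", "max")]
                for name in weights.index
            ],
            tick_labels=list(weights.index),
        )
        ax.set_ylabel("channel attention weight")
        ax.tick_params(axis="x", rotation=60)
        fig.tight_layout()
        fig.savefig(out / "channel-weights.png", dpi=120)
        plt.close(fig)
        written.append(out / "channel-weights.png")
    return written
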