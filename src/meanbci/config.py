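"""Nested pipeline configuration with strict (unknown-key rejecting) YAML
loading.  Every run writes the resolved configuration next to its outputs so
artifacts are reproducible from config + seed alone."""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .core import ConfigError

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class SynthSection:
    n_eeg_channels: int = 11
    fs_raw: float = 1000.0
    fs_aux: float = 80.0
    segment_duration_s: float = 600.0
    n_informative: int = 8  # leading EEG channels carrying class signal


@dataclass
class PreprocessSection:
    fs_target: float = 200.0
    notch_hz: float = 50.0
    band_low_hz: float = 2.0
    band_high_hz: float = 50.0
    hr_window_s: float = 5.0
    target_segment_s: float | None = None  # None -> synthgen segment duration


@dataclass
class MorphSection:
    element_s: float = 0.25  # flat structuring-element length in seconds


@dataclass
class FeatureSection:
    width_s: float = 9.0
    step_s: float = 1.0
    bin_width_hz: float = 1.0 / 3.0
    f_max_hz: float = 30.0
    smooth_frames: int = 3


@dataclass
class ModelSection:
    arch: str = "mean"
    lr: float = 1e-3
    weight_decay: float = 1e-4
    batch_size: int = 64
    epochs: int = 30


@dataclass
class EvalSection:
    k: int = 5
    reps: int = 5
    proportion: float = 0.8
    models: list[str] = field(default_factory=lambda: ["mean", "svm"])
    ablations: list[list[str]] = field(
        default_factory=lambda: [
            ["eeg"], ["eog"], ["ecg"],
            ["eeg", "eog"], ["eeg", "eog", "ecg"],
            ["eeg", "eog", "ecg", "pulse", "aux"],
        ]
    )


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "meanbci-out"
    synthgen: SynthSection = field(default_factory=SynthSection)
    preprocess: PreprocessSection = field(default_factory=PreprocessSection)
    ecg_morph: MorphSection = field(default_factory=MorphSection)
    features: FeatureSection = field(default_factory=FeatureSection)
    model: ModelSection = field(default_factory=ModelSection)
    eval: EvalSection = field(default_factory=EvalSection)

    def container_path(self) -> Path:
        return Path(self.outdir) / "container.h5"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def write_resolved(self) -> None:
        out = Path(self.outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.dump(out / "resolved-config.yaml")


_SECTIONS = {
    "synthgen": SynthSection,
    "preprocess": PreprocessSection,
    "ecg_morph": MorphSection,
    "features": FeatureSection,
    "model": ModelSection,
    "eval": EvalSection,
}


def _build(cls, data: dict, prefix: str, errors: list[str]):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    errors.extend(sorted(f"{prefix}{k}" for k in unknown))
    return cls(**{k: v for k, v in data.items() if k in known})


def config_from_dict(data: dict) -> PipelineConfig:
    errors: list[str] = []
    top_known = {"seed", "outdir"} | set(_SECTIONS)
    errors.extend(sorted(k for k in data if k not in top_known))
    kwargs: dict = {}
    for key in ("seed", "outdir"):
        if key in data:
            kwargs[key] = data[key]
    for name, cls in _SECTIONS.items():
        section = data.get(name, {})
        if not isinstance(section, dict):
            errors.append(name)
            continue
        kwargs[name] = _build(cls, section, f"{name}.", errors)
    if errors:
        raise ConfigError("unknown configuration keys: " + ", ".join(errors))
    return PipelineConfig(**kwargs)


def load_config(path: str | Path | None) -> PipelineConfig:
    if path is None:
        return PipelineConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ConfigError("config file must contain a mapping")
    return config_from_dict(data)
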