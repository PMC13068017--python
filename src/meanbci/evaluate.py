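"""Evaluation protocol: temporal five-fold cross-validation with
fixed-proportion resampling and repetitions, per-class confusion metrics,
baseline models and paired t-tests.

Folds are contiguous time blocks *within each class*, so training and test
instances are never temporally adjacent across the split; each fold x
repetition cycle randomly subsamples a fixed proportion of both train and
test sets before fitting.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .core import ConfigError, DataError, STATE_ORDER
from .features import FeatureSet
from .model import AttentionClassifier, TrainConfig

__all__ = [
    "FoldPlan",
    "ConfusionCounts",
    "ClassMetrics",
    "CVReport",
    "temporal_kfold",
    "subsample",
    "run_cv",
    "confusion_counts",
    "class_metrics",
    "paired_ttest",
    "MODALITY_GROUPS",
    "apply_modality_mask",
    "round_half_up",
]

MODEL_SPECS = ("mean", "cnn", "rnn", "lstm", "svm")

#: Channel-name groups for modality ablation. "aux" masks the two scalars.
MODALITY_GROUPS: dict[str, tuple[str, ...]] = {
    "eeg": ("F3", "Fz", "F4", "C3", "Cz", "C4", "T7", "T8", "P3", "Pz", "P4"),
    "eog": ("vEOG", "hEOG"),
    "ecg": ("ECG",),
    "pulse": ("Pulse",),
}


def round_half_up(x: float, decimals: int) -> float:
    """Decimal-style half-up rounding for report tables."""
    factor = 10.0**decimals
    return math.floor(x * factor + 0.5) / factor


def block_sizes(n: int, k: int) -> list[int]:
    """Split n into k contiguous block sizes; first n % k blocks one longer."""
    base, extra = divmod(n, k)
    return [base + (1 if i < extra else 0) for i in range(k)]


@dataclass
class FoldPlan:
    """Per-class contiguous time blocks assigned to folds 0..k-1."""

    k: int
    class_blocks: dict[str, list[np.ndarray]]  # label -> k arrays of global indices

    def test_indices(self, fold: int) -> np.ndarray:
        return np.concatenate([blocks[fold] for blocks in self.class_blocks.values()])

    def train_indices(self, fold: int) -> np.ndarray:
        parts = [
            blocks[j]
            for blocks in self.class_blocks.values()
            for j in range(self.k)
            if j != fold
        ]
        return np.concatenate(parts)


def temporal_kfold(labels: np.ndarray, frame_times: np.ndarray, k: int = 5) -> FoldPlan:
    """Per class, time-ordered indices split into k contiguous blocks."""
    if k < 2:
        raise ConfigError("k must be >= 2")
    labels = np.asarray(labels, dtype=object)
    class_blocks: dict[str, list[np.ndarray]] = {}
    for label in sorted(set(labels)):
        idx = np.flatnonzero(labels == label)
        idx = idx[np.argsort(frame_times[idx], kind="stable")]
        if idx.size < k:
            raise ConfigError(f"class {label!r} has {idx.size} instances, fewer than k={k}")
        sizes = block_sizes(idx.size, k)
        bounds = np.cumsum([0] + sizes)
        class_blocks[label] = [idx[bounds[j] : bounds[j + 1]] for j in range(k)]
    return FoldPlan(k=k, class_blocks=class_blocks)


def subsample(indices: np.ndarray, proportion: float, rng: np.random.Generator) -> np.ndarray:
    """Uniform without-replacement sample of ceil(p * n) indices."""
    if not 0 < proportion <= 1:
        raise ConfigError("proportion must lie in (0, 1]")
    n = indices.size
    m = int(np.ceil(proportion * n))
    if m >= n:
        return indices.copy()
    return rng.choice(indices, size=m, replace=False)


# ---------------------------------------------------------------------------
# confusion counts and metrics


@dataclass
class ConfusionCounts:
    """Per-class TP/FP/TN/FN and the full true x predicted matrix."""

    class_order: tuple[str, ...]
    matrix: np.ndarray  # rows true, cols predicted
    tp: dict[str, int]
    fp: dict[str, int]
    tn: dict[str, int]
    fn: dict[str, int]

    @property
    def total(self) -> int:
        return int(self.matrix.sum())


def confusion_counts(
    y: np.ndarray, y_pred: np.ndarray, class_order: tuple[str, ...] = STATE_ORDER
) -> ConfusionCounts:
    y = np.asarray(y, dtype=object)
    y_pred = np.asarray(y_pred, dtype=object)
    if y.shape != y_pred.shape or y.size == 0:
        raise DataError("labels and predictions must be equal-length and non-empty")
    bad = (set(y) | set(y_pred)) - set(class_order)
    if bad:
        raise DataError(f"labels outside the class set: {sorted(bad)}")
    c = len(class_order)
    matrix = np.zeros((c, c), dtype=int)
    lut = {lab: i for i, lab in enumerate(class_order)}
    for yi, pi in zip(y, y_pred):
        matrix[lut[yi], lut[pi]] += 1
    total = matrix.sum()
    tp, fp, tn, fn = {}, {}, {}, {}
    for i, lab in enumerate(class_order):
        tp[lab] = int(matrix[i, i])
        fp[lab] = int(matrix[:, i].sum() - matrix[i, i])
        fn[lab] = int(matrix[i, :].sum() - matrix[i, i])
        tn[lab] = int(total - tp[lab] - fp[lab] - fn[lab])
    return ConfusionCounts(tuple(class_order), matrix, tp, fp, tn, fn)


@dataclass
class ClassMetrics:
    """Per-class precision/recall/F1 plus overall accuracy."""

    class_order: tuple[str, ...]
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    accuracy: float
    degenerate: bool = False  # any zero-denominator metric was forced to 0

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "precision": self.precision,
                "recall": self.recall,
                "f1": self.f1,
            }
        ).loc[list(self.class_order)]


def class_metrics(counts: ConfusionCounts) -> ClassMetrics:
    precision, recall, f1 = {}, {}, {}
    degenerate = False

    def safe(num: float, den: float) -> float:
        nonlocal degenerate
        if den == 0:
            degenerate = True
            return 0.0
        return num / den

    for lab in counts.class_order:
        p = safe(counts.tp[lab], counts.tp[lab] + counts.fp[lab])
        r = safe(counts.tp[lab], counts.tp[lab] + counts.fn[lab])
        precision[lab] = p
        recall[lab] = r
        f1[lab] = safe(2 * p * r, p + r)
    accuracy = sum(counts.tp.values()) / counts.total
    if degenerate:
        warnings.warn("zero-denominator metric encountered; reported as 0", stacklevel=2)
    return ClassMetrics(counts.class_order, precision, recall, f1, accuracy, degenerate)


def paired_ttest(acc_a, acc_b) -> tuple[float, float]:
    """Two-sided paired t-test on per-subject accuracy lists."""
    a = np.asarray(acc_a, float)
    b = np.asarray(acc_b, float)
    if a.shape != b.shape or a.size < 2:
        raise DataError("accuracy lists must be equal-length with n >= 2")
    d = a - b
    if np.allclose(d.std(ddof=1), 0):
        raise DataError("zero-variance differences: paired t undefined")
    t, p = scipy.stats.ttest_rel(a, b)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# modality masking


def apply_modality_mask(fs: FeatureSet, groups: list[str] | None) -> FeatureSet:
    """Restrict a feature set to the named modality groups.

    ``groups=None`` keeps everything.  Scalars (SpO2/HR) are kept only when
    'aux' is included.
    """
    if groups is None:
        return fs
    unknown = set(groups) - (set(MODALITY_GROUPS) | {"aux"})
    if unknown:
        raise ConfigError(f"unknown modality groups: {sorted(unknown)}")
    names = [
        n for g in ("eeg", "eog", "ecg", "pulse") if g in groups
        for n in MODALITY_GROUPS[g] if n in fs.channel_names
    ]
    if not names:
        raise ConfigError("modality mask leaves no channels")
    return fs.select_channels(names, keep_scalars="aux" in groups)


# ---------------------------------------------------------------------------
# CV driver


def _fit_predict_cycle(
    fs: FeatureSet,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    model_spec: str,
    train_config: TrainConfig,
) -> np.ndarray:
    freq_tr, scal_tr = fs.freq_maps[train_idx], fs.scalars[train_idx]
    freq_te, scal_te = fs.freq_maps[test_idx], fs.scalars[test_idx]
    y_tr = fs.labels[train_idx]
    if model_spec == "svm":
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler
        from sklearn.svm import LinearSVC

        xtr = np.concatenate([freq_tr.reshape(len(train_idx), -1), scal_tr], axis=1)
        xte = np.concatenate([freq_te.reshape(len(test_idx), -1), scal_te], axis=1)
        clf = make_pipeline(StandardScaler(), LinearSVC(C=1.0, max_iter=5000))
        clf.fit(xtr, y_tr)
        return clf.predict(xte).astype(object)
    clf = AttentionClassifier(freq_tr, scal_tr, y_tr, arch=model_spec, config=train_config)
    return clf.fit().predict(freq_te, scal_te)


@dataclass
class CVReport:
    """Aggregated cross-validation predictions and derived summaries."""

    model_spec: str
    k: int
    reps: int
    proportion: float
    records: pd.DataFrame  # fold, rep, n_test, accuracy
    y_true: np.ndarray
    y_pred: np.ndarray
    class_order: tuple[str, ...] = STATE_ORDER

    @property
    def n_cycles(self) -> int:
        return len(self.records)

    def fold_accuracies(self) -> np.ndarray:
        return self.records.groupby("fold")["accuracy"].mean().to_numpy()

    @property
    def accuracy_mean(self) -> float:
        return float(self.fold_accuracies().mean())

    @property
    def accuracy_std(self) -> float:
        fa = self.fold_accuracies()
        return float(fa.std(ddof=1)) if fa.size > 1 else 0.0

    def confusion(self) -> ConfusionCounts:
        return confusion_counts(self.y_true, self.y_pred, self.class_order)

    def metrics(self) -> ClassMetrics:
        return class_metrics(self.confusion())

    def per_class_table(self) -> pd.DataFrame:
        """Counts and metrics per class, rounded the way report tables print
        them (4 decimals on metrics)."""
        counts = self.confusion()
        m = class_metrics(counts)
        rows = []
        for lab in self.class_order:
            rows.append(
                {
                    "class": lab,
                    "TP": counts.tp[lab],
                    "TN": counts.tn[lab],
                    "FP": counts.fp[lab],
                    "FN": counts.fn[lab],
                    "precision": round_half_up(m.precision[lab], 4),
                    "recall": round_half_up(m.recall[lab], 4),
                    "f1": round_half_up(m.f1[lab], 4),
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        m = self.metrics()
        lines = [
            f"Cross-validation report ({self.model_spec})",
            "=" * 44,
            f"folds x reps:      {self.k} x {self.reps} = {self.n_cycles} cycles",
            f"sample proportion: {self.proportion}",
            f"predictions:       {len(self.y_true)}",
            f"accuracy:          {round_half_up(100 * m.accuracy, 2):.2f}%"
            f" (fold std {round_half_up(100 * self.accuracy_std, 2):.2f}%)",
            "",
            self.per_class_table().to_string(index=False),
        ]
        return "\n".join(lines)


def run_cv(
    fs: FeatureSet,
    model_spec: str = "mean",
    k: int = 5,
    reps: int = 5,
    proportion: float = 0.8,
    modality_groups: list[str] | None = None,
    seed: int = 0,
    train_config: TrainConfig | None = None,
) -> CVReport:
    """Temporal k-fold CV with per-cycle fixed-proportion resampling.

    Each of the k folds is repeated ``reps`` times with a fresh subsample of
    both train and test indices; predictions from all cycles are aggregated.
    """
    if model_spec not in MODEL_SPECS:
        raise ConfigError(f"unknown model spec {model_spec!r}; expected one of {MODEL_SPECS}")
    fs = apply_modality_mask(fs, modality_groups)
    plan = temporal_kfold(fs.labels, fs.frame_times, k)
    base_cfg = train_config or TrainConfig()

    rows = []
    ys, yhats = [], []
    for fold in range(k):
        tr_all = plan.train_indices(fold)
        te_all = plan.test_indices(fold)
        for rep in range(reps):
            cycle_seed = (seed * 100003 + fold * 101 + rep) % (2**31 - 1)
            rng = np.random.default_rng(cycle_seed)
            tr = subsample(tr_all, proportion, rng)
            te = subsample(te_all, proportion, rng)
            cfg = TrainConfig(
                lr=base_cfg.lr, weight_decay=base_cfg.weight_decay,
                batch_size=base_cfg.batch_size, epochs=base_cfg.epochs,
                seed=cycle_seed,
            )
            pred = _fit_predict_cycle(fs, tr, te, model_spec, cfg)
            truth = fs.labels[te]
            acc = float(np.mean(pred == truth))
            rows.append({"fold": fold, "rep": rep, "n_test": te.size, "accuracy": acc})
            ys.append(truth)
            yhats.append(pred)
    return CVReport(
        model_spec=model_spec, k=k, reps=reps, proportion=proportion,
        records=pd.DataFrame(rows),
        y_true=np.concatenate(ys), y_pred=np.concatenate(yhats),
    )
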