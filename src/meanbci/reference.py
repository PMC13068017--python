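"""Published benchmark tables from a 10-subject, three-state attention study.

These tables are reference *inputs*: the per-class confusion counts let the
metric code be validated against independently computed precision/recall/F1
values, and the per-subject accuracies feed the paired-test and
accuracy-consistency checks.  Nothing here is produced by this package.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .core import STATE_ORDER

__all__ = [
    "CONFUSION_COUNTS",
    "PRINTED_METRICS",
    "INSTANCES_PER_CLASS",
    "TOTAL_INSTANCES",
    "MODEL_ACCURACY_PCT",
    "confusion_frame",
]

#: Per subject and state: aggregated TP, TN, FP, FN over all CV cycles.
CONFUSION_COUNTS: dict[str, dict[str, tuple[int, int, int, int]]] = {
    "S1": {"high": (3768, 7219, 117, 41), "medium": (3693, 7092, 110, 250), "low": (3314, 7609, 143, 79)},
    "S2": {"high": (3776, 8161, 51, 117), "medium": (4209, 7522, 314, 60), "low": (3739, 8146, 16, 204)},
    "S3": {"high": (3824, 7904, 67, 105), "medium": (3941, 7706, 159, 94), "low": (3877, 7932, 32, 59)},
    "S4": {"high": (6725, 10522, 12, 11), "medium": (6323, 10892, 33, 22), "low": (4167, 13071, 10, 22)},
    "S5": {"high": (3989, 7742, 52, 57), "medium": (3849, 7903, 48, 40), "low": (3860, 7893, 42, 45)},
    "S6": {"high": (4602, 8817, 141, 145), "medium": (4644, 8739, 184, 138), "low": (4041, 9436, 93, 135)},
    "S7": {"high": (4558, 9346, 101, 1010), "medium": (5460, 9161, 264, 130), "low": (3853, 10379, 779, 4)},
    "S8": {"high": (5321, 9393, 62, 79), "medium": (5462, 9048, 111, 234), "low": (3718, 10915, 181, 41)},
    "S9": {"high": (4825, 8876, 278, 221), "medium": (4125, 9038, 750, 287), "low": (3941, 9177, 281, 801)},
    "S10": {"high": (3577, 7395, 1057, 681), "medium": (3260, 7758, 679, 1013), "low": (3944, 8338, 193, 235)},
}

#: The precision/recall/F1 values printed alongside those counts.
PRINTED_METRICS: dict[str, dict[str, tuple[float, float, float]]] = {
    "S1": {"high": (0.9699, 0.9892, 0.9795), "medium": (0.9711, 0.9366, 0.9535), "low": (0.9586, 0.9767, 0.9676)},
    "S2": {"high": (0.9867, 0.9699, 0.9782), "medium": (0.9306, 0.9859, 0.9575), "low": (0.9957, 0.9483, 0.9714)},
    "S3": {"high": (0.9828, 0.9733, 0.9780), "medium": (0.9612, 0.9767, 0.9689), "low": (0.9918, 0.9850, 0.9884)},
    "S4": {"high": (0.9982, 0.9984, 0.9983), "medium": (0.9948, 0.9965, 0.9957), "low": (0.9976, 0.9947, 0.9962)},
    "S5": {"high": (0.9871, 0.9859, 0.9865), "medium": (0.9877, 0.9897, 0.9887), "low": (0.9892, 0.9885, 0.9889)},
    "S6": {"high": (0.9703, 0.9695, 0.9699), "medium": (0.9619, 0.9711, 0.9665), "low": (0.9775, 0.9677, 0.9726)},
    "S7": {"high": (0.9783, 0.8186, 0.8914), "medium": (0.9539, 0.9767, 0.9652), "low": (0.8318, 0.9990, 0.9078)},
    "S8": {"high": (0.9885, 0.9854, 0.9869), "medium": (0.9801, 0.9589, 0.9694), "low": (0.9536, 0.9891, 0.9710)},
    "S9": {"high": (0.9455, 0.9562, 0.9508), "medium": (0.8462, 0.9350, 0.8883), "low": (0.9334, 0.8311, 0.8793)},
    "S10": {"high": (0.7719, 0.8401, 0.8045), "medium": (0.8276, 0.7629, 0.7940), "low": (0.9533, 0.9438, 0.9485)},
}

#: Aggregated instances per class (high, medium, low) per subject.
INSTANCES_PER_CLASS: dict[str, tuple[int, int, int]] = {
    "S1": (3809, 3943, 3393),
    "S2": (3893, 4269, 3943),
    "S3": (3929, 4035, 3936),
    "S4": (6736, 6345, 4189),
    "S5": (4046, 3889, 3905),
    "S6": (4747, 4782, 4176),
    "S7": (5568, 5590, 3857),
    "S8": (5400, 5696, 3759),
    "S9": (5046, 4412, 4742),
    "S10": (4258, 4273, 4179),
}

TOTAL_INSTANCES: dict[str, int] = {s: sum(v) for s, v in INSTANCES_PER_CLASS.items()}

#: Per-subject accuracy (%) of each classifier in the benchmark comparison.
MODEL_ACCURACY_PCT: pd.DataFrame = pd.DataFrame(
    {
        "CNN": [91.41, 87.56, 87.26, 98.73, 94.82, 94.01, 88.99, 96.53, 84.61, 79.30],
        "RNN": [92.55, 91.96, 91.80, 80.57, 94.39, 84.88, 84.15, 90.70, 82.02, 73.50],
        "LSTM": [89.58, 92.45, 93.71, 97.42, 92.83, 87.06, 86.88, 90.19, 82.60, 73.81],
        "SVM": [91.00, 93.17, 93.85, 99.66, 94.20, 96.17, 91.84, 96.59, 86.41, 82.18],
        "MEAN": [96.68, 96.86, 97.83, 99.68, 98.80, 96.95, 92.39, 97.61, 90.79, 84.83],
    },
    index=[f"S{i}" for i in range(1, 11)],
)


def confusion_frame() -> pd.DataFrame:
    """Long-format frame of the reference counts and printed metrics."""
    rows = []
    for subject, states in CONFUSION_COUNTS.items():
        for state in STATE_ORDER:
            tp, tn, fp, fn = states[state]
            p, r, f1 = PRINTED_METRICS[subject][state]
            rows.append(
                dict(subject=subject, state=state, TP=tp, TN=tn, FP=fp, FN=fn,
                     precision=p, recall=r, f1=f1)
            )
    return pd.DataFrame(rows)
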