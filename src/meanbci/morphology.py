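"""Grey-scale morphological operators and the ECG baseline-wander estimator.

A flat (all-zero) structuring element much shorter than the wander period but
longer than a QRS complex lets opening/closing strip the beat complexes while
following the slow drift.  The baseline is estimated in two averaging stages:

    f_b        = (close(open(f)) + open(close(f))) / 2
    f_baseline = (close(open(f_b)) + open(close(f_b))) / 2

and subtracted from the signal.  The erosion/dilation primitives are defined
on valid index ranges only; results are edge-replicated back to the input
length so the compositions are length-stable (values near the edges are
therefore approximate).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .core import DataError, Signal

__all__ = [
    "StructuringElement",
    "BaselineDecomposition",
    "flat_element",
    "erode",
    "dilate",
    "opening",
    "closing",
    "morphology",
    "estimate_baseline",
]


@dataclass(frozen=True)
class StructuringElement:
    """Linear structuring element k(m), m = 0..M-1."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 1:
            raise DataError("structuring element must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(v)):
            raise DataError("structuring element contains non-finite values")
        object.__setattr__(self, "values", v)

    @property
    def m(self) -> int:
        return int(self.values.size)


def flat_element(length: int) -> StructuringElement:
    """All-zero element of the given length (the default shape)."""
    if length < 1:
        raise DataError("element length must be >= 1")
    return StructuringElement(np.zeros(length))


def _check(f: np.ndarray, k: StructuringElement) -> None:
    if k.m > f.size:
        raise DataError(f"element length {k.m} exceeds signal length {f.size}")
    if not np.all(np.isfinite(f)):
        raise DataError("signal contains non-finite values")


def _erode_core(f: np.ndarray, k: StructuringElement) -> np.ndarray:
    # (f Θ k)(n) = min_m f(n+m) - k(m), n = 0..N-M
    windows = sliding_window_view(f, k.m)
    return np.min(windows - k.values, axis=1)


def _dilate_core(f: np.ndarray, k: StructuringElement) -> np.ndarray:
    # (f ⊕ k)(n) = max_m f(n-m) + k(m), n = M-1..N-1
    windows = sliding_window_view(f, k.m)
    return np.max(windows + k.values[::-1], axis=1)


def erode(f: np.ndarray, k: StructuringElement) -> np.ndarray:
    """Erosion, edge-replicated to input length (core occupies the left)."""
    f = np.asarray(f, dtype=float)
    _check(f, k)
    core = _erode_core(f, k)
    return np.concatenate([core, np.full(k.m - 1, core[-1])])


def dilate(f: np.ndarray, k: StructuringElement) -> np.ndarray:
    """Dilation, edge-replicated to input length (core occupies the right)."""
    f = np.asarray(f, dtype=float)
    _check(f, k)
    core = _dilate_core(f, k)
    return np.concatenate([np.full(k.m - 1, core[0]), core])


def opening(f: np.ndarray, k: StructuringElement) -> np.ndarray:
    """Opening: erosion then dilation; suppresses narrow peaks."""
    return dilate(erode(f, k), k)


def closing(f: np.ndarray, k: StructuringElement) -> np.ndarray:
    """Closing: dilation then erosion; fills narrow valleys."""
    return erode(dilate(f, k), k)


_OPS = {"erode": erode, "dilate": dilate, "open": opening, "close": closing}


def morphology(signal: Signal, k: StructuringElement, op: str) -> Signal:
    """Apply one of the four morphological operators to a signal."""
    if op not in _OPS:
        raise DataError(f"unknown operator {op!r}; expected one of {sorted(_OPS)}")
    return signal.copy_with(_OPS[op](signal.samples, k))


@dataclass
class BaselineDecomposition:
    """Exact additive split of an ECG into baseline and corrected signal."""

    baseline: Signal
    corrected: Signal
    intermediate: Signal  # first-stage average f_b


def default_element(fs: float, width_s: float = 0.25) -> StructuringElement:
    """Flat element of 0.25 s: longer than a QRS (~0.1 s), far shorter than
    wander periods (> 1 s)."""
    return flat_element(max(int(round(width_s * fs)), 1))


def estimate_baseline(signal: Signal, k: StructuringElement | None = None) -> BaselineDecomposition:
    """Two-stage averaged opening/closing baseline estimate.

    ``corrected + baseline`` reproduces the input exactly by construction.
    """
    if k is None:
        k = default_element(signal.fs)
    f = signal.samples

    def stage(x: np.ndarray) -> np.ndarray:
        return (closing(opening(x, k), k) + opening(closing(x, k), k)) / 2.0

    fb = stage(f)
    baseline = stage(fb)
    return BaselineDecomposition(
        baseline=signal.copy_with(baseline, channel_name=signal.channel_name + "-baseline"),
        corrected=signal.copy_with(f - baseline),
        intermediate=signal.copy_with(fb, channel_name=signal.channel_name + "-fb"),
    )
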