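"""Threshold calibration against manual per-second scores.

Manual scorers lag instantaneous behavioral-state changes by roughly
1–3 s, so seconds near label transitions are systematically mislabeled.
Calibration therefore (1) splits videos into calibration/validation
sets, (2) removes k seconds on each side of every label transition,
(3) sweeps candidate Δ-area thresholds over the observed values to build
an ROC curve (positive class = immobile, predicted positive when the
trace value is strictly below the candidate threshold), and (4) picks
the cut-point c* maximizing Sensitivity(c) × Specificity(c).

Because the threshold grid is exactly the set of distinct observed
values (plus sentinels below the minimum and above the maximum), the
trapezoidal AUC equals the Mann–Whitney pair-ordering probability with
ties counted 1/2, and c* does not depend on any sweep step size.

The shipped default thresholds are the recommended calibrated values for
each assay (2.5861 %Δ-area for the forced swim test, 0.7808 for the tail
suspension test, both obtained with a 3-s exclusion window and a 60%
calibration split); they apply when no calibration of one's own is run.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_THRESHOLDS",
    "DEFAULT_EXCLUSION_K",
    "DEFAULT_CALIBRATION_FRACTION",
    "LabeledSeconds",
    "ROCCurve",
    "CalibrationResult",
    "split_calibration",
    "exclude_transitions",
    "roc_curve",
    "optimum_cutpoint",
    "load_manual_labels",
    "calibrate_pooled",
]

#: Recommended per-second Δ-area % thresholds per assay (3-s exclusion).
DEFAULT_THRESHOLDS: dict[str, float] = {"FST": 2.5861, "TST": 0.7808}
#: Seconds removed on each side of every manual-label transition.
DEFAULT_EXCLUSION_K: int = 3
#: Fraction of videos assigned to the calibration set.
DEFAULT_CALIBRATION_FRACTION: float = 0.60


class SingleClassError(ValueError):
    """The kept seconds contain only one class; no ROC can be built."""


class LabelFileError(ValueError):
    """Base class for malformed manual-label CSV files."""


class LabelGapError(LabelFileError):
    """second_index values are not contiguous from 0."""


class LabelDuplicateError(LabelFileError):
    """A second_index occurs more than once."""


class NonBinaryLabelError(LabelFileError):
    """A label outside {0, 1} was found."""


@dataclass
class LabeledSeconds:
    """Pooled per-second trace values with manual labels and the kept mask
    left after transition exclusion."""

    trace_values: np.ndarray
    labels: np.ndarray
    kept: np.ndarray

    def __post_init__(self) -> None:
        self.trace_values = np.asarray(self.trace_values, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        self.kept = np.asarray(self.kept, dtype=bool)
        if not len(self.trace_values) == len(self.labels) == len(self.kept):
            raise ValueError("trace_values, labels and kept must align")

    @classmethod
    def pooled(
        cls,
        traces: Sequence[Sequence[float]],
        labels: Sequence[Sequence[int]],
        k: int = DEFAULT_EXCLUSION_K,
    ) -> "LabeledSeconds":
        """Pool several videos' (trace, manual labels) pairs, applying the
        transition exclusion per video before pooling."""
        if len(traces) != len(labels):
            raise ValueError("need one label vector per trace")
        tv, lv, kv = [], [], []
        for t, l in zip(traces, labels):
            t = np.asarray(t, dtype=np.float64)
            l = np.asarray(l, dtype=np.int8)
            n = min(len(t), len(l))  # manual files may run a second short
            t, l = t[:n], l[:n]
            keep = exclude_transitions(l, k) & ~np.isnan(t)
            tv.append(t)
            lv.append(l)
            kv.append(keep)
        return cls(
            trace_values=np.concatenate(tv),
            labels=np.concatenate(lv),
            kept=np.concatenate(kv),
        )


@dataclass(frozen=True)
class ROCCurve:
    """ROC over the candidate-threshold grid (ascending)."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float


@dataclass(frozen=True)
class CalibrationResult:
    optimum_threshold: float
    auc: float
    exclusion_k: int
    metric_mode: str = "area"

    def to_json_dict(self) -> dict:
        return {
            "optimum_threshold": self.optimum_threshold,
            "auc": self.auc,
            "exclusion_k": self.exclusion_k,
            "metric_mode": self.metric_mode,
        }


def split_calibration(
    videos: Sequence, fraction: float = DEFAULT_CALIBRATION_FRACTION, seed: int = 0
) -> tuple[list, list]:
    """Deterministically shuffle and split videos into (calibration,
    validation) sets with round(fraction * n) calibration members."""
    if len(videos) < 2:
        raise ValueError("need at least 2 videos to split")
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie strictly between 0 and 1")
    order = np.random.default_rng(seed).permutation(len(videos))
    n_cal = int(np.floor(fraction * len(videos) + 0.5))
    n_cal = min(max(n_cal, 1), len(videos) - 1)  # both sets non-empty
    cal = [videos[i] for i in order[:n_cal]]
    val = [videos[i] for i in order[n_cal:]]
    return cal, val


def exclude_transitions(labels: Sequence[int], k: int) -> np.ndarray:
    """Boolean kept-mask after removing k seconds on each side of every
    label transition.

    A transition between seconds t−1 and t removes seconds t−k..t−1 and
    t..t+k−1 (clipped to range).  k = 0 keeps everything.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    labels = np.asarray(labels)
    kept = np.ones(len(labels), dtype=bool)
    if k == 0 or len(labels) < 2:
        return kept
    boundaries = np.flatnonzero(np.diff(labels)) + 1  # transition at t
    for t in boundaries:
        kept[max(0, t - k) : min(len(labels), t + k)] = False
    return kept


def roc_curve(data: LabeledSeconds) -> ROCCurve:
    """Build the ROC curve over the grid of observed kept trace values.

    Sensitivity(c) = TP/(TP+FN) and Specificity(c) = TN/(TN+FP) with
    positive = immobile and predicted positive when value < c.  AUC is
    the trapezoidal integral over (1 − specificity, sensitivity).
    """
    v = data.trace_values[data.kept]
    y = data.labels[data.kept]
    if v.size == 0 or y.min() == y.max():
        raise SingleClassError(
            "kept seconds must contain both mobile and immobile examples"
        )
    vals = np.unique(v)
    grid = np.concatenate(([vals[0] - 1.0], vals, [vals[-1] + 1.0]))
    imm = np.sort(v[y == 1])
    mob = np.sort(v[y == 0])
    tp = np.searchsorted(imm, grid, side="left")  # immobile values < c
    fp = np.searchsorted(mob, grid, side="left")
    sens = tp / imm.size
    spec = (mob.size - fp) / mob.size
    auc = float(np.trapezoid(sens, 1.0 - spec))
    return ROCCurve(
        thresholds=grid, sensitivity=sens, specificity=spec, auc=auc
    )


def optimum_cutpoint(
    roc: ROCCurve,
    exclusion_k: int = DEFAULT_EXCLUSION_K,
    metric_mode: str = "area",
) -> CalibrationResult:
    """Cut-point c* maximizing Sensitivity(c) × Specificity(c); ties break
    toward the smaller threshold (the grid is ascending and argmax takes
    the first maximum)."""
    if roc.thresholds.size == 0:
        raise ValueError("empty ROC curve")
    product = roc.sensitivity * roc.specificity
    best = int(np.argmax(product))
    return CalibrationResult(
        optimum_threshold=float(roc.thresholds[best]),
        auc=roc.auc,
        exclusion_k=exclusion_k,
        metric_mode=metric_mode,
    )


def load_manual_labels(path: str | Path) -> np.ndarray:
    """Read a manual-score CSV (columns second_index, label; 1 = immobile)
    into a validated 0/1 vector, contiguous from second 0."""
    df = pd.read_csv(path)
    missing = {"second_index", "label"} - set(df.columns)
    if missing:
        raise LabelFileError(f"{path}: missing column(s) {sorted(missing)}")
    idx = df["second_index"].to_numpy()
    labels = df["label"].to_numpy()
    dup = pd.Series(idx).duplicated()
    if dup.any():
        raise LabelDuplicateError(
            f"{path}: duplicate second_index {int(idx[dup.argmax()])}"
        )
    expected = np.arange(len(idx))
    if not np.array_equal(np.sort(idx), expected):
        raise LabelGapError(f"{path}: second_index must be contiguous from 0")
    order = np.argsort(idx)
    labels = labels[order]
    if not np.isin(labels, (0, 1)).all():
        bad = labels[~np.isin(labels, (0, 1))][0]
        raise NonBinaryLabelError(f"{path}: label {bad!r} is not 0 or 1")
    return labels.astype(np.int8)


def calibrate_pooled(
    traces: Sequence[Sequence[float]],
    labels: Sequence[Sequence[int]],
    k: int = DEFAULT_EXCLUSION_K,
    metric_mode: str = "area",
) -> tuple[CalibrationResult, ROCCurve]:
    """Pool (trace, manual-label) pairs, exclude transitions, and return
    the calibrated threshold with its ROC curve."""
    data = LabeledSeconds.pooled(traces, labels, k=k)
    roc = roc_curve(data)
    return optimum_cutpoint(roc, exclusion_k=k, metric_mode=metric_mode), roc
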