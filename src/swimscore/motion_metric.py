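"""Per-second motion statistic and immobility classification.

The default statistic is the Δ-area %: the unsigned change in binarized
animal area between consecutive frames, as a percentage of the previous
frame's area, averaged within each second.  Object-length change and
frame-by-frame variation (XOR pixel count) are available as alternative
modes; Δ-area is the one validated for both the swim and the suspension
test.

A second is immobile when its mean Δ value falls strictly below the
threshold; a value exactly at the threshold counts as mobile.  The
absolute difference is used — signed changes would cancel within a
second and stop measuring motion magnitude.  The per-frame ratio uses
the previous *frame's* feature as denominator; a per-second denominator
(mean area of the previous second) is exposed as ``denominator`` for
experimentation but is not the validated default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .segmentation import BinaryMask

__all__ = [
    "FrameFeatureSeries",
    "MotionTrace",
    "ImmobilityTrack",
    "frame_percent_change",
    "per_second_average",
    "classify_immobility",
]

MetricMode = Literal["area", "length", "variation"]


class AllEmptyError(ValueError):
    """Every analyzed frame had an empty mask; no motion can be measured."""


@dataclass(frozen=True)
class FrameFeatureSeries:
    """One feature value per analyzed frame (area A(t), major-axis length,
    or any non-negative per-frame scalar) plus the frame rate."""

    values: np.ndarray
    fps: float

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "values", np.asarray(self.values, dtype=np.float64)
        )
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.values.ndim != 1:
            raise ValueError("feature series must be one-dimensional")
        if np.any(self.values < 0):
            raise ValueError("feature values must be non-negative")


@dataclass
class MotionTrace:
    """Per-second motion statistic for one analyzed video segment.

    Invalid seconds (no valid frame ratio, e.g. the animal was lost) are
    stored as NaN and reported through :attr:`valid`.
    """

    values: np.ndarray
    metric_mode: MetricMode = "area"
    threshold_used: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def valid(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"second_index": np.arange(len(self.values)), "value": self.values}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "MotionTrace":
        df = pd.read_csv(path)
        return cls(values=df["value"].to_numpy(dtype=np.float64), **kwargs)


@dataclass
class ImmobilityTrack:
    """Per-second binary classification: 1 = immobile, 0 = mobile."""

    labels: np.ndarray
    source: Literal["automatic", "manual"] = "automatic"
    #: seconds whose label was inherited because the trace was invalid there
    flagged: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be 0 or 1")
        if self.flagged is None:
            self.flagged = np.zeros(len(self.labels), dtype=bool)
        else:
            self.flagged = np.asarray(self.flagged, dtype=bool)

    def __len__(self) -> int:
        return len(self.labels)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"second_index": np.arange(len(self.labels)), "label": self.labels}
        ).to_csv(path, index=False)


def frame_percent_change(
    series: FrameFeatureSeries,
    mode: MetricMode = "area",
    masks: Sequence[BinaryMask] | Sequence[np.ndarray] | None = None,
) -> np.ndarray:
    """Per-frame percentage change for frames t = 1..N−1.

    area / length mode:  100 · |x(t) − x(t−1)| / x(t−1)
    variation mode:      100 · XOR(mask_t, mask_{t−1}) / A(t−1)

    The output has length N−1 and is aligned to frame t (entry 0 is the
    change into frame 1).  Where the previous frame's feature is zero the
    ratio is undefined and the entry is NaN; if every previous-frame
    feature is zero an :class:`AllEmptyError` is raised.
    """
    x = series.values
    if len(x) < 2:
        raise ValueError("need at least two frames to compute changes")
    prev = x[:-1]
    if np.all(prev == 0):
        raise AllEmptyError("all previous-frame features are zero (empty masks)")
    out = np.full(len(x) - 1, np.nan)
    ok = prev > 0
    if mode in ("area", "length"):
        cur = x[1:]
        out[ok] = 100.0 * np.abs(cur[ok] - prev[ok]) / prev[ok]
    elif mode == "variation":
        if masks is None or len(masks) != len(x):
            raise ValueError("variation mode needs one mask per frame")
        pix = [m.pixels if isinstance(m, BinaryMask) else np.asarray(m) for m in masks]
        for t in range(1, len(pix)):
            if prev[t - 1] > 0:
                xor = np.logical_xor(pix[t], pix[t - 1]).sum()
                out[t - 1] = 100.0 * xor / prev[t - 1]
    else:
        raise ValueError(f"unknown metric mode {mode!r}")
    return out


def _second_frame_bounds(s: int, fps: float) -> tuple[int, int]:
    # half-open [s*fps, (s+1)*fps), boundaries rounded to the nearest frame
    lo = int(np.floor(s * fps + 0.5))
    hi = int(np.floor((s + 1) * fps + 0.5))
    return lo, hi


def per_second_average(
    per_frame: np.ndarray,
    fps: float,
    n_seconds: int,
    metric_mode: MetricMode = "area",
) -> MotionTrace:
    """Average the per-frame percentage changes within each second.

    ``per_frame`` is aligned to frames 1..N−1 (entry t−1 belongs to frame
    t).  Second ``s`` averages frames in [s·fps, (s+1)·fps); frame 0 has
    no predecessor and NaN entries are skipped.  A second with no valid
    frame is itself NaN (invalid).
    """
    if n_seconds < 1:
        raise ValueError("n_seconds must be >= 1")
    per_frame = np.asarray(per_frame, dtype=np.float64)
    n_frames = len(per_frame) + 1
    if _second_frame_bounds(n_seconds - 1, fps)[1] > n_frames:
        raise ValueError(
            f"{n_seconds} seconds at {fps} fps need more than {n_frames} frames"
        )
    values = np.full(n_seconds, np.nan)
    for s in range(n_seconds):
        lo, hi = _second_frame_bounds(s, fps)
        lo = max(lo, 1)  # frame 0 has no predecessor
        window = per_frame[lo - 1 : hi - 1]
        window = window[~np.isnan(window)]
        if window.size:
            values[s] = window.mean()
    return MotionTrace(values=values, metric_mode=metric_mode)


def classify_immobility(trace: MotionTrace, threshold: float) -> ImmobilityTrack:
    """Label each second 1 (immobile) when its value is strictly below the
    threshold, else 0.  Invalid (NaN) seconds inherit the previous second's
    label — mobile for a leading invalid second — and are flagged."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    values = trace.values
    labels = np.zeros(len(values), dtype=np.int8)
    flagged = np.zeros(len(values), dtype=bool)
    prev = 0
    for i, v in enumerate(values):
        if np.isnan(v):
            labels[i] = prev
            flagged[i] = True
        else:
            labels[i] = 1 if v < threshold else 0
        prev = labels[i]
    track = ImmobilityTrack(labels=labels, source="automatic", flagged=flagged)
    trace.threshold_used = threshold
    return track
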