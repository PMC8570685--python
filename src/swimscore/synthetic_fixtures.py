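"""Ground-truthed synthetic test videos.

Renders a high-contrast elliptical "animal" on a bright background
following a known per-second mobility schedule, and simulates manual
scorers whose key presses lag behavioral-state changes by 1–3 s.  The
fixtures emulate the acquisition conditions the method was validated
under — 15 fps, 5-minute tests, a dark animal on a uniform bright
background — without water, ripples, reflections or tail artifacts.

Motion model: during mobile seconds the blob performs an integer-pixel
random walk (so translation alone changes no rasterized pixels' count
but drives the frame-by-frame variation metric) and its horizontal
semi-axis oscillates sinusoidally (area-preserving in the mean), which
drives the Δ-area statistic well above the immobility thresholds.
During immobile seconds the blob is static up to a configurable residual
jitter and the pixel noise of the camera.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.draw import ellipse as draw_ellipse

from ._rawavi import RawAviWriter

__all__ = [
    "SyntheticSchedule",
    "LagModel",
    "render_video",
    "simulate_human_labels",
]


@dataclass(frozen=True)
class SyntheticSchedule:
    """Per-second ground-truth mobility plan.

    states holds one entry per second: 1 = immobile, 0 = mobile (the
    manual-score convention).  Jitter amplitudes are per-frame integer
    displacement bounds; deform_frac is the fractional amplitude of the
    sinusoidal axis oscillation during mobile seconds.
    """

    states: tuple[int, ...]
    mobile_jitter_px: int = 3
    immobile_jitter_px: int = 0
    deform_frac: float = 0.25

    def __post_init__(self) -> None:
        states = tuple(int(s) for s in self.states)
        if not states:
            raise ValueError("schedule must cover at least one second")
        if any(s not in (0, 1) for s in states):
            raise ValueError("states must be 0 (mobile) or 1 (immobile)")
        if self.mobile_jitter_px < 0 or self.immobile_jitter_px < 0:
            raise ValueError("jitter amplitudes must be non-negative")
        if self.immobile_jitter_px >= max(self.mobile_jitter_px, 1):
            raise ValueError("immobile jitter must be below mobile jitter")
        object.__setattr__(self, "states", states)

    @property
    def duration_s(self) -> int:
        return len(self.states)

    def truth_labels(self) -> np.ndarray:
        """Per-second 0/1 ground truth (1 = immobile)."""
        return np.asarray(self.states, dtype=np.int8)

    @classmethod
    def alternating(
        cls,
        total_s: int = 300,
        period_s: int = 20,
        start_immobile: bool = False,
        **kwargs,
    ) -> "SyntheticSchedule":
        """Blocks of `period_s` seconds alternating mobile/immobile."""
        states = [
            (s // period_s + int(start_immobile)) % 2 for s in range(total_s)
        ]
        return cls(states=tuple(states), **kwargs)

    @classmethod
    def constant(cls, total_s: int, immobile: bool, **kwargs) -> "SyntheticSchedule":
        return cls(states=(int(immobile),) * total_s, **kwargs)


@dataclass(frozen=True)
class LagModel:
    """Uniform integer reaction lag (in seconds) applied independently at
    every state transition; 1–3 s matches trained human scorers."""

    low_s: int = 1
    high_s: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.low_s < 0 or self.high_s < self.low_s:
            raise ValueError("need 0 <= low_s <= high_s")

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.integers(self.low_s, self.high_s + 1, size=n)


def render_video(
    schedule: SyntheticSchedule,
    out_path: str | Path,
    fps: float = 15.0,
    frame_size: tuple[int, int] = (120, 160),
    ellipse_axes: tuple[float, float] = (10.0, 18.0),
    animal_intensity: int = 40,
    background_intensity: int = 200,
    noise_sd: float = 5.0,
    seed: int = 0,
    labels_path: str | Path | None = None,
    deform_hz: float = 1.0,
) -> tuple[Path, Path]:
    """Render the schedule to an uncompressed grayscale AVI plus a
    ground-truth label CSV; deterministic given the seed.

    ellipse_axes are the (vertical, horizontal) semi-axes in pixels.
    Returns (video_path, labels_path).
    """
    out_path = Path(out_path)
    if labels_path is None:
        labels_path = out_path.with_suffix(".truth.csv")
    labels_path = Path(labels_path)

    height, width = frame_size
    a_r, a_c0 = float(ellipse_axes[0]), float(ellipse_axes[1])
    max_ac = a_c0 * (1 + schedule.deform_frac)
    margin = schedule.mobile_jitter_px + 2
    if 2 * (a_r + margin) >= height or 2 * (max_ac + margin) >= width:
        raise ValueError("animal does not fit in the frame with jitter margin")

    rng = np.random.default_rng(seed)
    n_frames = int(round(schedule.duration_s * fps))
    r, c = height // 2, width // 2
    r_lo, r_hi = int(np.ceil(a_r)) + margin, height - int(np.ceil(a_r)) - margin
    c_lo, c_hi = int(np.ceil(max_ac)) + margin, width - int(np.ceil(max_ac)) - margin
    phase = 0.0
    a_c = a_c0  # frozen (not reset) during immobile seconds: no shape jump

    with RawAviWriter(out_path, width=width, height=height, fps=fps) as writer:
        for f in range(n_frames):
            second = min(int(f / fps), schedule.duration_s - 1)
            immobile = schedule.states[second] == 1
            jitter = (
                schedule.immobile_jitter_px if immobile else schedule.mobile_jitter_px
            )
            if jitter > 0:
                dr, dc = rng.integers(-jitter, jitter + 1, size=2)
                r = int(np.clip(r + dr, r_lo, r_hi))
                c = int(np.clip(c + dc, c_lo, c_hi))
            if not immobile:
                phase += 2 * np.pi * deform_hz / fps
                a_c = a_c0 * (1 + schedule.deform_frac * np.sin(phase))

            frame = np.full((height, width), float(background_intensity))
            rr, cc = draw_ellipse(r, c, a_r, a_c, shape=(height, width))
            frame[rr, cc] = animal_intensity
            if noise_sd > 0:
                frame = frame + rng.normal(0.0, noise_sd, size=frame.shape)
            writer.append(np.clip(np.round(frame), 0, 255).astype(np.uint8))

    truth = schedule.truth_labels()
    pd.DataFrame(
        {"second_index": np.arange(len(truth)), "label": truth}
    ).to_csv(labels_path, index=False)
    return out_path, labels_path


def simulate_human_labels(
    truth: np.ndarray, lag_model: LagModel
) -> np.ndarray:
    """Delay every state transition in `truth` by an independently drawn
    reaction lag, resolving overlapping delayed transitions in
    chronological order.  Output length equals the input length."""
    truth = np.asarray(truth, dtype=np.int8)
    n = len(truth)
    if n == 0:
        return truth.copy()
    rng = np.random.default_rng(lag_model.seed)
    transitions = np.flatnonzero(np.diff(truth)) + 1
    lags = lag_model.draw(rng, len(transitions))
    delayed = transitions + lags
    # stable sort keeps original order among simultaneous events
    order = np.argsort(delayed, kind="stable")
    out = np.empty(n, dtype=np.int8)
    state = truth[0]
    pos = 0
    for t in delayed[order]:
        t = int(t)
        if t >= n:
            break
        out[pos:t] = state
        state = 1 - state
        pos = t
    out[pos:] = state
    return out
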