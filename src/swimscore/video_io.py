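"""Video access: metadata probing, time-window selection and ROI cropping.

Time is measured in seconds with 0-based frame indices.  Analyzed second
``s`` covers frames with index in ``[s*fps, (s+1)*fps)`` relative to the
window start (half-open binning, boundaries rounded to the nearest frame).

Uncompressed AVI files are decoded natively; other containers (MP4, MOV,
GIF, ...) are handed to :mod:`imageio`, which requires an ffmpeg-capable
backend for compressed codecs.  15 fps is the validated reference frame
rate, but any fps is accepted and processed natively without resampling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from . import _rawavi

logger = logging.getLogger(__name__)

#: ITU-R BT.709 luminance weights used for RGB -> grayscale conversion
#: (the scikit-image convention); logged with every run for provenance.
GRAY_WEIGHTS = (0.2125, 0.7154, 0.0721)


class VideoIOError(Exception):
    """Base class for video access failures."""


class MissingVideoError(VideoIOError, FileNotFoundError):
    """The video path does not exist."""


class UndecodableVideoError(VideoIOError):
    """The file exists but no available backend can decode it."""


class EmptyVideoError(VideoIOError):
    """The container decodes but holds zero frames."""


class WindowError(ValueError):
    """The analysis window is invalid for the given video."""


class DegenerateROIError(ValueError):
    """The region of interest collapses to fewer than 2x2 pixels."""


@dataclass(frozen=True)
class VideoMeta:
    """Container-level metadata; no frames are held."""

    path: Path
    fps: float
    n_frames: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError(f"fps must be positive, got {self.fps}")
        if self.n_frames < 1:
            raise EmptyVideoError(f"{self.path}: video reports zero frames")

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps


@dataclass(frozen=True)
class AnalysisWindow:
    """Half-open time window [start_s, end_s) within a video."""

    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.start_s < 0:
            raise WindowError(f"start_s must be >= 0, got {self.start_s}")
        if self.end_s <= self.start_s:
            raise WindowError(
                f"end_s ({self.end_s}) must exceed start_s ({self.start_s})"
            )

    @property
    def n_seconds(self) -> int:
        """Number of whole analyzed seconds."""
        return int(np.floor(self.end_s - self.start_s + 1e-9))

    def validate_against(self, meta: VideoMeta) -> None:
        if self.end_s > meta.duration_s + 0.5 / meta.fps:
            raise WindowError(
                f"window end {self.end_s}s exceeds video duration "
                f"{meta.duration_s:.3f}s"
            )

    def frame_range(self, fps: float) -> tuple[int, int]:
        """First (inclusive) and last (exclusive) frame index of the window,
        rounded to the nearest frame."""
        start = int(np.floor(self.start_s * fps + 0.5))
        end = int(np.floor(self.end_s * fps + 0.5))
        return start, end


@dataclass(frozen=True)
class RegionOfInterest:
    """Polygonal selection reduced to its minimal axis-aligned bounding
    rectangle; the analysis crops the rectangle, the polygon itself is not
    used as a mask."""

    vertices: tuple[tuple[float, float], ...]  # (x, y) pixel coordinates

    def __post_init__(self) -> None:
        if len(self.vertices) < 3:
            raise ValueError("a region of interest needs at least 3 vertices")
        object.__setattr__(
            self, "vertices", tuple((float(x), float(y)) for x, y in self.vertices)
        )

    @classmethod
    def full_frame(cls, width: int, height: int) -> "RegionOfInterest":
        return cls(((0, 0), (width, 0), (width, height), (0, height)))

    def bounding_rect(self, width: int, height: int) -> tuple[int, int, int, int]:
        """(x0, y0, x1, y1) half-open rectangle clipped to frame bounds."""
        xs = [v[0] for v in self.vertices]
        ys = [v[1] for v in self.vertices]
        x0 = max(0, int(np.floor(min(xs))))
        y0 = max(0, int(np.floor(min(ys))))
        x1 = min(width, int(np.ceil(max(xs))))
        y1 = min(height, int(np.ceil(max(ys))))
        if x1 - x0 < 2 or y1 - y0 < 2:
            raise DegenerateROIError(
                f"ROI clips to {x1 - x0}x{y1 - y0} px; need at least 2x2"
            )
        return x0, y0, x1, y1


def to_grayscale(frame: np.ndarray) -> np.ndarray:
    """Convert a decoded frame to single-channel uint8 luminance."""
    if frame.ndim == 2:
        return frame
    if frame.ndim == 3 and frame.shape[2] >= 3:
        rgb = frame[:, :, :3].astype(np.float64)
        gray = rgb @ np.asarray(GRAY_WEIGHTS)
        return np.clip(np.round(gray), 0, 255).astype(np.uint8)
    raise UndecodableVideoError(f"unexpected frame shape {frame.shape}")


def _open_backend(path: Path):
    """Return (fps, n_frames, width, height, frame_getter, closer)."""
    if _rawavi.is_raw_avi(path):
        try:
            reader = _rawavi.RawAviReader(path)
        except _rawavi.UnsupportedAviError as exc:
            raise UndecodableVideoError(str(exc)) from exc
        return (
            reader.fps,
            reader.n_frames,
            reader.width,
            reader.height,
            reader.read_frame,
            reader.close,
        )
    try:
        import imageio.v3 as iio

        props = iio.improps(path, index=...)
        meta = iio.immeta(path, index=...)
    except Exception as exc:  # no backend for this container/codec
        raise UndecodableVideoError(
            f"{path}: no available backend can decode this file ({exc})"
        ) from exc
    n_frames = int(props.n_images) if props.n_images is not None else 0
    fps = float(meta.get("fps", 0.0)) or 0.0
    if fps <= 0 and meta.get("duration"):
        # Pillow-style per-frame duration in ms
        fps = 1000.0 / float(meta["duration"])
    shape = props.shape[-3:] if len(props.shape) >= 3 else props.shape
    height, width = int(shape[0]), int(shape[1])

    def getter(i: int) -> np.ndarray:
        return np.asarray(iio.imread(path, index=i))

    return fps, n_frames, width, height, getter, lambda: None


def open_video(path: str | Path) -> VideoMeta:
    """Probe a video file and return its metadata without loading frames."""
    path = Path(path)
    if not path.exists():
        raise MissingVideoError(f"video file not found: {path}")
    fps, n_frames, width, height, _, closer = _open_backend(path)
    closer()
    if n_frames < 1:
        raise EmptyVideoError(f"{path}: video contains no frames")
    if fps <= 0:
        raise UndecodableVideoError(f"{path}: container reports no frame rate")
    logger.info(
        "opened %s: %.3f fps, %d frames, %dx%d, gray weights %s",
        path, fps, n_frames, width, height, GRAY_WEIGHTS,
    )
    return VideoMeta(path=path, fps=fps, n_frames=n_frames, width=width, height=height)


def frame_stream(
    meta: VideoMeta,
    window: AnalysisWindow | None = None,
    roi: RegionOfInterest | None = None,
) -> Iterator[np.ndarray]:
    """Yield grayscale frames cropped to the ROI bounding rectangle, for
    frame indices in the analysis window (order preserved)."""
    if window is None:
        window = AnalysisWindow(0.0, meta.duration_s)
    window.validate_against(meta)
    if roi is None:
        roi = RegionOfInterest.full_frame(meta.width, meta.height)
    x0, y0, x1, y1 = roi.bounding_rect(meta.width, meta.height)
    f_start, f_end = window.frame_range(meta.fps)
    if f_end > meta.n_frames:
        logger.warning(
            "window needs frames up to %d but container reports %d; truncating",
            f_end, meta.n_frames,
        )
        f_end = meta.n_frames
    _, _, _, _, getter, closer = _open_backend(meta.path)
    try:
        for i in range(f_start, f_end):
            frame = to_grayscale(np.asarray(getter(i)))
            yield frame[y0:y1, x0:x1]
    finally:
        closer()


def parse_roi(spec: str | Sequence[float]) -> RegionOfInterest:
    """Parse 'x1,y1,x2,y2,...' (or a flat sequence) into a RegionOfInterest."""
    if isinstance(spec, str):
        parts = [float(p) for p in spec.replace(";", ",").split(",") if p.strip()]
    else:
        parts = [float(p) for p in spec]
    if len(parts) % 2 or len(parts) < 6:
        raise ValueError(
            "ROI must be given as x1,y1,x2,y2,... with at least 3 points"
        )
    pts = tuple((parts[i], parts[i + 1]) for i in range(0, len(parts), 2))
    return RegionOfInterest(pts)
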