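"""Per-frame animal segmentation.

Each grayscale frame is reduced to a binary animal mask through an
optional background subtraction, Gaussian smoothing, a global threshold
(Otsu's method by default, or a user-supplied level), a minimum-size
filter, and largest-connected-component selection.  The mask's pixel
count is the area A(t) that feeds the per-second Δ-area motion statistic.

Background fill estimates the scene behind the animal by replacing the
pixels inside a user-marked outline with the median intensity of a thin
ring just outside it — adequate for the uniform, high-contrast arenas
these assays use.  When a background model is supplied, segmentation
thresholds the absolute difference |frame − background|, which is bright
wherever the animal is regardless of coat color, so the same settings
work for dark and light animals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from skimage.draw import polygon2mask
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label, regionprops
from skimage.morphology import dilation, disk

__all__ = [
    "SegmentationConfig",
    "BackgroundModel",
    "BinaryMask",
    "estimate_background",
    "binarize_frame",
    "measure_mask",
]

Polarity = Literal["animal-dark", "animal-light"]


@dataclass(frozen=True)
class SegmentationConfig:
    """User-tunable segmentation parameters.

    blur_sigma
        Gaussian smoothing scale in pixels; 0 disables smoothing.
    threshold_mode
        'automatic' (Otsu) or 'manual' (use `manual_threshold`).
    polarity
        Which side of the threshold is animal: 'animal-dark' for a dark
        animal on a bright background, 'animal-light' for the reverse.
        Ignored (forced light) when background subtraction is active.
    min_component_px
        Connected components smaller than this are discarded before the
        largest one is kept; rejects glare and ripple speckle.
    use_background
        Subtract a BackgroundModel before thresholding when one is given.
    """

    blur_sigma: float = 2.0
    threshold_mode: Literal["automatic", "manual"] = "automatic"
    manual_threshold: float | None = None
    polarity: Polarity = "animal-dark"
    min_component_px: int = 50
    use_background: bool = False

    def __post_init__(self) -> None:
        if self.blur_sigma < 0:
            raise ValueError("blur_sigma must be >= 0")
        if self.min_component_px < 1:
            raise ValueError("min_component_px must be >= 1")
        if self.threshold_mode == "manual":
            if self.manual_threshold is None:
                raise ValueError("manual threshold_mode requires manual_threshold")
            if not 0 <= self.manual_threshold <= 255:
                raise ValueError("manual_threshold must lie in the 8-bit range")
        if self.threshold_mode not in ("automatic", "manual"):
            raise ValueError(f"unknown threshold_mode {self.threshold_mode!r}")
        if self.polarity not in ("animal-dark", "animal-light"):
            raise ValueError(f"unknown polarity {self.polarity!r}")


@dataclass(frozen=True)
class BackgroundModel:
    """Reference frame with the animal replaced by estimated background."""

    image: np.ndarray
    fill_polygon: tuple[tuple[float, float], ...]


@dataclass(frozen=True)
class BinaryMask:
    """Binary animal mask for one frame.

    After component selection the mask holds at most one connected
    component; an empty mask is allowed but flagged so downstream motion
    statistics can mark the frame invalid instead of treating it as a
    vanished animal.
    """

    pixels: np.ndarray  # bool (H, W)
    area_px: int

    @property
    def empty(self) -> bool:
        return self.area_px == 0


def _polygon_mask(
    shape: tuple[int, int], polygon_xy: Sequence[tuple[float, float]]
) -> np.ndarray:
    pts = np.asarray([(y, x) for x, y in polygon_xy], dtype=float)
    return polygon2mask(shape, pts)


def estimate_background(
    reference_frame: np.ndarray,
    animal_polygon: Sequence[tuple[float, float]],
    ring_px: int = 3,
) -> BackgroundModel:
    """Inpaint the user-marked animal outline with the median intensity of
    the `ring_px`-wide ring of pixels just outside the polygon.

    Parameters use (x, y) pixel coordinates for the polygon, matching the
    ROI convention.  Raises ValueError when the polygon leaves no ring to
    sample from (e.g. it covers the whole frame).
    """
    if len(animal_polygon) < 3:
        raise ValueError("animal outline needs at least 3 vertices")
    frame = np.asarray(reference_frame)
    inside = _polygon_mask(frame.shape, animal_polygon)
    ring = dilation(inside, disk(ring_px)) & ~inside
    if not ring.any():
        raise ValueError("polygon covers the frame; no background ring available")
    filled = frame.copy()
    filled[inside] = np.median(frame[ring])
    return BackgroundModel(image=filled, fill_polygon=tuple(
        (float(x), float(y)) for x, y in animal_polygon
    ))


def _empty_mask(shape: tuple[int, int]) -> BinaryMask:
    return BinaryMask(pixels=np.zeros(shape, dtype=bool), area_px=0)


def binarize_frame(
    frame: np.ndarray,
    config: SegmentationConfig,
    background: BackgroundModel | None = None,
) -> BinaryMask:
    """Segment one grayscale frame into a BinaryMask.

    Pipeline: optional |frame − background| → Gaussian blur → global
    threshold → drop components below ``min_component_px`` → keep the
    largest remaining component.  Deterministic; an unresolvable frame
    (no bimodality, nothing above the size floor) yields an empty,
    flagged mask rather than an error.
    """
    img = np.asarray(frame, dtype=np.float64)
    if img.size == 0:
        raise ValueError("frame is empty")
    polarity = config.polarity
    if config.use_background and background is not None:
        img = np.abs(img - np.asarray(background.image, dtype=np.float64))
        polarity = "animal-light"
    if config.blur_sigma > 0:
        img = gaussian(img, sigma=config.blur_sigma, preserve_range=True)

    if config.threshold_mode == "manual":
        thr = float(config.manual_threshold)
    else:
        if np.ptp(img) < 1e-9:  # flat frame: Otsu undefined, no object
            return _empty_mask(img.shape)
        thr = float(threshold_otsu(img))

    fg = img < thr if polarity == "animal-dark" else img > thr
    labels = label(fg, connectivity=2)
    if labels.max() == 0:
        return _empty_mask(img.shape)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    sizes[sizes < config.min_component_px] = 0
    if sizes.max() == 0:
        return _empty_mask(img.shape)
    keep = int(sizes.argmax())
    pixels = labels == keep
    return BinaryMask(pixels=pixels, area_px=int(sizes[keep]))


def measure_mask(mask: BinaryMask) -> tuple[int, float]:
    """Return (area_px, major_axis_px) of the mask's component.

    The major axis is that of the best-fit ellipse (second image moments);
    an empty mask measures (0, 0.0).
    """
    if mask.empty:
        return 0, 0.0
    props = regionprops(mask.pixels.astype(np.uint8))[0]
    return mask.area_px, float(props.axis_major_length)
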