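"""Foreground segmentation of time-lapse frames against a daily background.

The processing chain, applied per frame:

    resize -> enhance (CLAHE + bilateral) -> |frame - daily background|
           -> binary threshold -> morphological cleanup -> connected
           components -> one Detection per sufficiently large component

The daily background is the per-pixel arithmetic mean of all frames of one
calendar day; with one frame per hour that is typically 24 frames.  Because
subtraction uses the absolute difference, both brighter-than-background
elements (fauna, turbidity clouds) and darker ones (cast shadows) are
segmented.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, datetime
from typing import Sequence

import numpy as np
from skimage import measure, morphology

from .config import EnhanceConfig, SegmentConfig
from .enhance import bilateral, clahe, rgb_to_ycbcr, ycbcr_to_rgb
from .io import Frame, to_grayscale

__all__ = [
    "BackgroundModel",
    "Detection",
    "daily_background",
    "enhance",
    "enhance_background",
    "subtract_background",
    "binarize",
    "clean_mask",
    "find_elements",
    "detect_pipeline",
]


@dataclass
class BackgroundModel:
    """Per-day reference image: the mean of that day's frames."""

    day: date
    pixels: np.ndarray  # float64, frame dims
    n_frames_used: int
    enhanced: bool = False  # True once passed through the enhancement chain


@dataclass
class Detection:
    """One segmented element of a frame.

    The bounding box is half-open with ``x`` indexing columns:
    ``(x_min, y_min, x_max, y_max)``.  ``crop`` is cut from the enhanced
    frame, ``mask_crop`` is the component's binary support inside the box.
    """

    image_id: str
    contour: np.ndarray        # (N, 2) array of (y, x) boundary coordinates
    box: tuple[int, int, int, int]
    area: int
    crop: np.ndarray
    mask_crop: np.ndarray

    @property
    def width(self) -> int:
        return self.box[2] - self.box[0]

    @property
    def height(self) -> int:
        return self.box[3] - self.box[1]


def daily_background(frames: Sequence[Frame]) -> BackgroundModel:
    """Average all frames of one calendar day into a background model."""
    if not frames:
        raise ValueError("daily_background needs at least one frame")
    day = frames[0].day
    shape = frames[0].pixels.shape
    for f in frames:
        if f.pixels.shape != shape:
            raise ValueError("all frames of a day must share dimensions")
        if f.day != day:
            raise ValueError(f"mixed days in background input: {day} vs {f.day}")
    acc = np.zeros(shape, dtype=np.float64)
    for f in frames:
        acc += f.pixels
    return BackgroundModel(day=day, pixels=acc / len(frames), n_frames_used=len(frames))


def enhance(frame: Frame, params: EnhanceConfig | None = None) -> Frame:
    """CLAHE on the luminance channel, then bilateral filtering.

    Color frames are converted to YCbCr, the Y channel is equalized, and the
    bilateral filter is then applied to each RGB channel of the
    reconstructed image.  Grayscale frames are processed directly.
    """
    p = params or EnhanceConfig()
    if frame.is_color:
        ycc = rgb_to_ycbcr(frame.pixels)
        y = np.clip(np.round(ycc[..., 0]), 0, 255).astype(np.uint8)
        ycc[..., 0] = clahe(y, p.clahe_clip, p.clahe_grid)
        rgb = ycbcr_to_rgb(ycc)
        out = np.stack(
            [
                bilateral(rgb[..., c], p.bilateral_diameter,
                          p.bilateral_sigma_color, p.bilateral_sigma_space)
                for c in range(3)
            ],
            axis=-1,
        )
    else:
        eq = clahe(frame.pixels, p.clahe_clip, p.clahe_grid)
        out = bilateral(eq, p.bilateral_diameter,
                        p.bilateral_sigma_color, p.bilateral_sigma_space)
    return Frame(frame.image_id, frame.timestamp, out)


def subtract_background(frame: Frame, bg: BackgroundModel) -> np.ndarray:
    """Absolute per-pixel grayscale difference between frame and background."""
    if frame.pixels.shape[:2] != bg.pixels.shape[:2]:
        raise ValueError("frame and background dimensions differ")
    f_gray = to_grayscale(frame.pixels).astype(np.float64)
    b_gray = to_grayscale(np.clip(np.round(bg.pixels), 0, 255).astype(np.uint8)).astype(np.float64)
    return np.clip(np.round(np.abs(f_gray - b_gray)), 0, 255).astype(np.uint8)


def binarize(diff: np.ndarray, threshold: int) -> np.ndarray:
    """Binary mask: pixel set iff difference strictly exceeds the threshold."""
    if not 0 <= threshold <= 255:
        raise ValueError("threshold must lie in [0, 255]")
    return np.asarray(diff) > threshold


_MORPH_OPS = {
    "closing": morphology.closing,
    "opening": morphology.opening,
    "dilation": morphology.dilation,
    "erosion": morphology.erosion,
}


def enhance_background(bg: BackgroundModel, params: EnhanceConfig | None = None) -> BackgroundModel:
    """Pass a background through the same enhancement chain as the frames."""
    if bg.enhanced:
        return bg
    px = np.clip(np.round(bg.pixels), 0, 255).astype(np.uint8)
    frame = Frame("background", datetime(bg.day.year, bg.day.month, bg.day.day), px)
    out = enhance(frame, params)
    return BackgroundModel(bg.day, out.pixels.astype(np.float64), bg.n_frames_used, True)


def clean_mask(
    mask: np.ndarray,
    ops: Sequence[tuple[str, int, int]],
) -> np.ndarray:
    """Apply morphological operations in order.

    ``ops`` is a list of ``(name, kernel_size, iterations)`` with square
    structuring elements of odd size.
    """
    out = np.asarray(mask, dtype=bool)
    for name, ksize, iters in ops:
        if name not in _MORPH_OPS:
            raise ValueError(f"unknown morphological op {name!r}; valid: {sorted(_MORPH_OPS)}")
        if ksize % 2 == 0 or ksize < 1:
            raise ValueError("structuring elements must have odd size >= 1")
        footprint = np.ones((ksize, ksize), dtype=bool)
        fn = _MORPH_OPS[name]
        for _ in range(int(iters)):
            out = fn(out, footprint)
    return out


def find_elements(
    mask: np.ndarray,
    enhanced: Frame,
    min_area: int = 50,
) -> list[Detection]:
    """One Detection per 8-connected foreground component of area >= min_area."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != enhanced.pixels.shape[:2]:
        raise ValueError("mask and frame dimensions differ")
    labels = measure.label(mask, connectivity=2)
    detections: list[Detection] = []
    for region in measure.regionprops(labels):
        if region.area < min_area:
            continue
        minr, minc, maxr, maxc = region.bbox
        box = (minc, minr, maxc, maxr)
        component = labels[minr:maxr, minc:maxc] == region.label
        crop = enhanced.pixels[minr:maxr, minc:maxc].copy()
        contours = measure.find_contours(np.pad(component, 1).astype(float), 0.5)
        contour = max(contours, key=len) + [minr - 1, minc - 1] if contours else np.empty((0, 2))
        detections.append(
            Detection(
                image_id=enhanced.image_id,
                contour=np.asarray(contour),
                box=box,
                area=int(region.area),
                crop=crop,
                mask_crop=component,
            )
        )
    return detections


def detect_pipeline(
    frame: Frame,
    bg: BackgroundModel,
    enhance_params: EnhanceConfig | None = None,
    segment_params: SegmentConfig | None = None,
) -> list[Detection]:
    """Full per-frame chain: enhance, subtract, threshold, clean, extract.

    The frame is assumed already at working size (see ``ResizeConfig``);
    the background must share its dimensions.
    """
    sp = segment_params or SegmentConfig()
    enhanced = enhance(frame, enhance_params)
    if sp.enhance_background:
        bg = enhance_background(bg, enhance_params)
    diff = subtract_background(enhanced, bg)
    mask = binarize(diff, sp.threshold)
    mask = clean_mask(mask, sp.morphology)
    return find_elements(mask, enhanced, sp.min_area)
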