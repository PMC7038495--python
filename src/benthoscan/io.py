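"""Frame and manifest I/O for fixed-camera time-lapse imagery.

Conventions used throughout the package:

* pixel coordinates are 0-based with the origin at the top-left corner;
  ``x`` indexes columns, ``y`` rows;
* bounding boxes are half-open: ``x_min <= x < x_max``, ``y_min <= y < y_max``;
* images are ``uint8`` arrays in ``[0, 255]``, either ``(H, W)`` grayscale or
  ``(H, W, 3)`` RGB (channel order R, G, B);
* frame filenames encode the acquisition timestamp as ``...YYYYMMDD_HH...``
  (e.g. ``cam1_20171117_06.png``), one frame per hour.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from datetime import date, datetime
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "Frame",
    "FrameError",
    "load_frames",
    "load_image",
    "save_image",
    "resize",
    "to_grayscale",
    "load_manifest",
    "save_manifest",
    "parse_timestamp",
]

#: luma weights used for every RGB -> grayscale conversion in the package
LUMA_WEIGHTS = (0.299, 0.587, 0.114)

_TS_RE = re.compile(r"(\d{8})_(\d{2})")

_IMAGE_SUFFIXES = {".png", ".tif", ".tiff", ".jpg", ".jpeg"}

MANIFEST_COLUMNS = ["image_id", "class", "x_min", "y_min", "x_max", "y_max"]


@dataclass
class Frame:
    """One time-stamped still image from a fixed camera."""

    image_id: str
    timestamp: datetime
    pixels: np.ndarray  # uint8, (H, W) or (H, W, 3)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim not in (2, 3) or (px.ndim == 3 and px.shape[2] != 3):
            raise ValueError("pixels must be (H, W) grayscale or (H, W, 3) color")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("frame must have height >= 1 and width >= 1")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("intensities must lie in [0, 255]")
            px = np.round(px).astype(np.uint8)
        self.pixels = px

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])

    @property
    def is_color(self) -> bool:
        return self.pixels.ndim == 3

    @property
    def day(self) -> date:
        """Calendar day used for background grouping."""
        return self.timestamp.date()


@dataclass
class FrameError:
    """Record of a file that could not be loaded as a frame."""

    path: str
    reason: str


def parse_timestamp(name: str) -> datetime:
    """Extract the acquisition timestamp from a filename.

    The convention is ``...YYYYMMDD_HH...`` anywhere in the stem; the last
    match wins so camera prefixes containing digits are tolerated.
    """
    matches = _TS_RE.findall(Path(name).stem)
    if not matches:
        raise ValueError(f"no YYYYMMDD_HH timestamp in filename {name!r}")
    day_s, hour_s = matches[-1]
    return datetime.strptime(day_s, "%Y%m%d").replace(hour=int(hour_s))


def load_image(path: str | Path) -> np.ndarray:
    """Read an image file into a uint8 array (RGB for color inputs)."""
    with Image.open(path) as im:
        if im.mode in ("L", "I;16", "I"):
            arr = np.asarray(im.convert("L"))
        else:
            arr = np.asarray(im.convert("RGB"))
    return arr.astype(np.uint8)


def save_image(path: str | Path, pixels: np.ndarray) -> None:
    """Write a uint8 array as an image file (PNG preferred: lossless)."""
    Image.fromarray(np.asarray(pixels, dtype=np.uint8)).save(path)


def load_frames(
    directory: str | Path, pattern: str = "*"
) -> tuple[list[Frame], list[FrameError]]:
    """Load all frames in ``directory``, sorted by timestamp.

    Returns the readable frames plus one :class:`FrameError` per file that
    could not be read or whose name carries no parseable timestamp —
    failures are reported, never silently dropped.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"frame directory not found: {directory}")
    frames: list[Frame] = []
    errors: list[FrameError] = []
    for path in sorted(directory.glob(pattern)):
        if not path.is_file() or path.suffix.lower() not in _IMAGE_SUFFIXES:
            continue
        try:
            ts = parse_timestamp(path.name)
        except ValueError as exc:
            errors.append(FrameError(str(path), str(exc)))
            continue
        try:
            pixels = load_image(path)
        except Exception as exc:  # corrupt / truncated file
            errors.append(FrameError(str(path), f"unreadable image: {exc}"))
            continue
        frames.append(Frame(image_id=path.stem, timestamp=ts, pixels=pixels))
    frames.sort(key=lambda f: (f.timestamp, f.image_id))
    return frames, errors


def group_by_day(frames: Sequence[Frame]) -> dict[date, list[Frame]]:
    """Partition frames by calendar day (every frame in exactly one group)."""
    groups: dict[date, list[Frame]] = {}
    for f in frames:
        groups.setdefault(f.day, []).append(f)
    return groups


def to_grayscale(pixels: np.ndarray) -> np.ndarray:
    """RGB -> grayscale with the standard luma weighting; grayscale passes through."""
    px = np.asarray(pixels)
    if px.ndim == 2:
        return px.astype(np.uint8) if px.dtype != np.uint8 else px
    w = np.asarray(LUMA_WEIGHTS)
    gray = px[..., :3].astype(np.float64) @ w
    return np.clip(np.round(gray), 0, 255).astype(np.uint8)


def resize(
    frame: Frame,
    factor: float | None = None,
    target: tuple[int, int] | None = None,
) -> Frame:
    """Rescale a frame by ``factor`` or to an explicit ``target=(height, width)``.

    Shrinking uses area averaging (each output pixel is the mean of the
    source box it covers); enlarging uses bilinear interpolation.  A factor
    of 1.0 (or a target equal to the input size) returns the pixels
    unchanged.
    """
    if (factor is None) == (target is None):
        raise ValueError("give exactly one of factor or target")
    if factor is not None:
        if factor <= 0:
            raise ValueError("resize factor must be > 0")
        out_h = max(1, int(round(frame.height * factor)))
        out_w = max(1, int(round(frame.width * factor)))
    else:
        out_h, out_w = int(target[0]), int(target[1])
        if out_h < 1 or out_w < 1:
            raise ValueError("target dimensions must be >= 1")
    if (out_h, out_w) == (frame.height, frame.width):
        return Frame(frame.image_id, frame.timestamp, frame.pixels.copy())
    shrinking = out_h <= frame.height and out_w <= frame.width
    resample = Image.Resampling.BOX if shrinking else Image.Resampling.BILINEAR
    im = Image.fromarray(frame.pixels).resize((out_w, out_h), resample=resample)
    return Frame(frame.image_id, frame.timestamp, np.asarray(im, dtype=np.uint8))


def load_manifest(path: str | Path) -> pd.DataFrame:
    """Read an annotation manifest (CSV: image_id,class,x_min,y_min,x_max,y_max)."""
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    bad = df[(df.x_min < 0) | (df.y_min < 0) | (df.x_min >= df.x_max) | (df.y_min >= df.y_max)]
    if len(bad):
        raise ValueError(f"{len(bad)} manifest rows violate box invariants")
    return df


def save_manifest(path: str | Path, rows: pd.DataFrame) -> None:
    rows.to_csv(path, index=False)
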