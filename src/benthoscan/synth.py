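"""Reproducible synthetic time-lapse scenes with exact ground truth.

The generator emulates the statistical structure a fixed-camera benthic
time-lapse pipeline assumes: a static textured seafloor background shared
by all frames, hourly frames with planted objects drawn from a 13-class
appearance bank (distinct shape family, color, and texture per class so
that shape/texture/color features can separate them), additive soft
turbidity clouds, multiplicative cast shadows, and additive Gaussian
sensor noise.  Every planted object — including each turbidity cloud and
shadow — yields exactly one ground-truth record with a tight half-open
bounding box.

All randomness is drawn from a single generator seeded by ``spec.seed``
in a fixed order (background first; then, per frame: classes in schema
order, objects in planting order; sensor noise last), so a spec and seed
reproduce a sequence bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .dataset import CLASSES, AnnotatedElement
from .io import Frame, save_image

__all__ = [
    "ObjectAppearance",
    "SceneSpec",
    "TruthRecord",
    "default_object_bank",
    "generate_sequence",
    "write_sequence",
    "generate_crop_bank",
]


@dataclass(frozen=True)
class ObjectAppearance:
    """Appearance of one class: shape family, size, color, texture."""

    shape: str                      # ellipse | star | cross | cloud | shadow
    size_range: tuple[int, int]     # half-size (max radius) in pixels
    color: tuple[int, int, int] = (128, 128, 128)
    elongation: float = 1.0         # major/minor axis ratio for ellipses
    n_points: int = 5               # lobes for star shapes
    texture: str = "plain"          # plain | stripes | speckle
    texture_amp: float = 0.2
    contrast: float = 30.0          # declared min |object - background| luminance
    gain: float = 70.0              # additive brightness for clouds
    darkness: float = 0.65          # multiplicative darkening for shadows


def default_object_bank() -> dict[str, ObjectAppearance]:
    """One separable appearance per schema class."""
    return {
        "rockfish": ObjectAppearance("ellipse", (9, 13), (230, 90, 60),
                                     elongation=1.8, texture="stripes"),
        "king crab": ObjectAppearance("star", (9, 13), (230, 140, 40),
                                      n_points=6, texture="speckle", texture_amp=0.25),
        "squid": ObjectAppearance("ellipse", (9, 13), (220, 210, 200), elongation=2.5),
        "starfish": ObjectAppearance("star", (9, 13), (240, 220, 60), n_points=5),
        "hermit crab": ObjectAppearance("ellipse", (8, 11), (180, 120, 60),
                                        elongation=1.2, texture="speckle",
                                        texture_amp=0.25),
        "anemone": ObjectAppearance("ellipse", (8, 12), (240, 120, 180),
                                    texture="speckle", texture_amp=0.25),
        "shrimp": ObjectAppearance("ellipse", (9, 12), (250, 180, 170),
                                   elongation=3.0, texture="stripes"),
        "sea urchin": ObjectAppearance("ellipse", (8, 11), (40, 10, 60),
                                       texture="speckle", texture_amp=0.25),
        "eel like fish": ObjectAppearance("ellipse", (11, 15), (170, 170, 175),
                                          elongation=4.0, texture="stripes"),
        "crab": ObjectAppearance("cross", (8, 11), (190, 80, 70)),
        "coral": ObjectAppearance("star", (9, 12), (235, 235, 235),
                                  n_points=8, texture="speckle", texture_amp=0.25),
        "turbidity": ObjectAppearance("cloud", (14, 20), gain=70.0, contrast=25.0),
        "shadow": ObjectAppearance("shadow", (14, 20), darkness=0.65, contrast=25.0),
    }


@dataclass
class SceneSpec:
    """Everything that defines one synthetic sequence."""

    height: int = 320
    width: int = 320
    days: int = 1
    frames_per_day: int = 24
    start_day: date = date(2024, 1, 1)
    noise_sigma: float = 2.0
    background_base: tuple[int, int, int] = (40, 70, 80)
    background_texture_amp: float = 6.0
    background_smooth: float = 10.0
    object_bank: dict[str, ObjectAppearance] = field(default_factory=default_object_bank)
    #: per-class objects per frame; a number (same every frame) or a
    #: per-day sequence of per-frame counts
    planting: Mapping[str, float | Sequence[float]] = field(
        default_factory=lambda: {c: 1 for c in CLASSES}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 64 or self.width < 64:
            raise ValueError("scene dimensions must be at least 64x64")
        if self.frames_per_day < 1 or self.days < 1:
            raise ValueError("need at least one frame per day and one day")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")
        for label in self.planting:
            if label not in CLASSES:
                raise ValueError(f"planting class {label!r} not in the schema")
        for label in self.object_bank:
            if label not in CLASSES:
                raise ValueError(f"object bank class {label!r} not in the schema")


@dataclass
class TruthRecord:
    """Ground truth for one planted object (half-open box)."""

    image_id: str
    class_label: str
    box: tuple[int, int, int, int]  # x_min, y_min, x_max, y_max
    object_id: str


def _make_background(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Static textured seafloor: base color + smooth random mottling."""
    base = np.asarray(spec.background_base, dtype=np.float64)
    bg = np.ones((spec.height, spec.width, 3)) * base
    if spec.background_texture_amp > 0:
        noise = rng.normal(0.0, 1.0, size=(spec.height, spec.width))
        smooth = gaussian_filter(noise, spec.background_smooth / 4.0)
        sd = smooth.std()
        if sd > 0:
            smooth = smooth / sd * spec.background_texture_amp
        bg += smooth[:, :, None]
    return np.clip(bg, 0, 255)


def _shape_mask(
    app: ObjectAppearance, size: int, theta: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Boolean mask, soft weight and rotated-x coordinate on a local grid."""
    n = 2 * size + 1
    yy, xx = np.mgrid[-size:size + 1, -size:size + 1].astype(np.float64)
    xr = np.cos(theta) * xx + np.sin(theta) * yy
    yr = -np.sin(theta) * xx + np.cos(theta) * yy
    rad = np.hypot(xx, yy)
    if app.shape == "ellipse":
        a, b = float(size), max(2.0, size / app.elongation)
        mask = (xr / a) ** 2 + (yr / b) ** 2 <= 1.0
        soft = np.ones((n, n))
    elif app.shape == "star":
        phi = np.arctan2(yr, xr)
        r_phi = size * (0.55 + 0.45 * np.cos(app.n_points * phi))
        mask = rad <= r_phi
        soft = np.ones((n, n))
    elif app.shape == "cross":
        arm = 0.35 * size
        mask = ((np.abs(xr) <= size) & (np.abs(yr) <= arm)) | (
            (np.abs(yr) <= size) & (np.abs(xr) <= arm)
        )
        soft = np.ones((n, n))
    elif app.shape in ("cloud", "shadow"):
        mask = rad <= size
        soft = np.sqrt(np.clip(1.0 - (rad / size) ** 2, 0.0, 1.0))
    else:
        raise ValueError(f"unknown shape family {app.shape!r}")
    return mask, soft, xr


def _texture_factor(
    app: ObjectAppearance, xr: np.ndarray, mask: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    if app.texture == "stripes":
        return 1.0 + app.texture_amp * np.sign(np.sin(2.0 * np.pi * xr / 4.0))
    if app.texture == "speckle":
        return 1.0 + app.texture_amp * rng.uniform(-1.0, 1.0, size=mask.shape)
    return np.ones(mask.shape)


def _tight_box(mask: np.ndarray, top: int, left: int) -> tuple[int, int, int, int]:
    rows = np.nonzero(mask.any(axis=1))[0]
    cols = np.nonzero(mask.any(axis=0))[0]
    return (
        left + int(cols[0]),
        top + int(rows[0]),
        left + int(cols[-1]) + 1,
        top + int(rows[-1]) + 1,
    )


_PLACEMENT_MARGIN = 4  # min pixel gap between planted boxes


def _boxes_clash(box: tuple[int, int, int, int], others: list) -> bool:
    x0, y0, x1, y1 = box
    m = _PLACEMENT_MARGIN
    for ox0, oy0, ox1, oy1 in others:
        if x0 - m < ox1 and ox0 - m < x1 and y0 - m < oy1 and oy0 - m < y1:
            return True
    return False


def _plant_object(
    img: np.ndarray,
    label: str,
    app: ObjectAppearance,
    rng: np.random.Generator,
    occupied: list,
) -> tuple[int, int, int, int]:
    """Draw one object at a free position; returns its tight box."""
    H, W = img.shape[:2]
    lo, hi = app.size_range
    if 2 * hi + 1 > min(H, W) - 2:
        raise ValueError(f"object of class {label!r} larger than the frame")
    size = int(rng.integers(lo, hi + 1))
    theta = float(rng.uniform(0.0, np.pi))
    mask, soft, xr = _shape_mask(app, size, theta)
    factor = _texture_factor(app, xr, mask, rng)
    n = mask.shape[0]
    for _ in range(300):
        top = int(rng.integers(1, H - n))
        left = int(rng.integers(1, W - n))
        box = _tight_box(mask, top, left)
        if not _boxes_clash(box, occupied):
            break
    else:
        raise RuntimeError(
            f"could not place an object of class {label!r}; scene too crowded"
        )
    patch = img[top:top + n, left:left + n]
    if app.shape == "cloud":
        patch += app.gain * (soft * mask)[:, :, None]
    elif app.shape == "shadow":
        patch *= 1.0 - app.darkness * (soft * mask)[:, :, None]
    else:
        color = np.asarray(app.color, dtype=np.float64)
        painted = color[None, None, :] * factor[:, :, None]
        patch[mask] = np.clip(painted, 0, 255)[mask]
    img[top:top + n, left:left + n] = np.clip(patch, 0, 255)
    occupied.append(box)
    return box


def _counts_for(value, day_index: int) -> int:
    if isinstance(value, (list, tuple, np.ndarray)):
        return int(value[day_index]) if day_index < len(value) else 0
    return int(value)


def generate_sequence(spec: SceneSpec) -> tuple[list[Frame], list[TruthRecord]]:
    """Render all frames of the sequence plus one truth record per object."""
    rng = np.random.default_rng(spec.seed)
    background = _make_background(spec, rng)
    frames: list[Frame] = []
    records: list[TruthRecord] = []
    serial = 0
    for d in range(spec.days):
        day = spec.start_day + timedelta(days=d)
        for h in range(spec.frames_per_day):
            hour = h % 24
            image_id = f"synthetic_{day.strftime('%Y%m%d')}_{hour:02d}"
            if spec.frames_per_day > 24:
                image_id += f"_{h:03d}"
            img = background.copy()
            occupied: list = []
            for label in CLASSES:
                if label not in spec.planting:
                    continue
                count = _counts_for(spec.planting[label], d)
                app = spec.object_bank[label]
                for _ in range(count):
                    box = _plant_object(img, label, app, rng, occupied)
                    records.append(
                        TruthRecord(image_id, label, box, f"obj{serial:05d}")
                    )
                    serial += 1
            if spec.noise_sigma > 0:
                img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
            pixels = np.clip(np.round(img), 0, 255).astype(np.uint8)
            ts = datetime(day.year, day.month, day.day, hour)
            frames.append(Frame(image_id=image_id, timestamp=ts, pixels=pixels))
    return frames, records


def write_sequence(
    directory: str | Path, frames: Sequence[Frame], records: Sequence[TruthRecord]
) -> Path:
    """Write frames as PNGs plus a truth CSV in the manifest schema."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for f in frames:
        save_image(directory / f"{f.image_id}.png", f.pixels)
    truth = pd.DataFrame(
        [
            {
                "image_id": r.image_id,
                "class": r.class_label,
                "x_min": r.box[0],
                "y_min": r.box[1],
                "x_max": r.box[2],
                "y_max": r.box[3],
                "object_id": r.object_id,
            }
            for r in records
        ]
    )
    truth_path = directory / "truth.csv"
    truth.to_csv(truth_path, index=False)
    return truth_path


def generate_crop_bank(
    per_class: int,
    seed: int = 0,
    patch_size: int = 64,
    classes: Sequence[str] = CLASSES,
    noise_sigma: float = 2.0,
) -> list[AnnotatedElement]:
    """Labelled single-object crops, one tiny rendered patch per element.

    A fast stand-in for the detect-then-crop path when a test needs
    annotated elements directly (classifier and dataset tests).
    """
    rng = np.random.default_rng(seed)
    bank = default_object_bank()
    spec = SceneSpec()  # for background parameters only
    base = np.asarray(spec.background_base, dtype=np.float64)
    elements: list[AnnotatedElement] = []
    for label in classes:
        app = bank[label]
        for k in range(per_class):
            img = np.ones((patch_size, patch_size, 3)) * base
            texture = gaussian_filter(
                rng.normal(0.0, 1.0, size=(patch_size, patch_size)), 2.5
            )
            sd = texture.std()
            if sd > 0:
                img += (texture / sd * spec.background_texture_amp)[:, :, None]
            box = _plant_object(img, label, app, rng, [])
            img += rng.normal(0.0, noise_sigma, size=img.shape)
            pixels = np.clip(np.round(img), 0, 255).astype(np.uint8)
            x0, y0, x1, y1 = box
            elements.append(
                AnnotatedElement(
                    element_id=f"{label.replace(' ', '_')}_{k:03d}",
                    crop=pixels[y0:y1, x0:x1],
                    label=label,
                )
            )
    return elements
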