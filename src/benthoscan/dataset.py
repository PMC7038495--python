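"""Annotated-element management: class schema, train/test split, augmentation.

The pipeline targets a fixed 13-class schema of benthic megafauna plus the
two optical nuisance classes that a background-subtraction detector also
segments (turbidity clouds and cast fish shadows).  The class order is
fixed so confusion-matrix axes and classifier score columns are stable.

The split is stratified by class: each class contributes
``floor(fraction * n_c)`` training elements and the global training size is
topped up to ``floor(fraction * n_total)`` by largest remainder.  Balanced
augmentation grows each class to ``min(per_original * n_c, class_cap)``
elements by adding label-preserving transformed copies (flip, rotation,
brightness, zoom); originals are never dropped and test elements are never
touched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage import transform as sktransform

__all__ = [
    "CLASSES",
    "REFERENCE_SPECIMEN_COUNTS",
    "AnnotatedElement",
    "SplitDataset",
    "split_train_test",
    "augment_element",
    "balance_augment",
    "stratified_allocation",
    "flip_horizontal",
    "rotate_crop",
    "scale_brightness",
    "zoom_crop",
    "save_elements",
    "load_elements",
]

#: the 13-class schema, order fixed for confusion-matrix axes
CLASSES: tuple[str, ...] = (
    "rockfish",
    "king crab",
    "squid",
    "starfish",
    "hermit crab",
    "anemone",
    "shrimp",
    "sea urchin",
    "eel like fish",
    "crab",
    "coral",
    "turbidity",
    "shadow",
)

#: specimen counts of the manually annotated reference collection the
#: default configuration emulates (1934 elements in total)
REFERENCE_SPECIMEN_COUNTS: dict[str, int] = {
    "rockfish": 205,
    "king crab": 170,
    "squid": 96,
    "starfish": 169,
    "hermit crab": 184,
    "anemone": 98,
    "shrimp": 154,
    "sea urchin": 138,
    "eel like fish": 199,
    "crab": 102,
    "coral": 142,
    "turbidity": 176,
    "shadow": 101,
}


@dataclass(eq=False)  # identity comparison: crops are arrays
class AnnotatedElement:
    """One labelled crop, either manually selected or an augmented copy."""

    element_id: str
    crop: np.ndarray
    label: str
    origin: str = "manual"  # "manual" | "augmented"
    parent_id: str | None = None

    def __post_init__(self) -> None:
        if self.label not in CLASSES:
            raise ValueError(f"label {self.label!r} not in the 13-class schema")
        if self.origin not in ("manual", "augmented"):
            raise ValueError("origin must be 'manual' or 'augmented'")


@dataclass
class SplitDataset:
    train: list[AnnotatedElement]
    test: list[AnnotatedElement]
    fraction: float
    seed: int


def stratified_allocation(class_counts: dict[str, int], fraction: float) -> dict[str, int]:
    """Per-class training allocation: floor per class, largest-remainder top-up.

    The allocations sum exactly to ``floor(fraction * n_total)``.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    total = sum(class_counts.values())
    target = math.floor(fraction * total)
    alloc = {c: math.floor(fraction * n) for c, n in class_counts.items()}
    shortfall = target - sum(alloc.values())
    # rank by remainder, ties broken by schema order for determinism
    order = sorted(
        class_counts,
        key=lambda c: (-(fraction * class_counts[c] - alloc[c]),
                       CLASSES.index(c) if c in CLASSES else len(CLASSES)),
    )
    i = 0
    while shortfall > 0:
        c = order[i % len(order)]
        if alloc[c] < class_counts[c]:
            alloc[c] += 1
            shortfall -= 1
        i += 1
    return alloc


def split_train_test(
    elements: Sequence[AnnotatedElement], fraction: float, seed: int = 0
) -> SplitDataset:
    """Stratified random split; train size is exactly floor(fraction * n)."""
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[AnnotatedElement]] = {}
    for e in elements:
        by_class.setdefault(e.label, []).append(e)
    counts = {c: len(v) for c, v in by_class.items()}
    for c in CLASSES:
        if c not in counts:
            import warnings

            warnings.warn(f"class {c!r} has no elements; split proceeds without it")
    alloc = stratified_allocation(counts, fraction)
    train: list[AnnotatedElement] = []
    test: list[AnnotatedElement] = []
    for c in sorted(by_class, key=lambda c: CLASSES.index(c)):
        idx = rng.permutation(len(by_class[c]))
        take = alloc[c]
        for rank, k in enumerate(idx):
            (train if rank < take else test).append(by_class[c][k])
    return SplitDataset(train=train, test=test, fraction=fraction, seed=seed)


# ---------------------------------------------------------------------------
# augmentation primitives (all label-preserving, uint8 in / uint8 out)

def flip_horizontal(crop: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(crop[:, ::-1])


def rotate_crop(crop: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate about the crop centre, keeping the frame size (edges replicate)."""
    out = sktransform.rotate(
        crop.astype(np.float64), angle_deg, resize=False, mode="edge",
        preserve_range=True, order=1,
    )
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def scale_brightness(crop: np.ndarray, factor: float) -> np.ndarray:
    out = crop.astype(np.float64) * factor
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def zoom_crop(crop: np.ndarray, factor: float) -> np.ndarray:
    """Zoom about the centre; output keeps the input size.

    Zoom-in crops the centre; zoom-out pads by edge replication.
    """
    h, w = crop.shape[:2]
    channel_axis = -1 if crop.ndim == 3 else None
    out = sktransform.rescale(
        crop.astype(np.float64), factor, order=1, mode="edge",
        preserve_range=True, channel_axis=channel_axis,
    )
    # restore the original size axis by axis (rounding can make the two
    # spatial axes land on different sides of the original size)
    for axis, target in enumerate((h, w)):
        current = out.shape[axis]
        if current > target:
            start = (current - target) // 2
            out = out.take(range(start, start + target), axis=axis)
        elif current < target:
            before = (target - current) // 2
            pad = [(0, 0)] * out.ndim
            pad[axis] = (before, target - current - before)
            out = np.pad(out, pad, mode="edge")
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def augment_element(
    elem: AnnotatedElement,
    rng: np.random.Generator,
    rotation_max_deg: float = 25.0,
    brightness_range: tuple[float, float] = (0.7, 1.3),
    zoom_range: tuple[float, float] = (0.8, 1.2),
    copy_index: int = 0,
) -> AnnotatedElement:
    """One augmented copy: a random composition of flip/rotate/brightness/zoom.

    Each transform is included with probability 1/2; if none is drawn the
    horizontal flip is forced so the copy always differs from its parent.
    The label is preserved and the parent recorded.
    """
    if elem.crop.size == 0:
        raise ValueError("cannot augment an empty crop")
    crop = elem.crop
    use = rng.random(4) < 0.5
    if not use.any():
        use[0] = True
    if use[0]:
        crop = flip_horizontal(crop)
    if use[1]:
        crop = rotate_crop(crop, float(rng.uniform(-rotation_max_deg, rotation_max_deg)))
    if use[2]:
        crop = scale_brightness(crop, float(rng.uniform(*brightness_range)))
    if use[3]:
        crop = zoom_crop(crop, float(rng.uniform(*zoom_range)))
    return AnnotatedElement(
        element_id=f"{elem.element_id}#aug{copy_index}",
        crop=crop,
        label=elem.label,
        origin="augmented",
        parent_id=elem.element_id,
    )


def save_elements(
    directory,
    elements: Sequence[AnnotatedElement],
    splits: dict[str, str] | None = None,
) -> None:
    """Write a dataset directory: crop PNGs plus an elements CSV.

    ``splits`` optionally maps element_id -> "train"/"test".
    """
    import pandas as pd
    from pathlib import Path

    from .io import save_image

    directory = Path(directory)
    (directory / "crops").mkdir(parents=True, exist_ok=True)
    rows = []
    for e in elements:
        fname = f"{e.element_id.replace('#', '_')}.png"
        save_image(directory / "crops" / fname, e.crop)
        rows.append(
            {
                "element_id": e.element_id,
                "class": e.label,
                "origin": e.origin,
                "parent_id": e.parent_id or "",
                "split": (splits or {}).get(e.element_id, ""),
                "file": fname,
            }
        )
    pd.DataFrame(rows).to_csv(directory / "elements.csv", index=False)


def load_elements(directory) -> tuple[list[AnnotatedElement], dict[str, str]]:
    """Read a dataset directory written by :func:`save_elements`."""
    import pandas as pd
    from pathlib import Path

    from .io import load_image

    directory = Path(directory)
    df = pd.read_csv(directory / "elements.csv", keep_default_na=False)
    elements, splits = [], {}
    for row in df.to_dict("records"):
        elements.append(
            AnnotatedElement(
                element_id=row["element_id"],
                crop=load_image(directory / "crops" / row["file"]),
                label=row["class"],
                origin=row["origin"],
                parent_id=row["parent_id"] or None,
            )
        )
        if row["split"]:
            splits[row["element_id"]] = row["split"]
    return elements, splits


def balance_augment(
    train: Sequence[AnnotatedElement],
    per_original: int = 37,
    class_cap: int = 3034,
    rng: np.random.Generator | None = None,
    **augment_kwargs,
) -> list[AnnotatedElement]:
    """Grow each class to ``min(per_original * n_c, class_cap)`` elements.

    Originals are always kept; augmented copies are assigned round-robin
    over the class's originals, so no original contributes more than
    ``per_original - 1`` copies.
    """
    if per_original < 1:
        raise ValueError("per_original must be >= 1")
    rng = rng or np.random.default_rng(0)
    by_class: dict[str, list[AnnotatedElement]] = {}
    for e in train:
        by_class.setdefault(e.label, []).append(e)
    out: list[AnnotatedElement] = []
    for label in sorted(by_class, key=lambda c: CLASSES.index(c)):
        originals = by_class[label]
        n_c = len(originals)
        target = min(per_original * n_c, class_cap)
        out.extend(originals)
        n_copies = target - n_c
        for k in range(n_copies):
            parent = originals[k % n_c]
            out.append(
                augment_element(parent, rng, copy_index=k // n_c, **augment_kwargs)
            )
    return out
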