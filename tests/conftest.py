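"""Shared fixtures: small synthetic scenes and crop banks, built once."""

import numpy as np
import pytest

from benthoscan.dataset import AnnotatedElement
from benthoscan.detection import daily_background, detect_pipeline, enhance_background
from benthoscan.synth import SceneSpec, generate_crop_bank, generate_sequence


def box_iou(a, b):
    ax0, ay0, ax1, ay1 = a
    bx0, by0, bx1, by1 = b
    ix = max(0, min(ax1, bx1) - max(ax0, bx0))
    iy = max(0, min(ay1, by1) - max(ay0, by0))
    inter = ix * iy
    union = (ax1 - ax0) * (ay1 - ay0) + (bx1 - bx0) * (by1 - by0) - inter
    return inter / union if union else 0.0


@pytest.fixture(scope="session")
def small_scene():
    """One hourly day (24 frames) with a reduced planting load.

    A full day of frames matters: the daily-mean background assumes each
    object pollutes the average only at 1/n strength.
    """
    spec = SceneSpec(
        height=192,
        width=192,
        days=1,
        frames_per_day=24,
        planting={"rockfish": 2, "starfish": 1, "turbidity": 1, "shadow": 1},
        seed=11,
    )
    frames, records = generate_sequence(spec)
    return spec, frames, records


@pytest.fixture(scope="session")
def crop_bank():
    """Five labelled single-object crops for each of the 13 classes."""
    return generate_crop_bank(per_class=5, seed=21)


@pytest.fixture(scope="session")
def gaussian_features():
    """Separable 13-class synthetic feature table (n = 260, L = 532)."""
    from benthoscan.dataset import CLASSES

    rng = np.random.default_rng(5)
    X, y = [], []
    for i, label in enumerate(CLASSES):
        centre = rng.normal(0.0, 1.0, 532)
        X.append(centre + rng.normal(0.0, 0.15, (20, 532)))
        y.extend([label] * 20)
    return np.vstack(X), np.asarray(y, dtype=object)
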