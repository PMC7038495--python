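"""Global features of detection crops: Hu moments, Haralick texture, color.

Each crop is summarized by a fixed-length 1-D vector

    [ 7 Hu invariants | 13 Haralick statistics | B^3 joint color histogram ]

(with the default 8 bins per channel, L = 7 + 13 + 512 = 532).  The Hu
invariants capture shape irrespective of position, scale and rotation; the
Haralick statistics summarize the gray-level co-occurrence matrix (GLCM)
of the crop; the joint color histogram captures the color distribution.

Haralick conventions (all thirteen classical statistics, the unstable
fourteenth omitted): GLCMs are symmetric and normalized, gray levels are
quantized uniformly from [0, 256) into ``levels`` bins, the statistics are
averaged over the four standard directions (0, 45, 90, 135 degrees) at the
given pixel distance, logarithms are base 2, the sum-variance statistic is
centred on the sum average, and correlation is defined as 0 for a constant
crop (zero marginal variance).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.feature import graycomatrix

from .config import FeatureConfig
from .detection import Detection
from .io import to_grayscale

__all__ = [
    "FeatureVector",
    "hu_moments",
    "haralick_features",
    "color_histogram",
    "global_feature_vector",
    "crop_features",
    "feature_length",
    "HARALICK_NAMES",
]

HARALICK_NAMES = [
    "angular_second_moment",
    "contrast",
    "correlation",
    "sum_of_squares_variance",
    "inverse_difference_moment",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "difference_variance",
    "difference_entropy",
    "info_measure_correlation_1",
    "info_measure_correlation_2",
]

_FOUR_ANGLES = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)


@dataclass
class FeatureVector:
    """Fixed-length 1-D feature array with the detection it came from."""

    values: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature vector contains non-finite entries")


def _axis_integrals(n: int) -> np.ndarray:
    """Per-pixel integrals of x^p over the pixel support [x, x+1), p = 0..3."""
    x = np.arange(n, dtype=np.float64)
    out = np.empty((4, n))
    for p in range(4):
        out[p] = ((x + 1) ** (p + 1) - x ** (p + 1)) / (p + 1)
    return out


def hu_moments(crop: np.ndarray) -> np.ndarray:
    """The seven Hu invariants of a grayscale crop (intensity-weighted).

    Moments are computed as exact integrals of the piecewise-constant
    intensity surface over the pixel supports (not point sums at pixel
    centres), so the invariants are exactly preserved — up to floating
    point — under translation, 90/180-degree rotation, mirroring (sign
    flip of the seventh) and integer nearest-neighbour rescaling.

    Degenerate inputs: an all-zero crop, or one whose support is a single
    pixel (a point mass carries no shape), returns all zeros with a warning.
    """
    img = to_grayscale(np.asarray(crop)).astype(np.float64)
    if img.size == 0:
        raise ValueError("empty crop")
    if img.sum() == 0:
        warnings.warn("all-zero crop: Hu moments defined as zeros", stacklevel=2)
        return np.zeros(7)
    if np.count_nonzero(img) == 1:
        warnings.warn("single-pixel support: Hu moments defined as zeros", stacklevel=2)
        return np.zeros(7)
    h, w = img.shape
    iy = _axis_integrals(h)   # row axis
    ix = _axis_integrals(w)   # column axis
    M = np.empty((4, 4))      # M[p, q]: x (column) order p, y (row) order q
    for p in range(4):
        for q in range(4):
            M[p, q] = iy[q] @ img @ ix[p]
    xb, yb = M[1, 0] / M[0, 0], M[0, 1] / M[0, 0]
    mu = np.zeros((4, 4))
    mu[0, 0] = M[0, 0]
    mu[2, 0] = M[2, 0] - xb * M[1, 0]
    mu[0, 2] = M[0, 2] - yb * M[0, 1]
    mu[1, 1] = M[1, 1] - xb * M[0, 1]
    mu[3, 0] = M[3, 0] - 3 * xb * M[2, 0] + 2 * xb ** 2 * M[1, 0]
    mu[2, 1] = M[2, 1] - 2 * xb * M[1, 1] - yb * M[2, 0] + 2 * xb ** 2 * M[0, 1]
    mu[1, 2] = M[1, 2] - 2 * yb * M[1, 1] - xb * M[0, 2] + 2 * yb ** 2 * M[1, 0]
    mu[0, 3] = M[0, 3] - 3 * yb * M[0, 2] + 2 * yb ** 2 * M[0, 1]
    eta = {
        (p, q): mu[p, q] / mu[0, 0] ** (1 + (p + q) / 2)
        for p, q in [(2, 0), (0, 2), (1, 1), (3, 0), (2, 1), (1, 2), (0, 3)]
    }
    n20, n02, n11 = eta[(2, 0)], eta[(0, 2)], eta[(1, 1)]
    n30, n21, n12, n03 = eta[(3, 0)], eta[(2, 1)], eta[(1, 2)], eta[(0, 3)]
    s1, s2 = n30 + n12, n21 + n03
    d1, d2 = n30 - 3 * n12, 3 * n21 - n03
    return np.array([
        n20 + n02,
        (n20 - n02) ** 2 + 4 * n11 ** 2,
        d1 ** 2 + d2 ** 2,
        s1 ** 2 + s2 ** 2,
        d1 * s1 * (s1 ** 2 - 3 * s2 ** 2) + d2 * s2 * (3 * s1 ** 2 - s2 ** 2),
        (n20 - n02) * (s1 ** 2 - s2 ** 2) + 4 * n11 * s1 * s2,
        d2 * s1 * (s1 ** 2 - 3 * s2 ** 2) - d1 * s2 * (3 * s1 ** 2 - s2 ** 2),
    ])


def _entropy2(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def _haralick_one(P: np.ndarray) -> np.ndarray:
    """The 13 statistics of one symmetric, normalized GLCM."""
    L = P.shape[0]
    i = np.arange(L, dtype=np.float64)[:, None]
    j = np.arange(L, dtype=np.float64)[None, :]
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = float((np.arange(L) * px).sum())
    mu_y = float((np.arange(L) * py).sum())
    var_x = float(((np.arange(L) - mu_x) ** 2 * px).sum())
    var_y = float(((np.arange(L) - mu_y) ** 2 * py).sum())

    asm = float((P ** 2).sum())
    contrast = float(((i - j) ** 2 * P).sum())
    denom = np.sqrt(var_x * var_y)
    correlation = float(((i * j * P).sum() - mu_x * mu_y) / denom) if denom > 0 else 0.0
    variance = float(((i - mu_x) ** 2 * P).sum())
    idm = float((P / (1.0 + (i - j) ** 2)).sum())

    k_sum = (np.arange(L)[:, None] + np.arange(L)[None, :]).ravel()
    p_sum = np.bincount(k_sum, weights=P.ravel(), minlength=2 * L - 1)
    ks = np.arange(2 * L - 1, dtype=np.float64)
    sum_average = float((ks * p_sum).sum())
    sum_variance = float(((ks - sum_average) ** 2 * p_sum).sum())
    sum_entropy = _entropy2(p_sum)

    entropy = _entropy2(P.ravel())

    k_diff = np.abs(np.arange(L)[:, None] - np.arange(L)[None, :]).ravel()
    p_diff = np.bincount(k_diff, weights=P.ravel(), minlength=L)
    kd = np.arange(L, dtype=np.float64)
    diff_mean = float((kd * p_diff).sum())
    diff_variance = float(((kd - diff_mean) ** 2 * p_diff).sum())
    diff_entropy = _entropy2(p_diff)

    hx = _entropy2(px)
    hy = _entropy2(py)
    pxpy = np.outer(px, py)
    mask = (P > 0) & (pxpy > 0)
    hxy1 = float(-(P[mask] * np.log2(pxpy[mask])).sum())
    hxy2 = _entropy2(pxpy.ravel())
    max_h = max(hx, hy)
    imc1 = float((entropy - hxy1) / max_h) if max_h > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy)))))

    return np.array([
        asm, contrast, correlation, variance, idm,
        sum_average, sum_variance, sum_entropy, entropy,
        diff_variance, diff_entropy, imc1, imc2,
    ])


def haralick_features(
    crop: np.ndarray,
    levels: int = 32,
    distance: int = 1,
    angles: tuple[float, ...] = _FOUR_ANGLES,
) -> np.ndarray:
    """The 13 Haralick statistics, averaged over the given directions."""
    if levels < 2:
        raise ValueError("need at least 2 gray levels")
    img = to_grayscale(np.asarray(crop))
    if img.shape[0] < 2 or img.shape[1] < 2:
        raise ValueError("crop must be at least 2x2 for co-occurrence features")
    if min(img.shape) <= distance:
        raise ValueError("crop smaller than the co-occurrence offset")
    quant = (img.astype(np.uint16) * levels // 256).astype(np.uint8)
    glcm = graycomatrix(
        quant, distances=[distance], angles=list(angles),
        levels=levels, symmetric=True, normed=True,
    )
    per_angle = [_haralick_one(glcm[:, :, 0, a]) for a in range(len(angles))]
    return np.mean(per_angle, axis=0)


def color_histogram(crop: np.ndarray, bins_per_channel: int = 8) -> np.ndarray:
    """Joint 3-D color histogram, flattened R-major and normalized to sum 1.

    Flattening order: index = r_bin * B^2 + g_bin * B + b_bin.
    """
    if bins_per_channel < 1:
        raise ValueError("bins_per_channel must be >= 1")
    px = np.asarray(crop)
    if px.ndim == 2:
        px = np.stack([px] * 3, axis=-1)
    flat = px.reshape(-1, 3).astype(np.float64)
    hist, _ = np.histogramdd(
        flat, bins=bins_per_channel, range=[(0, 256)] * 3
    )
    total = hist.sum()
    if total > 0:
        hist = hist / total
    return hist.ravel()


def feature_length(params: FeatureConfig | None = None) -> int:
    p = params or FeatureConfig()
    return 7 + 13 + p.histogram_bins ** 3


def crop_features(crop: np.ndarray, params: FeatureConfig | None = None) -> np.ndarray:
    """[Hu | Haralick | color histogram] values for a raw crop array."""
    p = params or FeatureConfig()
    hu = hu_moments(crop)
    har = haralick_features(crop, p.haralick_levels, p.haralick_distance)
    hist = color_histogram(crop, p.histogram_bins)
    return np.concatenate([hu, har, hist])


def global_feature_vector(
    detection: Detection, params: FeatureConfig | None = None
) -> FeatureVector:
    """Concatenate [Hu | Haralick | color histogram] for one detection crop."""
    p = params or FeatureConfig()
    crop = detection.crop
    if p.mask_crops:
        crop = crop.copy()
        crop[~detection.mask_crop] = 0
    return FeatureVector(values=crop_features(crop, p), provenance=detection.image_id)
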