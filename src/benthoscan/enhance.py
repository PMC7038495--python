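"""Contrast enhancement: CLAHE and edge-preserving bilateral filtering.

Both operators are implemented directly on numpy arrays so that their
numeric conventions are fully specified here:

* :func:`clahe` — contrast-limited adaptive histogram equalization.  The
  image is divided into a grid of tiles; each tile's 256-bin histogram is
  clipped at ``clip_limit * tile_area / 256`` counts, the clipped excess is
  redistributed uniformly, and the tile's remapping is the textbook
  CDF equalization ``v -> round((cdf(v) - cdf_min) / (area - cdf_min) * 255)``.
  Pixels are remapped by bilinear interpolation between the four
  surrounding tile mappings, which removes tile-boundary seams.  With a
  single tile and an unbounded clip limit this reduces exactly to global
  histogram equalization.
* :func:`bilateral` — a weighted mean over a square window where each
  neighbour's weight is the product of a spatial Gaussian (``sigma_space``,
  pixels) and a range Gaussian on the intensity difference
  (``sigma_color``, intensity units).  Neighbours across a strong edge get
  negligible range weight, so edges survive while texture is smoothed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["clahe", "bilateral", "rgb_to_ycbcr", "ycbcr_to_rgb"]


def _tile_lut(hist: np.ndarray, clip_limit: float) -> np.ndarray:
    """Equalization lookup table for one tile histogram (256 bins)."""
    area = int(hist.sum())
    occupied = np.nonzero(hist)[0]
    if len(occupied) <= 1:
        # homogeneous tile: equalization is the identity by convention
        return np.arange(256, dtype=np.uint8)
    h = hist.astype(np.int64).copy()
    if np.isfinite(clip_limit):
        limit = max(1, int(clip_limit * area / 256.0))
        excess = int(np.maximum(h - limit, 0).sum())
        if excess > 0:
            h = np.minimum(h, limit)
            h += excess // 256
            rem = excess % 256
            if rem:
                h[:rem] += 1
    cdf = np.cumsum(h)
    cdf_min = cdf[np.nonzero(h)[0][0]]
    denom = cdf[-1] - cdf_min
    if denom <= 0:
        return np.arange(256, dtype=np.uint8)
    lut = np.round((cdf - cdf_min) / denom * 255.0)
    return np.clip(lut, 0, 255).astype(np.uint8)


def clahe(
    image: np.ndarray,
    clip_limit: float = 2.0,
    grid: tuple[int, int] = (8, 8),
) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization of a grayscale image.

    Parameters
    ----------
    image : uint8 array (H, W)
    clip_limit : positive multiplier on the uniform histogram level;
        ``numpy.inf`` disables clipping (plain adaptive equalization).
    grid : (rows, cols) tile grid; (1, 1) means global equalization.
    """
    if clip_limit <= 0:
        raise ValueError("clahe clip limit must be > 0")
    gr, gc = int(grid[0]), int(grid[1])
    if gr < 1 or gc < 1:
        raise ValueError("clahe grid must be at least 1x1")
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("clahe operates on a single (luminance) channel")
    img = img.astype(np.uint8)
    H, W = img.shape
    gr, gc = min(gr, H), min(gc, W)

    row_edges = np.round(np.linspace(0, H, gr + 1)).astype(int)
    col_edges = np.round(np.linspace(0, W, gc + 1)).astype(int)
    luts = np.empty((gr, gc, 256), dtype=np.uint8)
    for i in range(gr):
        for j in range(gc):
            tile = img[row_edges[i]:row_edges[i + 1], col_edges[j]:col_edges[j + 1]]
            hist = np.bincount(tile.ravel(), minlength=256)
            luts[i, j] = _tile_lut(hist, clip_limit)

    # bilinear interpolation between tile-center mappings
    r_centers = (row_edges[:-1] + row_edges[1:] - 1) / 2.0
    c_centers = (col_edges[:-1] + col_edges[1:] - 1) / 2.0

    def _axis_weights(coords, centers):
        i0 = np.clip(np.searchsorted(centers, coords) - 1, 0, len(centers) - 1)
        i1 = np.minimum(i0 + 1, len(centers) - 1)
        span = centers[i1] - centers[i0]
        w = np.where(span > 0, (coords - centers[i0]) / np.where(span > 0, span, 1), 0.0)
        return i0, i1, np.clip(w, 0.0, 1.0)

    ri0, ri1, wr = _axis_weights(np.arange(H, dtype=float), r_centers)
    cj0, cj1, wc = _axis_weights(np.arange(W, dtype=float), c_centers)

    wr = wr[:, None]
    wc = wc[None, :]
    v00 = luts[ri0[:, None], cj0[None, :], img].astype(np.float64)
    v01 = luts[ri0[:, None], cj1[None, :], img].astype(np.float64)
    v10 = luts[ri1[:, None], cj0[None, :], img].astype(np.float64)
    v11 = luts[ri1[:, None], cj1[None, :], img].astype(np.float64)
    out = (1 - wr) * ((1 - wc) * v00 + wc * v01) + wr * ((1 - wc) * v10 + wc * v11)
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def bilateral(
    image: np.ndarray,
    diameter: int = 9,
    sigma_color: float = 75.0,
    sigma_space: float = 75.0,
) -> np.ndarray:
    """Edge-preserving bilateral filter of a single-channel image.

    ``diameter`` is the full side length of the square neighbourhood (odd);
    ``sigma_color`` is in intensity units on the [0, 255] scale and
    ``sigma_space`` in pixels.
    """
    if sigma_color <= 0 or sigma_space <= 0:
        raise ValueError("bilateral sigmas must be > 0")
    if diameter < 1:
        raise ValueError("bilateral diameter must be >= 1")
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("bilateral operates on a single channel")
    r = int(diameter) // 2
    if r == 0:
        return np.clip(np.round(img), 0, 255).astype(np.uint8)
    padded = np.pad(img, r, mode="edge")
    num = np.zeros_like(img)
    den = np.zeros_like(img)
    inv2ss = 1.0 / (2.0 * sigma_space * sigma_space)
    inv2sc = 1.0 / (2.0 * sigma_color * sigma_color)
    H, W = img.shape
    for dy in range(-r, r + 1):
        for dx in range(-r, r + 1):
            w_space = np.exp(-(dx * dx + dy * dy) * inv2ss)
            shifted = padded[r + dy:r + dy + H, r + dx:r + dx + W]
            diff = shifted - img
            w = w_space * np.exp(-(diff * diff) * inv2sc)
            num += w * shifted
            den += w
    return np.clip(np.round(num / den), 0, 255).astype(np.uint8)


_YCBCR_FWD = np.array(
    [[0.299, 0.587, 0.114],
     [-0.168736, -0.331264, 0.5],
     [0.5, -0.418688, -0.081312]]
)


def rgb_to_ycbcr(rgb: np.ndarray) -> np.ndarray:
    """Full-range BT.601 RGB -> YCbCr (float64, Cb/Cr offset by 128)."""
    out = np.asarray(rgb, dtype=np.float64)[..., :3] @ _YCBCR_FWD.T
    out[..., 1:] += 128.0
    return out


def ycbcr_to_rgb(ycc: np.ndarray) -> np.ndarray:
    ycc = np.asarray(ycc, dtype=np.float64).copy()
    ycc[..., 1:] -= 128.0
    inv = np.linalg.inv(_YCBCR_FWD)
    rgb = ycc @ inv.T
    return np.clip(np.round(rgb), 0, 255).astype(np.uint8)
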