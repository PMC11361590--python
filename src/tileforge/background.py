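"""Background-over-tile (BoT) scoring.

A tile cut from an H&E slide may consist largely of blank glass (near
white, low saturation, high value) rather than tissue. BoT is the
fraction of a tile raster classified as such background by a fixed
pipeline:

    Gaussian blur (5×5) → RGB→HSV → background predicate
    (saturation ≤ sat_max AND value ≥ val_min) → binary mask →
    3×3 dilation → area fraction

and ToT = 1 − BoT ("tissue over tile") is the quantity the extraction
gate actually thresholds. The blur kernel replicates the standard 5-tap
discrete Gaussian (σ = 0.3·((k−1)/2 − 1) + 0.8) with reflect-101
borders, so a uniform tile stays uniform and the limit values are
exact: BoT = 1 on an all-background tile, 0 on an all-tissue tile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.color import rgb2hsv

__all__ = [
    "BackgroundParams",
    "BackgroundMask",
    "make_background_mask",
    "compute_bot",
    "tot",
    "as_tile_raster",
]


def as_tile_raster(tile: np.ndarray) -> np.ndarray:
    """Validate an 8-bit RGB tile raster (h×w×3 uint8)."""
    arr = np.asarray(tile)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise TypeError(f"expected h×w×3 RGB raster, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        raise TypeError(f"expected uint8 raster, got {arr.dtype}")
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise TypeError("raster must be non-empty")
    return arr


@dataclass(frozen=True)
class BackgroundParams:
    """Fixed operators and thresholds of the background pipeline.

    Thresholds are on 8-bit HSV scales: a pixel is a background
    candidate when saturation ≤ ``sat_max`` and value ≥ ``val_min``
    (defaults target white glass on H&E slides; stained tissue has
    high saturation). ``area_mode`` chooses how mask area is measured:
    ``pixel_count`` counts nonzero mask pixels; ``contour_fill`` fills
    holes inside background blobs first, so enclosed specks count as
    background.
    """

    blur_kernel: int = 5
    sat_max: float = 20.0
    val_min: float = 235.0
    combine: str = "and"
    dilate_kernel: int = 3
    dilate_iters: int = 1
    area_mode: str = "contour_fill"

    def __post_init__(self) -> None:
        for k in (self.blur_kernel, self.dilate_kernel):
            if k < 1 or k % 2 == 0:
                raise ValueError("kernels must be odd and >= 1")
        if not (0 <= self.sat_max <= 255 and 0 <= self.val_min <= 255):
            raise ValueError("HSV thresholds must lie in [0, 255]")
        if self.combine not in ("and", "or"):
            raise ValueError("combine must be 'and' or 'or'")
        if self.area_mode not in ("pixel_count", "contour_fill"):
            raise ValueError("area_mode must be 'pixel_count' or 'contour_fill'")
        if self.dilate_iters < 0:
            raise ValueError("dilate_iters must be >= 0")


@dataclass(frozen=True)
class BackgroundMask:
    """Binary background mask plus its measured area in px²."""

    mask: np.ndarray = field(compare=False)
    s_bg: int

    def __post_init__(self) -> None:
        if self.s_bg > self.mask.size:
            raise ValueError("background area cannot exceed tile area")


def _gaussian_blur(img: np.ndarray, kernel: int) -> np.ndarray:
    """Separable k-tap Gaussian, σ from the kernel size, mirror borders."""
    if kernel == 1:
        return img.astype(np.float64)
    sigma = 0.3 * ((kernel - 1) * 0.5 - 1) + 0.8
    r = (kernel - 1) // 2
    taps = np.exp(-0.5 * (np.arange(-r, r + 1) / sigma) ** 2)
    taps /= taps.sum()
    out = img.astype(np.float64)
    for axis in (0, 1):
        out = ndimage.correlate1d(out, taps, axis=axis, mode="mirror")
    return out


def make_background_mask(tile: np.ndarray, params: BackgroundParams | None = None) -> BackgroundMask:
    """Run the blur → HSV → threshold → dilate pipeline on one tile."""
    params = params or BackgroundParams()
    arr = as_tile_raster(tile)
    blurred = _gaussian_blur(arr, params.blur_kernel)
    hsv = rgb2hsv(blurred / 255.0)
    sat = hsv[..., 1] * 255.0
    val = hsv[..., 2] * 255.0
    if params.combine == "and":
        mask = (sat <= params.sat_max) & (val >= params.val_min)
    else:
        mask = (sat <= params.sat_max) | (val >= params.val_min)
    if params.dilate_iters > 0 and params.dilate_kernel > 1:
        mask = ndimage.binary_dilation(
            mask,
            structure=np.ones((params.dilate_kernel, params.dilate_kernel), bool),
            iterations=params.dilate_iters,
        )
    if params.area_mode == "contour_fill":
        s_bg = int(ndimage.binary_fill_holes(mask).sum())
    else:
        s_bg = int(mask.sum())
    return BackgroundMask(mask=mask, s_bg=s_bg)


def compute_bot(tile: np.ndarray, params: BackgroundParams | None = None) -> float:
    """Background fraction s_bg / (h·w) of one tile, in [0, 1]."""
    arr = as_tile_raster(tile)
    bg = make_background_mask(arr, params)
    return float(min(max(bg.s_bg / arr[..., 0].size, 0.0), 1.0))


def tot(bot: float) -> float:
    """Tissue over tile: 1 − BoT."""
    if not 0.0 <= bot <= 1.0:
        raise ValueError(f"BoT must lie in [0, 1], got {bot}")
    return 1.0 - bot
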