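"""Thin, swappable access to pyramidal slides.

Slides are pyramidal TIFFs (multi-resolution, SubIFD or multi-page) read
with tifffile; a flat PNG/JPEG is accepted as a one-level pyramid via
Pillow. Tile footprints are always expressed in level-0 coordinates with
level-0 extents; the raster returned for a footprint read at level k has
``extent / downsample[k]`` pixels per side, which keeps IoT — a level-0
geometric quantity — independent of the extraction level.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import tifffile
from PIL import Image

from .geometry import TileFootprint

__all__ = ["SlideHandle", "open_slide", "read_region"]


@dataclass
class SlideHandle:
    """An opened slide: per-level dimensions plus lazily cached pixels."""

    slide_id: str
    path: str
    level_dims: tuple[tuple[int, int], ...]  # (w, h) per level
    downsamples: tuple[float, ...]
    mpp: float | None = None  # microns per pixel at level 0, when recorded
    read_count: int = 0
    _levels: dict = field(default_factory=dict, repr=False)

    @property
    def level_count(self) -> int:
        return len(self.level_dims)

    @property
    def dimensions(self) -> tuple[int, int]:
        """(w, h) at level 0."""
        return self.level_dims[0]

    def _level_array(self, level: int) -> np.ndarray:
        if level not in self._levels:
            self._levels[level] = _load_level(self.path, level)
        return self._levels[level]


def _flatten_rgba(arr: np.ndarray) -> np.ndarray:
    """Drop or composite an alpha channel against white."""
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[2] == 4:
        alpha = arr[..., 3:4].astype(np.float64) / 255.0
        rgb = arr[..., :3].astype(np.float64)
        arr = np.rint(rgb * alpha + 255.0 * (1.0 - alpha)).astype(np.uint8)
    return np.ascontiguousarray(arr[..., :3])


def _is_tiff(path: str) -> bool:
    return str(path).lower().endswith((".tif", ".tiff", ".svs"))


def _load_level(path: str, level: int) -> np.ndarray:
    if _is_tiff(path):
        with tifffile.TiffFile(path) as tf:
            arr = tf.series[0].levels[level].asarray()
    else:
        arr = np.asarray(Image.open(path).convert("RGBA"))
    return _flatten_rgba(arr)


def open_slide(path: str) -> SlideHandle:
    """Open a pyramidal TIFF (or flat image) and read its level metadata."""
    if not os.path.exists(path):
        raise OSError(f"slide file not found: {path}")
    slide_id = os.path.splitext(os.path.basename(str(path)))[0]
    mpp = None
    if _is_tiff(path):
        try:
            with tifffile.TiffFile(path) as tf:
                levels = tf.series[0].levels
                dims = []
                for lv in levels:
                    shape = lv.shape
                    h, w = shape[0], shape[1]
                    dims.append((int(w), int(h)))
                page = tf.pages[0]
                res = page.tags.get("XResolution")
                unit = page.tags.get("ResolutionUnit")
                if res is not None and unit is not None and getattr(unit.value, "name", "") == "CENTIMETER":
                    num, den = res.value
                    if num:
                        mpp = 1e4 * den / num
        except (tifffile.TiffFileError, IndexError) as exc:
            raise OSError(f"cannot read {path} as a pyramidal TIFF: {exc}") from exc
    else:
        try:
            with Image.open(path) as im:
                dims = [(im.width, im.height)]
        except OSError as exc:
            raise OSError(f"cannot read {path} as an image: {exc}") from exc
    w0, h0 = dims[0]
    downs = tuple(round(w0 / w, 6) for w, _ in dims)
    if list(downs) != sorted(downs):
        raise OSError(f"{path}: pyramid levels are not ordered largest first")
    return SlideHandle(
        slide_id=slide_id,
        path=str(path),
        level_dims=tuple(dims),
        downsamples=downs,
        mpp=mpp,
    )


def read_region(handle: SlideHandle, tile: TileFootprint) -> np.ndarray:
    """Read the RGB raster for a footprint at its stated pyramid level.

    The footprint must lie fully inside the level-0 bounds: an
    overlapping read raises instead of silently padding.
    """
    if not 0 <= tile.level < handle.level_count:
        raise ValueError(f"level {tile.level} outside 0..{handle.level_count - 1}")
    w0, h0 = handle.dimensions
    if tile.x + tile.w > w0 or tile.y + tile.h > h0:
        raise ValueError(
            f"footprint ({tile.x}, {tile.y}, {tile.w}, {tile.h}) exceeds "
            f"slide bounds {w0}×{h0}"
        )
    ds = handle.downsamples[tile.level]
    x = int(round(tile.x / ds))
    y = int(round(tile.y / ds))
    w = int(round(tile.w / ds))
    h = int(round(tile.h / ds))
    arr = handle._level_array(tile.level)
    handle.read_count += 1
    return np.ascontiguousarray(arr[y:y + h, x:x + w])
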