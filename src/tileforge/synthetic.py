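"""Synthetic pyramidal slides with analytic ground truth.

Every capability of the extraction pipeline is testable without
downloading gigapixel slides: this module paints small pyramidal TIFFs
emulating an H&E scan (saturated "tissue" blobs on a near-white glass
background), writes a matching plain_json annotation file, and
tabulates per-tile ground truth — exact IoT per label, the ideal
tissue fraction, and the expected gate decision for every preset of
the threshold ladder.

Two deliberate design points make the ground truth exact rather than
approximate:

* painted color blobs in the preset-exactness cases are axis-aligned
  to the tile grid, so every tile raster is uniform and its BoT is
  exactly 0 or 1 (blur and dilation are no-ops on a uniform tile);
* annotation polygons are decoupled from the painted blobs, so IoT
  still sweeps through fractional values.

IoT ground truth is closed-form for axis-aligned annotations and uses
the scanline rasterization oracle at g = 4096 for curved ones; the
generator asserts every non-exact IoT keeps a ≥ 0.01 margin from each
preset threshold, so oracle round-off can never flip a decision.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile

from .annotation_io import AnnotatedRegion, AnnotationSet, write_plain_json
from .geometry import RegionUnion, TileFootprint, rasterized_iot_oracle, region_union
from .tiler import _PRESETS

__all__ = [
    "Blob",
    "FixtureSpec",
    "GroundTruth",
    "generate_fixture",
    "make_basic_case",
    "make_offset_grid_case",
    "make_checkerboard_case",
    "make_concave_case",
    "CASES",
    "TISSUE_RGB",
    "BACKGROUND_RGB",
]

#: default paint colors; both sit far (≥ 30 units on the governing HSV
#: channel) from the default background predicate's decision boundary
BACKGROUND_RGB = (245, 245, 245)
TISSUE_RGB = (200, 100, 150)

_THRESHOLD_MARGIN = 0.01


@dataclass(frozen=True)
class Blob:
    """One painted shape. bbox = (x0, y0, x1, y1) in level-0 px."""

    shape: str  # rectangle | ellipse | crescent
    bbox: tuple[float, float, float, float]
    rgb: tuple[int, int, int] = TISSUE_RGB
    # crescent only: the removed inner disc, as (cx, cy, r)
    notch: tuple[float, float, float] | None = None


@dataclass
class FixtureSpec:
    """Recipe for one synthetic slide + annotation file + ground truth."""

    name: str
    canvas: tuple[int, int]  # (W, H) level-0 px
    blobs: list[Blob] = field(default_factory=list)
    annotations: list[AnnotatedRegion] = field(default_factory=list)
    background_rgb: tuple[int, int, int] = BACKGROUND_RGB
    levels: int = 3
    tile_size: int = 512
    seed: int = 0
    #: tiles whose painted content is grid-aligned have exact {0,1}
    #: tissue fractions; curved-color fixtures set this False and are
    #: excluded from bit-exact preset checks
    colors_grid_aligned: bool = True

    def __post_init__(self) -> None:
        W, H = self.canvas
        d = 2 ** (self.levels - 1)
        if W % d or H % d:
            raise ValueError("canvas must be divisible by 2**(levels-1)")
        for b in self.blobs:
            x0, y0, x1, y1 = b.bbox
            if not (0 <= x0 < x1 <= W and 0 <= y0 < y1 <= H):
                raise ValueError(f"blob bbox {b.bbox} outside canvas {self.canvas}")


@dataclass
class GroundTruth:
    """Per-grid-tile expectations at the spec'd tile size.

    ``table`` has one row per grid tile with columns x, y, iot,
    tissue_fraction and decision_<preset> for every preset name.
    Decisions follow the inclusive gate pair with IoT short-circuit:
    rejected_iot if iot < iot_thresh, else rejected_bot if
    tissue < tot_thresh, else extracted.
    """

    tile_size: int
    label: str
    table: pd.DataFrame

    def decision(self, preset: str) -> pd.Series:
        return self.table[f"decision_{preset}"]


def _expected_decision(iot: float, tissue: float, iot_t: float, tot_t: float) -> str:
    if iot < iot_t:
        return "rejected_iot"
    if tissue < tot_t:
        return "rejected_bot"
    return "extracted"


# ---------------------------------------------------------------------------
# painting

def _paint(spec: FixtureSpec) -> np.ndarray:
    W, H = spec.canvas
    img = np.empty((H, W, 3), np.uint8)
    img[:] = np.asarray(spec.background_rgb, np.uint8)
    for b in spec.blobs:
        x0, y0, x1, y1 = (int(round(v)) for v in b.bbox)
        if b.shape == "rectangle":
            img[y0:y1, x0:x1] = b.rgb
        elif b.shape in ("ellipse", "crescent"):
            yy, xx = np.mgrid[y0:y1, x0:x1]
            cx, cy = (x0 + x1) / 2.0, (y0 + y1) / 2.0
            rx, ry = (x1 - x0) / 2.0, (y1 - y0) / 2.0
            inside = ((xx + 0.5 - cx) / rx) ** 2 + ((yy + 0.5 - cy) / ry) ** 2 <= 1.0
            if b.shape == "crescent":
                if b.notch is None:
                    raise ValueError("crescent blob needs a notch disc")
                ncx, ncy, nr = b.notch
                inside &= (xx + 0.5 - ncx) ** 2 + (yy + 0.5 - ncy) ** 2 > nr ** 2
            sub = img[y0:y1, x0:x1]
            sub[inside] = b.rgb
        else:
            raise ValueError(f"unknown blob shape {b.shape!r}")
    return img


def _pyramid(level0: np.ndarray, levels: int) -> list[np.ndarray]:
    out = [level0]
    for _ in range(levels - 1):
        a = out[-1].astype(np.float64)
        h, w = a.shape[:2]
        pooled = a.reshape(h // 2, 2, w // 2, 2, 3).mean(axis=(1, 3))
        out.append(np.rint(pooled).astype(np.uint8))
    return out


def write_pyramid_tiff(levels: list[np.ndarray], path: str) -> None:
    """Tiled multi-resolution TIFF via SubIFDs; byte-deterministic."""
    with tifffile.TiffWriter(path, bigtiff=False) as tw:
        tw.write(
            levels[0], subifds=len(levels) - 1, tile=(256, 256),
            photometric="rgb", compression=None, software="tileforge",
        )
        for lv in levels[1:]:
            tw.write(
                lv, subfiletype=1, tile=(256, 256),
                photometric="rgb", compression=None, software="tileforge",
            )


# ---------------------------------------------------------------------------
# ground truth

def _rect_overlap_fraction(tile: TileFootprint, bbox) -> float:
    x0, y0, x1, y1 = bbox
    ox = max(0.0, min(tile.x + tile.w, x1) - max(tile.x, x0))
    oy = max(0.0, min(tile.y + tile.h, y1) - max(tile.y, y0))
    return (ox * oy) / tile.area


def _tissue_fraction(tile: TileFootprint, spec: FixtureSpec) -> float:
    frac = 0.0
    for b in spec.blobs:
        if b.shape == "rectangle":
            frac += _rect_overlap_fraction(tile, b.bbox)
        else:
            # curved blobs: pixel-count fraction at level 0
            x0, y0 = int(tile.x), int(tile.y)
            raster = _paint(spec)[y0:y0 + int(tile.h), x0:x0 + int(tile.w)]
            return float(np.all(raster != spec.background_rgb, axis=-1).mean())
    return min(frac, 1.0)


def _axis_aligned(region: AnnotatedRegion) -> tuple | None:
    """bbox if the region is an axis-aligned hole-free rectangle."""
    if region.holes:
        return None
    pts = list(dict.fromkeys(region.exterior))
    if len(pts) != 4:
        return None
    xs = sorted({p[0] for p in pts})
    ys = sorted({p[1] for p in pts})
    if len(xs) != 2 or len(ys) != 2:
        return None
    return (xs[0], ys[0], xs[1], ys[1])


def _gt_iot(tile: TileFootprint, annots: AnnotationSet, label: str,
            union: RegionUnion) -> tuple[float, bool]:
    """(iot, exact) ground-truth IoT for one tile and label."""
    regions = annots.filter(label)
    bboxes = [_axis_aligned(r) for r in regions]
    if all(b is not None for b in bboxes) and len(bboxes) == 1:
        return _rect_overlap_fraction(tile, bboxes[0]), True
    # curved or multiple regions: scanline oracle on the same polygons
    v = rasterized_iot_oracle(union, tile, g=4096)
    if v in (0.0, 1.0):
        return v, True
    return v, False


def _ground_truth(spec: FixtureSpec, annots: AnnotationSet, label: str) -> GroundTruth:
    from .tiler import partition

    W, H = spec.canvas
    union = region_union(annots, label)
    rows = []
    for fp in partition(W, H, spec.tile_size):
        iot, exact = _gt_iot(fp, annots, label, union)
        tissue = _tissue_fraction(fp, spec)
        row = {"x": fp.x, "y": fp.y, "iot": iot, "tissue_fraction": tissue}
        for name, (iot_t, tot_t) in _PRESETS.items():
            if not exact and abs(iot - iot_t) < _THRESHOLD_MARGIN:
                raise AssertionError(
                    f"fixture {spec.name}: tile ({fp.x},{fp.y}) IoT {iot:.4f} "
                    f"is within {_THRESHOLD_MARGIN} of threshold {iot_t}"
                )
            row[f"decision_{name}"] = _expected_decision(iot, tissue, iot_t, tot_t)
        rows.append(row)
    return GroundTruth(tile_size=spec.tile_size, label=label, table=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# generation

@dataclass
class FixtureResult:
    spec: FixtureSpec
    slide_path: str
    annotation_path: str
    ground_truth: GroundTruth
    ground_truth_path: str


def generate_fixture(spec: FixtureSpec, out_dir: str) -> FixtureResult:
    """Write slide TIFF + plain_json annotations + ground-truth CSV.

    Deterministic for a fixed spec: rerunning produces byte-identical
    files.
    """
    os.makedirs(out_dir, exist_ok=True)
    level0 = _paint(spec)
    slide_path = os.path.join(out_dir, f"{spec.name}.tiff")
    write_pyramid_tiff(_pyramid(level0, spec.levels), slide_path)

    annots = AnnotationSet(slide_id=spec.name, regions=list(spec.annotations))
    ann_path = os.path.join(out_dir, f"{spec.name}.json")
    write_plain_json(annots, ann_path)

    label = spec.annotations[0].label if spec.annotations else "tumor"
    gt = _ground_truth(spec, annots, label)
    gt_path = os.path.join(out_dir, f"{spec.name}_ground_truth.csv")
    gt.table.to_csv(gt_path, index=False)
    return FixtureResult(spec=spec, slide_path=slide_path, annotation_path=ann_path,
                         ground_truth=gt, ground_truth_path=gt_path)


def _square_ring(x0, y0, x1, y1) -> list[tuple[float, float]]:
    return [(x0, y0), (x1, y0), (x1, y1), (x0, y1)]


def _circle_ring(cx, cy, r, n=256, ccw=True) -> list[tuple[float, float]]:
    sign = 1.0 if ccw else -1.0
    ang = [2 * math.pi * sign * i / n for i in range(n)]
    return [(cx + r * math.cos(a), cy + r * math.sin(a)) for a in ang]


def make_basic_case() -> FixtureSpec:
    """A 1024² tissue square aligned to the 512 grid on a white canvas,
    annotated exactly; 4 tiles have IoT = 1, all others 0."""
    sq = (512.0, 512.0, 1536.0, 1536.0)
    return FixtureSpec(
        name="basic",
        canvas=(2048, 2048),
        blobs=[Blob("rectangle", sq)],
        annotations=[AnnotatedRegion(label="tumor", exterior=_square_ring(*sq),
                                     region_id="sq0")],
    )


def make_offset_grid_case() -> FixtureSpec:
    """Annotation offset half a tile from the painted square.

    The annotation covers [256, 1280)²: per-tile IoT is the product of
    per-axis overlap fractions, giving the 3×3 pattern {0.25, 0.5,
    1.0}. The paint stays grid-aligned on [512, 1536)² so BoT remains
    exactly 0 or 1 per tile.
    """
    return FixtureSpec(
        name="offset_grid",
        canvas=(2048, 2048),
        blobs=[Blob("rectangle", (512.0, 512.0, 1536.0, 1536.0))],
        annotations=[AnnotatedRegion(label="tumor",
                                     exterior=_square_ring(256.0, 256.0, 1280.0, 1280.0),
                                     region_id="off0")],
    )


def make_checkerboard_case() -> FixtureSpec:
    """Alternating tissue/background 512 px squares; annotation covers
    the full canvas so the tissue gate alone decides."""
    blobs = [
        Blob("rectangle", (i * 512.0, j * 512.0, (i + 1) * 512.0, (j + 1) * 512.0))
        for j in range(4) for i in range(4) if (i + j) % 2 == 0
    ]
    return FixtureSpec(
        name="checkerboard",
        canvas=(2048, 2048),
        blobs=blobs,
        annotations=[AnnotatedRegion(label="tumor",
                                     exterior=_square_ring(0.0, 0.0, 2048.0, 2048.0),
                                     region_id="all")],
    )


def make_concave_case() -> tuple[FixtureSpec, TileFootprint]:
    """The concave-region failure case for corner/midpoint probing.

    A disc annotation (radius 480, centered on grid tile (1, 1)) has a
    small notch disc removed near the tile's top edge, placed between
    two probe points. All four corners and all four edge midpoints of
    the 512 px tile at (512, 512) lie inside the region, yet IoT < 1 —
    an eight-point containment heuristic would extract the tile as
    fully positive. Paint is a grid-aligned square covering the disc,
    so per-tile BoT stays exact.
    """
    cx, cy, r = 768.0, 768.0, 480.0
    notch = (896.0, 512.0, 60.0)
    exterior = _circle_ring(cx, cy, r, n=256, ccw=True)
    hole = _circle_ring(*notch, n=256, ccw=False)
    spec = FixtureSpec(
        name="concave",
        canvas=(2048, 2048),
        blobs=[Blob("rectangle", (0.0, 0.0, 1536.0, 1536.0))],
        annotations=[AnnotatedRegion(label="tumor", exterior=exterior,
                                     holes=[hole], region_id="crescent0")],
    )
    probe_tile = TileFootprint(x=512, y=512, w=512, h=512)
    return spec, probe_tile


def probe_points(tile: TileFootprint) -> list[tuple[float, float]]:
    """The four corners and four edge midpoints of a tile — the probe
    set of the prior containment heuristic."""
    x0, y0 = tile.x, tile.y
    x1, y1 = tile.x + tile.w, tile.y + tile.h
    xm, ym = (x0 + x1) / 2, (y0 + y1) / 2
    return [(x0, y0), (x1, y0), (x0, y1), (x1, y1),
            (xm, y0), (xm, y1), (x0, ym), (x1, ym)]


CASES = {
    "basic": make_basic_case,
    "offset_grid": make_offset_grid_case,
    "checkerboard": make_checkerboard_case,
    "concave": lambda: make_concave_case()[0],
}
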