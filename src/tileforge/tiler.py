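"""Threshold-gated tile extraction from whole-slide images.

The engine partitions a slide into a non-overlapping grid from the top
left corner, then runs each grid location through two inclusive gates:

1. IoT gate (annotated mode only): the tile's intersection-over-tile
   against the union of selected annotation labels must reach
   ``iot_thresh``. Tiles failing this gate are never read from disk —
   the background gate is short-circuited.
2. Tissue gate: the tile raster is read and its background fraction
   (BoT) computed; the tile is kept iff 1 − BoT ≥ ``tot_thresh``.

Holistic mode skips the IoT gate and reads every grid tile. An optional
uniform random subsample (e.g. 10% of the tiles of a negative slide)
can be applied after the tissue gate (default, so sampled tiles are
guaranteed non-blank) or before it.

Every grid location gets exactly one auditable TileRecord; the manifest
of one run round-trips through CSV plus a JSON config sidecar.
"""

from __future__ import annotations

import dataclasses
import json
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image

from .annotation_io import AnnotationSet
from .background import BackgroundParams, compute_bot
from .geometry import RegionUnion, TileFootprint, compute_iot, region_union
from .wsi_access import SlideHandle, read_region

__all__ = [
    "ExtractionConfig",
    "TileRecord",
    "ExtractionManifest",
    "partition",
    "extract_annotated",
    "extract_holistic",
    "sample_records",
    "threshold_presets",
    "TRAINING_PRESET_NAMES",
    "write_manifest",
    "read_manifest",
    "write_tile",
]

DECISIONS = ("extracted", "rejected_iot", "rejected_bot", "rejected_sampling")


@dataclass(frozen=True)
class ExtractionConfig:
    """One extraction run's thresholds and bookkeeping.

    ``tile_size`` is in pixels at the extraction ``level``;
    ``iot_thresh`` and ``tot_thresh`` (the tissue threshold compared
    against 1 − BoT) are fractions in [0, 1] and the gates are
    inclusive (≥). ``iot_thresh = 0`` admits every tile to the tissue
    gate. ``labels`` selects which annotation labels form the positive
    union (None = all). ``out_dir = None`` runs a dry pass producing a
    manifest but writing no tile images.
    """

    tile_size: int = 512
    level: int = 0
    iot_thresh: float = 0.0
    tot_thresh: float = 0.0
    labels: frozenset[str] | None = None
    bg_params: BackgroundParams = field(default_factory=BackgroundParams)
    sample_fraction: float = 1.0
    sample_stage: str = "after_bot"
    seed: int = 0
    out_format: str = "png"
    out_dir: str | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.tile_size <= 0:
            raise ValueError("tile_size must be positive")
        for t in (self.iot_thresh, self.tot_thresh):
            if not 0.0 <= t <= 1.0:
                raise ValueError("thresholds must lie in [0, 1]")
        if not 0.0 < self.sample_fraction <= 1.0:
            raise ValueError("sample_fraction must lie in (0, 1]")
        if self.sample_stage not in ("after_bot", "before_bot"):
            raise ValueError("sample_stage must be 'after_bot' or 'before_bot'")
        if self.out_format not in ("png", "jpeg"):
            raise ValueError("out_format must be 'png' or 'jpeg'")
        if self.labels is not None and not isinstance(self.labels, frozenset):
            object.__setattr__(self, "labels", frozenset(self.labels))


@dataclass
class TileRecord:
    """Outcome for one grid location.

    ``iot`` is None when not computed (holistic mode); ``bot`` is None
    when the tile was rejected before being read. ``out_path`` is set
    exactly when the decision is ``extracted``.
    """

    slide_id: str
    footprint: TileFootprint
    iot: float | None
    bot: float | None
    decision: str
    out_path: str | None = None


@dataclass
class ExtractionManifest:
    """Auditable result of one extraction run."""

    slide_id: str
    config: ExtractionConfig
    records: list[TileRecord]
    timing_seconds: float = 0.0

    @property
    def counts(self) -> dict[str, int]:
        c = {d: 0 for d in DECISIONS}
        for r in self.records:
            c[r.decision] += 1
        return c

    @property
    def extracted(self) -> list[TileRecord]:
        return [r for r in self.records if r.decision == "extracted"]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "slide_id": r.slide_id,
                "x": r.footprint.x,
                "y": r.footprint.y,
                "w": r.footprint.w,
                "h": r.footprint.h,
                "level": r.footprint.level,
                "iot": r.iot,
                "bot": r.bot,
                "decision": r.decision,
                "out_path": r.out_path,
            }
            for r in self.records
        ]
        return pd.DataFrame(
            rows,
            columns=["slide_id", "x", "y", "w", "h", "level", "iot", "bot",
                     "decision", "out_path"],
        )


def partition(slide_w: int, slide_h: int, tile_size_l0: int) -> list[TileFootprint]:
    """Non-overlapping grid footprints from the top-left corner.

    Partial edge tiles are dropped (floor division); order is
    row-major (y outer, x inner) and deterministic. A tile larger than
    the slide yields an empty list.
    """
    if tile_size_l0 <= 0:
        raise ValueError("tile size must be positive")
    nx = slide_w // tile_size_l0
    ny = slide_h // tile_size_l0
    return [
        TileFootprint(x=i * tile_size_l0, y=j * tile_size_l0,
                      w=tile_size_l0, h=tile_size_l0)
        for j in range(ny)
        for i in range(nx)
    ]


def _grid(handle: SlideHandle, cfg: ExtractionConfig) -> list[TileFootprint]:
    ds = handle.downsamples[cfg.level]
    ts_l0 = int(round(cfg.tile_size * ds))
    w0, h0 = handle.dimensions
    return [
        TileFootprint(x=fp.x, y=fp.y, w=fp.w, h=fp.h, level=cfg.level)
        for fp in partition(w0, h0, ts_l0)
    ]


def tile_filename(slide_id: str, fp: TileFootprint, tile_size: int, ext: str) -> str:
    """Canonical tile name; the footprint is recoverable from it."""
    return f"{slide_id}__x{int(fp.x)}_y{int(fp.y)}_l{fp.level}_ts{tile_size}.{ext}"


def write_tile(raster: np.ndarray, path: str, fmt: str = "png") -> None:
    """Write one tile raster as PNG (lossless) or JPEG (quality 90)."""
    img = Image.fromarray(raster, mode="RGB")
    if fmt == "png":
        img.save(path, format="PNG")
    elif fmt == "jpeg":
        img.save(path, format="JPEG", quality=90)
    else:
        raise ValueError(f"unsupported tile format {fmt!r}")


def _tissue_gate(handle: SlideHandle, rec: TileRecord, cfg: ExtractionConfig) -> np.ndarray | None:
    """Read the tile, score BoT, set the record's decision. Returns the
    raster when the tile passed."""
    raster = read_region(handle, rec.footprint)
    rec.bot = compute_bot(raster, cfg.bg_params)
    if 1.0 - rec.bot >= cfg.tot_thresh:
        rec.decision = "extracted"
        return raster
    rec.decision = "rejected_bot"
    return None


def _maybe_write(handle, rec, raster, cfg: ExtractionConfig) -> None:
    if cfg.out_dir is None or raster is None:
        return
    os.makedirs(cfg.out_dir, exist_ok=True)
    name = tile_filename(rec.slide_id, rec.footprint, cfg.tile_size, cfg.out_format)
    path = os.path.join(cfg.out_dir, name)
    write_tile(raster, path, cfg.out_format)
    rec.out_path = name


def _run(handle: SlideHandle, union: RegionUnion | None, cfg: ExtractionConfig) -> ExtractionManifest:
    t0 = time.perf_counter()
    records: list[TileRecord] = []
    for fp in _grid(handle, cfg):
        rec = TileRecord(slide_id=handle.slide_id, footprint=fp,
                         iot=None, bot=None, decision="rejected_iot")
        if union is not None:
            rec.iot = compute_iot(union, fp)
            if rec.iot < cfg.iot_thresh:
                records.append(rec)  # BoT short-circuited, tile never read
                continue
        rec.decision = "pending"
        records.append(rec)

    pending = [r for r in records if r.decision == "pending"]
    if cfg.sample_fraction < 1.0 and cfg.sample_stage == "before_bot":
        keep = _sample_indices(len(pending), cfg.sample_fraction, cfg.seed)
        for i, rec in enumerate(pending):
            if i not in keep:
                rec.decision = "rejected_sampling"
        pending = [r for r in pending if r.decision == "pending"]

    rasters: dict[int, np.ndarray] = {}
    for rec in pending:
        raster = _tissue_gate(handle, rec, cfg)
        if raster is not None:
            rasters[id(rec)] = raster

    if cfg.sample_fraction < 1.0 and cfg.sample_stage == "after_bot":
        kept = [r for r in records if r.decision == "extracted"]
        keep = _sample_indices(len(kept), cfg.sample_fraction, cfg.seed)
        for i, rec in enumerate(kept):
            if i not in keep:
                rec.decision = "rejected_sampling"
                rasters.pop(id(rec), None)

    for rec in records:
        if rec.decision == "extracted":
            _maybe_write(handle, rec, rasters.get(id(rec)), cfg)

    return ExtractionManifest(
        slide_id=handle.slide_id,
        config=cfg,
        records=records,
        timing_seconds=time.perf_counter() - t0,
    )


def extract_annotated(handle: SlideHandle, annots: AnnotationSet, cfg: ExtractionConfig) -> ExtractionManifest:
    """Annotation-guided extraction: IoT gate, then tissue gate."""
    if annots.space != "level0_pixels":
        raise ValueError("annotation coordinate space must be level0_pixels")
    union = region_union(annots, cfg.labels)
    return _run(handle, union, cfg)


def extract_holistic(handle: SlideHandle, cfg: ExtractionConfig) -> ExtractionManifest:
    """Whole-slide extraction using the tissue gate only."""
    return _run(handle, None, cfg)


def _sample_indices(n: int, fraction: float, seed: int) -> set[int]:
    if n == 0:
        return set()
    k = max(1, round(n * fraction))
    rng = np.random.default_rng(seed)
    return set(rng.choice(n, size=k, replace=False).tolist())


def sample_records(records: list[TileRecord], fraction: float, seed: int) -> list[TileRecord]:
    """Uniform subsample (without replacement) of the extracted records.

    Keeps round(n·fraction) extracted records, at least 1 when any
    exist; the others become ``rejected_sampling``. Reproducible for a
    fixed seed. Returns the kept records.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    kept = [r for r in records if r.decision == "extracted"]
    keep = _sample_indices(len(kept), fraction, seed)
    out = []
    for i, rec in enumerate(kept):
        if i in keep:
            out.append(rec)
        else:
            rec.decision = "rejected_sampling"
            rec.out_path = None
    return out


# ---------------------------------------------------------------------------
# preset threshold ladder

#: (iot_thresh, tot_thresh) pairs of the named training sets, plus the
#: stricter-IoT / looser-tissue "test" preset used for hold-out slides.
_PRESETS: dict[str, tuple[float, float]] = {
    "A": (0.1, 0.0),
    "B": (0.2, 0.0),
    "C": (0.2, 0.2),
    "D": (0.2, 0.5),
    "E": (0.5, 0.2),
    "F": (0.5, 0.5),
    "G": (1.0, 0.2),
    "H": (1.0, 0.5),
    "test": (0.3, 0.3),
}

TRAINING_PRESET_NAMES = tuple("ABCDEFGH")


def threshold_presets(dataset_tag: str = "cam", **overrides) -> dict[str, ExtractionConfig]:
    """The named (IoT, 1−BoT) threshold ladder as ready-made configs.

    Eight training presets A–H sweep iot_thresh over {0.1, 0.2, 0.5,
    1.0} and tot_thresh over {0.0, 0.2, 0.5}; the ``test`` preset is
    (0.3, 0.3). ``dataset_tag`` ("cam" or "paip") selects the native
    scan setting the defaults emulate — both use 512 px tiles at
    level 0. Extra keyword arguments override config fields.
    """
    if dataset_tag not in ("cam", "paip"):
        raise ValueError(f"unknown dataset tag {dataset_tag!r}")
    return {
        name: ExtractionConfig(name=name, iot_thresh=iot, tot_thresh=tt, **overrides)
        for name, (iot, tt) in _PRESETS.items()
    }


# ---------------------------------------------------------------------------
# manifest I/O

def _config_dict(cfg: ExtractionConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["labels"] = sorted(cfg.labels) if cfg.labels is not None else None
    return d


def write_manifest(manifest: ExtractionManifest, path: str) -> None:
    """Write the manifest CSV plus a JSON sidecar of the config.

    The sidecar (``<path>.config.json``) also records the decision
    counts; timing is reported separately so manifest bytes are
    deterministic across runs.
    """
    manifest.to_frame().to_csv(path, index=False)
    sidecar = {
        "slide_id": manifest.slide_id,
        "config": _config_dict(manifest.config),
        "counts": manifest.counts,
    }
    with open(str(path) + ".config.json", "w") as fh:
        json.dump(sidecar, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_manifest(path: str) -> pd.DataFrame:
    """Read a manifest CSV back into a DataFrame."""
    return pd.read_csv(path)
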