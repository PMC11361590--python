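"""Run summaries and extraction-map previews.

The preview draws the slide thumbnail with annotation contours and
every grid tile outlined, color-coded by its manifest decision. The
decisions are read from the manifest — never recomputed — so a preview
can never disagree with the extraction it depicts.
"""

from __future__ import annotations

import numpy as np
from PIL import Image, ImageDraw

from .annotation_io import AnnotationSet
from .tiler import ExtractionManifest
from .wsi_access import SlideHandle

__all__ = ["preview_overlay", "timing_summary", "DECISION_COLORS"]

#: extracted tiles are blue (candidate tiles), IoT rejections red,
#: background rejections orange; sampling rejections gray
DECISION_COLORS = {
    "extracted": (0, 90, 255),
    "rejected_iot": (220, 30, 30),
    "rejected_bot": (255, 150, 0),
    "rejected_sampling": (130, 130, 130),
}

ANNOTATION_COLOR = (0, 170, 60)


def preview_overlay(
    handle: SlideHandle,
    manifest: ExtractionManifest,
    annots: AnnotationSet | None = None,
    thumb_long_side: int = 1024,
    colors: dict[str, tuple[int, int, int]] | None = None,
) -> Image.Image:
    """Thumbnail with annotation contours and decision-coded tile boxes."""
    if thumb_long_side < 64:
        raise ValueError("thumbnail must be at least 64 px on its long side")
    colors = {**DECISION_COLORS, **(colors or {})}
    w0, h0 = handle.dimensions
    scale = thumb_long_side / max(w0, h0)
    tw, th = max(1, round(w0 * scale)), max(1, round(h0 * scale))

    # render from the coarsest pyramid level that still covers the thumbnail
    level = handle.level_count - 1
    while level > 0 and handle.level_dims[level][0] < tw:
        level -= 1
    base = handle._level_array(level)
    img = Image.fromarray(base, mode="RGB").resize((tw, th), Image.BILINEAR)
    draw = ImageDraw.Draw(img)

    for rec in manifest.records:
        fp = rec.footprint
        draw.rectangle(
            [fp.x * scale, fp.y * scale, (fp.x + fp.w) * scale, (fp.y + fp.h) * scale],
            outline=colors.get(rec.decision, (0, 0, 0)),
            width=2 if rec.decision == "extracted" else 1,
        )
    if annots is not None:
        for region in annots.regions:
            pts = [(x * scale, y * scale) for x, y in region.exterior]
            draw.polygon(pts, outline=ANNOTATION_COLOR)
            for hole in region.holes:
                draw.polygon([(x * scale, y * scale) for x, y in hole],
                             outline=ANNOTATION_COLOR)
    return img


def timing_summary(per_slide_seconds: list[float]) -> dict[str, float]:
    """Per-slide wall-time statistics.

    Returns min, max, mean, std, variance, Q1, median, Q3 (quartiles by
    linear interpolation) and total. Std and variance are the sample
    (ddof = 1) statistics; a single observation has variance 0.
    """
    if len(per_slide_seconds) == 0:
        raise ValueError("timing summary needs at least one observation")
    a = np.asarray(per_slide_seconds, dtype=float)
    ddof = 1 if a.size > 1 else 0
    return {
        "min": float(a.min()),
        "max": float(a.max()),
        "mean": float(a.mean()),
        "std": float(a.std(ddof=ddof)),
        "variance": float(a.var(ddof=ddof)),
        "q1": float(np.percentile(a, 25)),
        "median": float(np.percentile(a, 50)),
        "q3": float(np.percentile(a, 75)),
        "total": float(a.sum()),
    }
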