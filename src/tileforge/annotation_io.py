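"""Read and validate region annotations for whole-slide images.

Annotations are hand-drawn polygons (possibly concave, possibly with
holes) delimiting a tissue class such as "tumor". Three dialects are
supported:

* ``asap_xml`` — the format used by the CAMELYON challenges
  (``<Annotation>`` elements with ordered ``<Coordinate>`` children,
  grouped by ``PartOfGroup``),
* ``geojson`` — QuPath-style FeatureCollections of Polygon /
  MultiPolygon features, labelled via ``properties.classification.name``
  (falling back to ``properties.label``),
* ``plain_json`` — a minimal neutral interchange format
  (``{"slide_id": ..., "regions": [{"label", "exterior", "holes"}]}``).

All coordinates are interpreted as level-0 pixels, 0-based, x rightward
and y downward. Self-intersecting rings are repaired rather than
rejected, because hand-drawn clinical annotations commonly self-touch
and silent data loss is worse than repair.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import shapely
from lxml import etree
from shapely.geometry import MultiPolygon, Polygon
from shapely.validation import make_valid

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotatedRegion",
    "AnnotationSet",
    "AnnotationParseError",
    "DegenerateRegionError",
    "parse_annotations",
    "validate_region",
    "write_plain_json",
]


class AnnotationParseError(ValueError):
    """The file could not be parsed in the requested dialect."""


class DegenerateRegionError(ValueError):
    """A region collapsed to zero area after validation/repair."""

    def __init__(self, region_id: str, message: str):
        self.region_id = region_id
        super().__init__(f"region {region_id!r}: {message}")


Ring = list[tuple[float, float]]


@dataclass
class AnnotatedRegion:
    """One labelled polygon in level-0 pixel coordinates.

    ``exterior`` is an ordered vertex ring; closure is implicit (the
    last vertex need not repeat the first). ``holes`` are interior
    rings whose area is subtracted from the region.
    """

    label: str
    exterior: Ring
    holes: list[Ring] = field(default_factory=list)
    region_id: str = ""

    def __post_init__(self) -> None:
        self.exterior = [(float(x), float(y)) for x, y in self.exterior]
        self.holes = [[(float(x), float(y)) for x, y in h] for h in self.holes]
        if len({(x, y) for x, y in self.exterior}) < 3:
            raise ValueError(
                f"region {self.region_id!r}: exterior needs >= 3 distinct vertices"
            )

    def geometry(self) -> Polygon | MultiPolygon:
        """Validated shapely geometry (repaired if self-intersecting)."""
        return _repair(self.exterior, self.holes, self.region_id)

    @property
    def area(self) -> float:
        return self.geometry().area


def _polygonal(geom) -> list[Polygon]:
    parts: list[Polygon] = []
    for g in getattr(geom, "geoms", [geom]):
        if isinstance(g, Polygon) and g.area > 0:
            parts.append(g)
        elif isinstance(g, MultiPolygon):
            parts.extend(p for p in g.geoms if p.area > 0)
    return parts


def _repair(exterior: Ring, holes: list[Ring], region_id: str) -> Polygon | MultiPolygon:
    poly = Polygon(exterior, holes)
    if poly.is_valid:
        geom = poly
    else:
        # Repair rings separately, then subtract: make_valid decomposes
        # a self-crossing ring (e.g. a bowtie) into its covered parts,
        # preserving covered area, and hole area is always removed even
        # when the hole itself needed repair.
        ext_parts = _polygonal(make_valid(Polygon(exterior)))
        if not ext_parts:
            raise DegenerateRegionError(region_id, "repair yielded empty geometry")
        geom = shapely.union_all(ext_parts)
        for hole in holes:
            hole_parts = _polygonal(make_valid(Polygon(hole)))
            if hole_parts:
                geom = geom.difference(shapely.union_all(hole_parts))
        parts = _polygonal(geom)
        if not parts:
            raise DegenerateRegionError(region_id, "repair yielded empty geometry")
        geom = parts[0] if len(parts) == 1 else MultiPolygon(parts)
    if geom.is_empty or geom.area <= 0:
        raise DegenerateRegionError(region_id, "zero area after validation")
    return geom


def validate_region(region: AnnotatedRegion) -> AnnotatedRegion:
    """Check a region repairs to a valid positive-area (multi)polygon.

    Returns the region unchanged on success so calls can be chained;
    raises :class:`DegenerateRegionError` if repair yields nothing.
    """
    region.geometry()
    return region


@dataclass
class AnnotationSet:
    """All annotated regions of one slide, in one coordinate space."""

    slide_id: str
    regions: list[AnnotatedRegion]
    space: str = "level0_pixels"

    def __post_init__(self) -> None:
        if self.space != "level0_pixels":
            raise ValueError(f"unsupported coordinate space {self.space!r}")

    @property
    def labels(self) -> set[str]:
        return {r.label for r in self.regions}

    def filter(self, labels: str | set[str] | None) -> list[AnnotatedRegion]:
        """Regions whose label is in ``labels`` (None selects all)."""
        if labels is None:
            return list(self.regions)
        if isinstance(labels, str):
            labels = {labels}
        return [r for r in self.regions if r.label in labels]


# ---------------------------------------------------------------------------
# parsing

def parse_annotations(path: str, dialect: str = "auto") -> AnnotationSet:
    """Parse an annotation file into level-0 pixel polygons.

    ``dialect`` is one of ``asap_xml``, ``geojson``, ``plain_json`` or
    ``auto`` (sniffs by extension, then content). Regions with fewer
    than 3 distinct vertices are dropped with a warning rather than
    aborting the run.
    """
    if dialect == "auto":
        dialect = _sniff_dialect(path)
    parsers = {
        "asap_xml": _parse_asap_xml,
        "geojson": _parse_geojson,
        "plain_json": _parse_plain_json,
    }
    if dialect not in parsers:
        raise ValueError(f"unknown dialect {dialect!r}")
    try:
        return parsers[dialect](path)
    except (OSError, etree.XMLSyntaxError, json.JSONDecodeError, KeyError, TypeError) as exc:
        raise AnnotationParseError(f"cannot parse {path} as {dialect}: {exc}") from exc


def _sniff_dialect(path: str) -> str:
    p = str(path).lower()
    if p.endswith(".xml"):
        return "asap_xml"
    if p.endswith(".geojson"):
        return "geojson"
    with open(path, "rb") as fh:
        head = fh.read(4096).lstrip()
    if head.startswith(b"<"):
        return "asap_xml"
    if b'"FeatureCollection"' in head or b'"features"' in head:
        return "geojson"
    return "plain_json"


def _make_region(label, exterior, holes, region_id, dropped) -> AnnotatedRegion | None:
    try:
        return AnnotatedRegion(label=label, exterior=exterior, holes=holes,
                               region_id=region_id)
    except ValueError as exc:
        logger.warning("dropping region: %s", exc)
        warnings.warn(str(exc), stacklevel=3)
        dropped.append(region_id)
        return None


def _parse_asap_xml(path: str) -> AnnotationSet:
    tree = etree.parse(str(path))
    regions: list[AnnotatedRegion] = []
    dropped: list[str] = []
    for i, ann in enumerate(tree.iter("Annotation")):
        coords = []
        for c in ann.iter("Coordinate"):
            coords.append((int(c.get("Order", len(coords))),
                           float(c.get("X")), float(c.get("Y"))))
        coords.sort(key=lambda t: t[0])
        rid = ann.get("Name") or f"annotation_{i}"
        label = ann.get("PartOfGroup") or "unlabeled"
        region = _make_region(label, [(x, y) for _, x, y in coords], [], rid, dropped)
        if region is not None:
            regions.append(region)
    slide_id = tree.getroot().get("Name") or _stem(path)
    return AnnotationSet(slide_id=slide_id, regions=regions)


def _geojson_label(props: dict) -> str:
    cls = props.get("classification")
    if isinstance(cls, dict) and cls.get("name"):
        return str(cls["name"])
    return str(props.get("label", "unlabeled"))


def _parse_geojson(path: str) -> AnnotationSet:
    with open(path) as fh:
        doc = json.load(fh)
    features = doc["features"] if doc.get("type") == "FeatureCollection" else [doc]
    regions: list[AnnotatedRegion] = []
    dropped: list[str] = []
    for i, feat in enumerate(features):
        geom = feat.get("geometry", feat)
        label = _geojson_label(feat.get("properties") or {})
        rid = str(feat.get("id", f"feature_{i}"))
        if geom["type"] == "Polygon":
            polys = [geom["coordinates"]]
        elif geom["type"] == "MultiPolygon":
            polys = geom["coordinates"]
        else:
            logger.warning("skipping non-polygon geometry %s", geom["type"])
            continue
        for j, rings in enumerate(polys):
            sub = rid if len(polys) == 1 else f"{rid}_{j}"
            region = _make_region(label, [tuple(pt) for pt in rings[0]],
                                  [[tuple(pt) for pt in h] for h in rings[1:]],
                                  sub, dropped)
            if region is not None:
                regions.append(region)
    return AnnotationSet(slide_id=str(doc.get("slide_id", _stem(path))), regions=regions)


def _parse_plain_json(path: str) -> AnnotationSet:
    with open(path) as fh:
        doc = json.load(fh)
    regions: list[AnnotatedRegion] = []
    dropped: list[str] = []
    for i, r in enumerate(doc["regions"]):
        region = _make_region(str(r["label"]), [tuple(pt) for pt in r["exterior"]],
                              [[tuple(pt) for pt in h] for h in r.get("holes", [])],
                              str(r.get("region_id", f"region_{i}")), dropped)
        if region is not None:
            regions.append(region)
    return AnnotationSet(slide_id=str(doc.get("slide_id", _stem(path))), regions=regions)


def _stem(path: str) -> str:
    import os
    return os.path.splitext(os.path.basename(str(path)))[0]


def write_plain_json(annots: AnnotationSet, path: str) -> None:
    """Write an AnnotationSet in the plain_json interchange dialect."""
    doc = {
        "slide_id": annots.slide_id,
        "regions": [
            {
                "label": r.label,
                "region_id": r.region_id,
                "exterior": [[x, y] for x, y in r.exterior],
                "holes": [[[x, y] for x, y in h] for h in r.holes],
            }
            for r in annots.regions
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")
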