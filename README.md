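# tileforge

Threshold-gated tile extraction from pyramidal whole-slide images
(WSIs), for building histopathology deep-learning datasets.

A gigapixel H&E slide is trained on as a grid of small tiles
(here 512×512 px). Around the boundary of a hand-annotated region the
usual corner/midpoint containment heuristics fail — a concave region
can contain all eight probe points of a tile that is not actually
inside it — and tiles inside an annotation can still be mostly blank
glass. tileforge scores every grid tile with two metrics and extracts
the tiles passing both inclusive gates:

* **IoT (intersection over tile)** — `IoT = area(A ∩ T) / area(T)`,
  where `A` is the polygonal union of the selected annotated regions
  and `T` the tile footprint. Computed exactly by polygon clipping;
  1 iff the tile lies inside the region (including touching its
  boundary from inside), 0 iff they are disjoint or touch only from
  outside, strictly between otherwise. Invariant to joint scaling and
  translation of the coordinates.
* **BoT (background over tile)** — the fraction of the tile raster
  classified as blank background by a fixed pipeline: 5×5 Gaussian
  blur → RGB→HSV → background predicate (saturation ≤ 20 **and**
  value ≥ 235, 8-bit scales) → 3×3 dilation → area fraction. The gate
  thresholds the tissue fraction **ToT = 1 − BoT**.

A tile at grid location `loc` is extracted iff

```
IoT(A, loc) ≥ iot_thresh   and   1 − BoT(T) ≥ tot_thresh
```

with the BoT stage short-circuited (the tile is never read) when the
IoT gate fails. Holistic mode tiles a whole slide with the tissue gate
only — no annotations needed — and an optional uniform random sample
(e.g. 10% of a negative slide's tiles) can be applied after the gate.
The named preset ladder A–H sweeps `iot_thresh` over
{0.1, 0.2, 0.5, 1.0} and `tot_thresh` over {0.0, 0.2, 0.5}, plus a
(0.3, 0.3) hold-out testing preset.

Annotations are read from ASAP XML (CAMELYON-style), QuPath-flavoured
GeoJSON, or a plain JSON interchange format; slides are pyramidal
TIFFs (a flat PNG/JPEG is accepted as a one-level pyramid). Every run
produces an auditable per-tile manifest (CSV + JSON config sidecar),
and a synthetic-fixture module generates pyramidal slides with known
geometry and analytic per-tile ground truth, so the whole pipeline is
testable without any slide archive.

## Worked example

```python
from tileforge import extract_annotated, open_slide, parse_annotations, threshold_presets
from tileforge.synthetic import generate_fixture, make_offset_grid_case

fx = generate_fixture(make_offset_grid_case(), "demo")
handle = open_slide(fx.slide_path)
annots = parse_annotations(fx.annotation_path)
for name, cfg in threshold_presets("cam").items():
    m = extract_annotated(handle, annots, cfg)
    print(name, cfg.iot_thresh, cfg.tot_thresh, m.counts["extracted"])
```

This fixture is a 2048² slide with a 1024² tissue square whose
annotation is offset by half a tile, so per-tile IoT takes the values
{0.25, 0.5, 1.0}. Running `examples/extract_with_presets.py` prints:

```
preset  iot_thresh  tot_thresh  extracted  rejected_iot  rejected_bot
     A         0.1         0.0          9             7             0
     B         0.2         0.0          9             7             0
     C         0.2         0.2          4             7             5
     D         0.2         0.5          4             7             5
     E         0.5         0.2          3            11             2
     F         0.5         0.5          3            11             2
     G         1.0         0.2          1            15             0
     H         1.0         0.5          1            15             0
  test         0.3         0.3          3            11             2
```

Of 16 grid tiles, 9 overlap the annotation by ≥ 10% (preset A); only
1 lies fully inside it (presets G/H). Where `tot_thresh` rises to 0.2,
the IoT-passing tiles that sit on blank glass (the annotation is
deliberately offset from the painted tissue) are rejected by the
background gate — the mechanism that keeps blank tiles out of a
training set. Stricter presets always extract a subset of looser ones.

The other scripts in `examples/` show single-tile scoring, holistic
extraction with seeded 50% sampling, and the decision-coded extraction
map + per-slide timing summary.

## Command line

```
tileforge extract --wsi slide.tiff --annotation regions.xml \
    --labels tumor --preset C --out run/
tileforge extract --wsi slide.tiff --holistic --tot 0.3 \
    --sample-fraction 0.1 --seed 17 --out run/
tileforge stats run/manifest.csv --timing run/timing.json
tileforge synth --case concave --out fixtures/
tileforge preview --wsi slide.tiff --manifest run/manifest.csv \
    --annotation regions.xml --out overlay.png
```

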