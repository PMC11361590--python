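# Methods

## The extraction model

A whole-slide image `W` is partitioned into non-overlapping `ts × ts`
tiles from the top-left corner; partial edge tiles are dropped (floor
division) because downstream consumers need fixed tile dimensions.
Footprints are half-open boxes `[x, x+w) × [y, y+h)` in level-0 pixel
coordinates, so grid tiles partition the plane without double
counting; tile size is specified at the extraction pyramid level and
the level-0 footprint extent is `ts · downsample(level)`.

Each grid location passes through two inclusive gates:

1. **IoT gate** (annotation-guided mode). `IoT = area(A ∩ T)/area(T)`
   is computed by exact polygon clipping (shapely) between the tile
   box and the union of all validated regions matching the requested
   labels. The union — not per-region sums or maxima — guarantees
   `IoT ≤ 1` even for overlapping hand annotations. A tile failing
   `IoT ≥ iot_thresh` is recorded as `rejected_iot` and its raster is
   never read (the background stage is short-circuited).
2. **Tissue gate.** The tile raster is read and its background
   fraction BoT computed; the tile is `extracted` iff
   `1 − BoT ≥ tot_thresh`, else `rejected_bot`.

Both gates are inclusive (≥): a tile exactly at threshold is kept.
`iot_thresh = 0` admits every tile to the tissue stage; holistic mode
skips the IoT gate entirely and scores the whole grid with BoT only.

IoT properties relied on throughout: range [0, 1]; value 1 exactly
when the tile is contained in the region (touching the boundary from
inside included); value 0 exactly when the tile interior and region
are disjoint (touching from outside included); invariance under joint
scaling and translation. These make IoT robust on concave regions
where the older eight-point heuristic (test four corners and four edge
midpoints for containment) reports full containment for tiles that a
notch intrudes into — the regression case `make_concave_case`
constructs explicitly.

## BoT pipeline and parameters

Order is fixed: Gaussian blur → HSV conversion → predicate → dilation
→ area. Defaults (all config-exposed via `BackgroundParams`):

| parameter | default | meaning |
|---|---|---|
| `blur_kernel` | 5 px | separable Gaussian tap count; σ = 0.3·((k−1)/2 − 1) + 0.8, mirror borders |
| `sat_max` | 20 (8-bit) | background candidates have HSV saturation ≤ this |
| `val_min` | 235 (8-bit) | … and HSV value ≥ this (white glass is bright and unsaturated) |
| `combine` | `and` | predicate conjunction; `or` available |
| `dilate_kernel`, `dilate_iters` | 3 px, 1 | minimal morphology to close pinholes in the mask |
| `area_mode` | `contour_fill` | mask area = filled external contours (enclosed tissue specks count as background); `pixel_count` is the literal alternative |

The HSV cutoffs are a design choice targeting white slide background
under standard H&E staining; they are not derived from data, and both
are deliberately far from the colors the synthetic fixtures paint
(≥ 30 units margin on the governing channel) so tests do not hinge on
the default values. The blur σ convention is fixed so results
reproduce across backends. The "and" predicate with these defaults
makes a uniform white tile score exactly BoT = 1 and a uniform
stain-colored tile exactly 0 — blur and dilation are no-ops on
uniform rasters — which is what makes the limit-value checks exact
rather than approximate.

The two area modes agree exactly on masks without interior holes;
`contour_fill` reads "area of the mask's contours" as filled external
contours, the interpretation that treats a tissue speck enclosed by
glass as background. Tests use `pixel_count` where literal counting is
the point.

## Numerical choices

* Float polygon geometry with an absolute/relative clamp of 1e-9:
  computed IoT within 1e-9 of 0 or 1 snaps to the exact limit value.
  Exact rational arithmetic was rejected as unnecessary at pixel
  scale.
* Edge contact from outside yields exactly 0 because a shared edge has
  zero area; the intersects-then-clip order mirrors the two-step
  "test, then measure" structure of the gate.
* Self-intersecting annotation rings are repaired, not rejected:
  exterior and hole rings are made valid separately (decomposing a
  bowtie into its covered triangles) and holes are subtracted
  afterwards, so hole area is always removed even when the hole ring
  itself needed repair and a hole swallowing the exterior is reported
  as a degenerate region rather than silently ignored.
* The rasterization oracle (`rasterized_iot_oracle`) computes the
  fraction of a g×g pixel-center grid inside the union by a scanline
  even–odd crossing count — the same quantity as brute-force
  point-in-polygon over the grid, evaluated row-wise in closed form.
  It shares no code with the clipping path; agreement within
  `2/g + 1e-6` is asserted on 200 randomized polygon/tile pairs
  including concave crescents and self-intersecting stars.
* Random subsampling keeps `round(n·fraction)` tiles (at least 1 when
  any pass) without replacement, via a generator seeded from the
  config, so manifests are bit-reproducible. The sampling stage
  defaults to after the tissue gate — sampled tiles are then
  guaranteed non-blank — with `before_bot` available since the
  alternative order (sample first, then filter) is also defensible for
  negative slides.
* Timing summaries report sample (ddof = 1) std/variance and
  linearly-interpolated quartiles.

## Synthetic fixtures: what they emulate and what they do not

`tileforge.synthetic` paints small pyramidal TIFFs (2× mean-pooled
levels, tiled, uncompressed, byte-deterministic) emulating the
geometry of an H&E scan: saturated tissue blobs on near-white glass,
annotation polygons that may be offset from the stained area, concave
regions with notches. Ground truth per grid tile — exact IoT
(closed-form for axis-aligned annotations, g = 4096 scanline oracle
for curved ones), ideal tissue fraction, and the expected decision
under every preset — is written alongside.

Two constructions make end-to-end comparisons exact. Painted colors in
the preset-fidelity cases are aligned to the tile grid, so every tile
raster is uniform and BoT is exactly 0 or 1; annotations are decoupled
from the paint so IoT still sweeps fractional values. For curved
annotations the generator asserts every non-exact ground-truth IoT
keeps a ≥ 0.01 margin from each preset threshold, so oracle round-off
cannot flip a decision.

What the fixtures do **not** emulate: stain texture and nuclei,
gradual tissue/glass transitions, fat and pen-marker artifacts,
scanner compression, or microns-per-pixel metadata differences.
Passing the fixture suite therefore demonstrates the gating logic,
geometry and bookkeeping are correct under clean conditions, not that
the default HSV thresholds are optimal on real stains — on real slides
those thresholds are the knob a user should expect to tune.
Boundary-band behaviour (blur + dilation on tiles containing a color
edge) is tested separately with explicit tolerances (±0.03 on a
half/half tile; ±0.02 under 2× upscaling).

Problem sizes were chosen to exercise every code path at desk scale:
2048² canvases (4×4 grids of 512 px tiles), 3-level pyramids, 200
random pairs for oracle agreement. Nothing in the method depends on
canvas size; the engine streams tiles one at a time.

## Known limitations

* Slide reading loads one pyramid level lazily into memory per level
  rather than windowed reads; adequate for fixture-scale and
  moderate slides, not for 100k² level-0 reads on small-memory
  machines. The reading contract (`open_slide` / `read_region`) is
  deliberately thin so an OpenSlide-backed handle can be swapped in.
* Background segmentation is a fixed HSV rule, not learned; no Otsu
  auto-thresholding.
* No overlapping/strided tiling, no magnification resampling, no
  stain normalization; annotation coordinates must already be level-0
  pixels.
* A tile overlapping regions of two different labels is scored per
  label-filter; class assignment across labels is left to the caller.
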