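"""Score individual tiles with the two gate metrics.

IoT (intersection over tile) measures how much of a tile's footprint
lies inside an annotated region; BoT (background over tile) measures
how much of a tile's pixels are blank glass. Extraction keeps a tile
when IoT >= iot_thresh and 1 - BoT >= tot_thresh.
"""

import numpy as np

from tileforge import (
    AnnotatedRegion,
    AnnotationSet,
    TileFootprint,
    compute_bot,
    compute_iot,
    region_union,
    tot,
)

# a 1024 px square tumor annotation, and three 512 px tiles
annots = AnnotationSet("demo", [AnnotatedRegion(
    "tumor", [(0, 0), (1024, 0), (1024, 1024), (0, 1024)])])
union = region_union(annots, "tumor")

for name, tile in [
    ("inside", TileFootprint(256, 256, 512, 512)),
    ("straddling", TileFootprint(768, 0, 512, 512)),
    ("outside, edge contact", TileFootprint(1024, 0, 512, 512)),
]:
    print(f"IoT {name:>22}: {compute_iot(union, tile):.3f}")

# BoT on a synthetic tile: left half blank glass, right half stain
tile_img = np.full((512, 512, 3), 245, np.uint8)
tile_img[:, 256:] = (200, 100, 150)
bot = compute_bot(tile_img)
print(f"BoT half glass/half tissue: {bot:.3f}  (tissue fraction 1-BoT = {tot(bot):.3f})")

# IoT = 1 means fully inside; 0.5 means half the tile overlaps the
# region; 0 means no interior overlap at all. The half-blank tile
# passes a tot_thresh gate up to 0.5.
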