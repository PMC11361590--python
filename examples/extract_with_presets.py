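"""Annotation-guided extraction across the named threshold ladder.

Generates a synthetic pyramidal slide whose annotation is offset half a
tile from the painted tissue, then runs the eight training presets A-H
plus the hold-out "test" preset and prints the extracted-tile counts.
Counts shrink as the thresholds rise - the stricter preset always
extracts a subset of the looser one.
"""

import tempfile

from tileforge import extract_annotated, open_slide, parse_annotations, threshold_presets
from tileforge.synthetic import generate_fixture, make_offset_grid_case

workdir = tempfile.mkdtemp(prefix="tileforge_demo_")
fx = generate_fixture(make_offset_grid_case(), workdir)
handle = open_slide(fx.slide_path)
annots = parse_annotations(fx.annotation_path)

print("preset  iot_thresh  tot_thresh  extracted  rejected_iot  rejected_bot")
for name, cfg in threshold_presets("cam").items():
    m = extract_annotated(handle, annots, cfg)
    c = m.counts
    print(f"{name:>6}  {cfg.iot_thresh:>10.1f}  {cfg.tot_thresh:>10.1f}"
          f"  {c['extracted']:>9}  {c['rejected_iot']:>12}  {c['rejected_bot']:>12}")

# 16 grid tiles in total. Tiles fail the IoT gate when their overlap
# with the annotation is below iot_thresh, and fail the tissue gate
# when they sit on blank glass (the annotation is deliberately offset
# from the painted tissue, so some IoT-passing tiles are blank).
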