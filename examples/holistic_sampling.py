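"""Holistic extraction (no annotations) with random subsampling.

Negative slides carry no region annotations; the whole grid is scored
with the tissue gate only, and a random fraction of the passing tiles
(here 50%, reproducible by seed) is kept - the way a training set's
negative tiles are drawn without extracting every blank-free tile.
"""

import tempfile

from tileforge import ExtractionConfig, extract_holistic, open_slide
from tileforge.synthetic import generate_fixture, make_checkerboard_case

workdir = tempfile.mkdtemp(prefix="tileforge_demo_")
fx = generate_fixture(make_checkerboard_case(), workdir)
handle = open_slide(fx.slide_path)

cfg = ExtractionConfig(tot_thresh=0.5, sample_fraction=0.5, seed=17)
m = extract_holistic(handle, cfg)
c = m.counts
print(f"grid tiles: {len(m.records)}")
print(f"passed tissue gate and sampled: {c['extracted']}")
print(f"dropped by sampling: {c['rejected_sampling']}")
print(f"rejected as background: {c['rejected_bot']}")

# The checkerboard has 8 tissue and 8 blank tiles: the tissue gate
# keeps 8, and 50% sampling then keeps 4 of them, chosen uniformly
# without replacement - identical for a fixed seed.
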