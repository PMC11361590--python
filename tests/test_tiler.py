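"""Grid partition, the threshold-gated extraction loop, sampling,
presets and manifest I/O."""

import numpy as np
import pytest
from PIL import Image

from tileforge.annotation_io import parse_annotations
from tileforge.geometry import TileFootprint
from tileforge.tiler import (
    TRAINING_PRESET_NAMES,
    ExtractionConfig,
    TileRecord,
    extract_annotated,
    extract_holistic,
    partition,
    read_manifest,
    sample_records,
    threshold_presets,
    tile_filename,
    write_manifest,
    write_tile,
)
from tileforge.wsi_access import open_slide


class TestPartition:
    def test_grid_counts(self):
        fps = partition(2048, 1536, 512)
        assert len(fps) == 12  # 4 × 3
        assert fps[0] == TileFootprint(0, 0, 512, 512)
        assert fps[4] == TileFootprint(0, 512, 512, 512)  # row-major, y outer

    def test_partial_edge_tiles_dropped(self):
        assert len(partition(700, 700, 512)) == 1
        assert partition(511, 511, 512) == []

    def test_completeness_and_disjointness(self):
        fps = partition(1700, 1200, 512)
        assert sum(f.area for f in fps) == (1700 // 512) * (1200 // 512) * 512 ** 2
        boxes = {(f.x, f.y) for f in fps}
        assert len(boxes) == len(fps)


class TestExtractAnnotated:
    def test_aligned_square_full_iot_only(self, basic_fixture):
        handle = open_slide(basic_fixture.slide_path)
        annots = parse_annotations(basic_fixture.annotation_path)
        m = extract_annotated(handle, annots,
                              ExtractionConfig(iot_thresh=1.0, tot_thresh=0.0))
        assert m.counts["extracted"] == 4
        assert len(m.records) == 16

    @pytest.mark.parametrize("iot_thresh,expected", [(0.1, 9), (0.5, 5), (1.0, 1)])
    def test_offset_square_threshold_ladder(self, offset_fixture, iot_thresh, expected):
        handle = open_slide(offset_fixture.slide_path)
        annots = parse_annotations(offset_fixture.annotation_path)
        m = extract_annotated(handle, annots,
                              ExtractionConfig(iot_thresh=iot_thresh, tot_thresh=0.0))
        assert m.counts["extracted"] == expected

    def test_annotation_over_blank_glass_rejected_by_bot(self, basic_fixture, tmp_path):
        """A region drawn on pure background passes IoT but fails the
        tissue gate."""
        import json
        doc = {"slide_id": "basic", "regions": [{
            "label": "tumor",
            "exterior": [[0, 0], [512, 0], [512, 512], [0, 512]],
        }]}
        p = tmp_path / "blank.json"
        p.write_text(json.dumps(doc))
        handle = open_slide(basic_fixture.slide_path)
        annots = parse_annotations(str(p))
        m = extract_annotated(handle, annots,
                              ExtractionConfig(iot_thresh=0.1, tot_thresh=0.2))
        assert m.counts["extracted"] == 0
        assert m.counts["rejected_bot"] == 1

    def test_iot_gate_short_circuits_reads(self, offset_fixture):
        """Tiles failing the IoT gate are never read from the slide."""
        handle = open_slide(offset_fixture.slide_path)
        annots = parse_annotations(offset_fixture.annotation_path)
        m = extract_annotated(handle, annots,
                              ExtractionConfig(iot_thresh=0.5, tot_thresh=0.0))
        passing = sum(1 for r in m.records if r.iot >= 0.5)
        assert handle.read_count == passing == 5
        for r in m.records:
            if r.decision == "rejected_iot":
                assert r.bot is None

    def test_iot_zero_admits_all_tiles(self, basic_fixture):
        handle = open_slide(basic_fixture.slide_path)
        annots = parse_annotations(basic_fixture.annotation_path)
        m = extract_annotated(handle, annots,
                              ExtractionConfig(iot_thresh=0.0, tot_thresh=0.0))
        assert all(r.bot is not None for r in m.records)
        assert m.counts["extracted"] == 16

    def test_determinism_identical_manifests(self, offset_fixture):
        handle = open_slide(offset_fixture.slide_path)
        annots = parse_annotations(offset_fixture.annotation_path)
        cfg = ExtractionConfig(iot_thresh=0.2, tot_thresh=0.2,
                               sample_fraction=0.5, seed=9)
        f1 = extract_annotated(handle, annots, cfg).to_frame()
        f2 = extract_annotated(handle, annots, cfg).to_frame()
        assert f1.equals(f2)


class TestExtractHolistic:
    def test_all_tissue_and_half_grid(self, checkerboard_fixture):
        handle = open_slide(checkerboard_fixture.slide_path)
        m = extract_holistic(handle, ExtractionConfig(tot_thresh=0.5))
        assert m.counts["extracted"] == 8  # exactly the tissue squares
        extracted = {(r.footprint.x // 512, r.footprint.y // 512)
                     for r in m.extracted}
        assert all((i + j) % 2 == 0 for i, j in extracted)
        assert all(r.iot is None for r in m.records)

    def test_all_background_slide_yields_nothing(self, tmp_path):
        from tileforge.synthetic import FixtureSpec, generate_fixture
        res = generate_fixture(
            FixtureSpec(name="blank", canvas=(1024, 1024), blobs=[],
                        annotations=[]),
            str(tmp_path))
        handle = open_slide(res.slide_path)
        m = extract_holistic(handle, ExtractionConfig(tot_thresh=0.2))
        assert m.counts["extracted"] == 0
        assert m.counts["rejected_bot"] == len(m.records) == 4


class TestThresholdMonotonicity:
    def test_stricter_config_extracts_subset(self, offset_fixture):
        handle = open_slide(offset_fixture.slide_path)
        annots = parse_annotations(offset_fixture.annotation_path)
        prev = None
        for iot_t, tot_t in [(0.1, 0.0), (0.2, 0.2), (0.5, 0.2), (1.0, 0.5)]:
            m = extract_annotated(handle, annots,
                                  ExtractionConfig(iot_thresh=iot_t, tot_thresh=tot_t))
            cur = {(r.footprint.x, r.footprint.y) for r in m.extracted}
            if prev is not None:
                assert cur <= prev
            prev = cur


class TestSampling:
    def make_records(self, n):
        return [TileRecord("s", TileFootprint(i * 512, 0, 512, 512), 1.0, 0.0,
                           "extracted") for i in range(n)]

    def test_fraction_and_reproducibility(self):
        a = sample_records(self.make_records(100), 0.1, seed=17)
        b = sample_records(self.make_records(100), 0.1, seed=17)
        assert len(a) == 10
        assert [r.footprint.x for r in a] == [r.footprint.x for r in b]

    def test_identity_at_full_fraction(self):
        records = self.make_records(7)
        assert sample_records(records, 1.0, seed=0) == records

    def test_at_least_one_kept(self):
        records = self.make_records(5)
        kept = sample_records(records, 0.1, seed=0)
        assert len(kept) == 1
        assert sum(r.decision == "rejected_sampling" for r in records) == 4

    @pytest.mark.parametrize("fraction", [0.0, 1.5, -0.1])
    def test_invalid_fraction_rejected(self, fraction):
        with pytest.raises(ValueError):
            sample_records(self.make_records(3), fraction, seed=0)

    def test_sampling_inside_extraction_marks_records(self, checkerboard_fixture):
        handle = open_slide(checkerboard_fixture.slide_path)
        m = extract_holistic(handle, ExtractionConfig(
            tot_thresh=0.5, sample_fraction=0.5, seed=3))
        assert m.counts["extracted"] == 4
        assert m.counts["rejected_sampling"] == 4

    def test_sampling_before_bot_skips_reads(self, checkerboard_fixture):
        handle = open_slide(checkerboard_fixture.slide_path)
        m = extract_holistic(handle, ExtractionConfig(
            tot_thresh=0.0, sample_fraction=0.25, seed=3,
            sample_stage="before_bot"))
        assert handle.read_count == 4
        assert sum(r.bot is None for r in m.records) == 12


class TestPresets:
    def test_training_ladder_pairs(self):
        presets = threshold_presets("cam")
        expected = {"A": (0.1, 0.0), "B": (0.2, 0.0), "C": (0.2, 0.2),
                    "D": (0.2, 0.5), "E": (0.5, 0.2), "F": (0.5, 0.5),
                    "G": (1.0, 0.2), "H": (1.0, 0.5)}
        assert TRAINING_PRESET_NAMES == tuple("ABCDEFGH")
        for name, (iot_t, tot_t) in expected.items():
            assert presets[name].iot_thresh == iot_t
            assert presets[name].tot_thresh == tot_t

    def test_testing_preset(self):
        cfg = threshold_presets("paip")["test"]
        assert (cfg.iot_thresh, cfg.tot_thresh) == (0.3, 0.3)

    def test_unknown_tag_rejected(self):
        with pytest.raises(ValueError):
            threshold_presets("tcga")


class TestManifestIO:
    def test_csv_round_trip_preserves_counts(self, offset_fixture, tmp_path):
        handle = open_slide(offset_fixture.slide_path)
        annots = parse_annotations(offset_fixture.annotation_path)
        m = extract_annotated(handle, annots,
                              ExtractionConfig(iot_thresh=0.5, tot_thresh=0.2))
        path = tmp_path / "manifest.csv"
        write_manifest(m, str(path))
        df = read_manifest(str(path))
        assert len(df) == len(m.records)
        assert df["decision"].value_counts().to_dict() == {
            k: v for k, v in m.counts.items() if v}
        assert (path.parent / "manifest.csv.config.json").exists()

    def test_written_tiles_and_filenames(self, checkerboard_fixture, tmp_path):
        handle = open_slide(checkerboard_fixture.slide_path)
        out = tmp_path / "tiles"
        m = extract_holistic(handle, ExtractionConfig(
            tot_thresh=0.5, out_dir=str(out)))
        assert len(list(out.glob("*.png"))) == 8
        rec = m.extracted[0]
        assert rec.out_path == tile_filename(rec.slide_id, rec.footprint, 512, "png")

    def test_png_tile_round_trip_lossless(self, tmp_path):
        rng = np.random.default_rng(0)
        raster = rng.integers(0, 256, (64, 64, 3), dtype=np.uint8)
        p = tmp_path / "t.png"
        write_tile(raster, str(p), "png")
        back = np.asarray(Image.open(p))
        assert (back == raster).all()


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        dict(iot_thresh=1.2), dict(tot_thresh=-0.1), dict(tile_size=0),
        dict(sample_fraction=0.0), dict(out_format="bmp"),
        dict(sample_stage="midway"),
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ExtractionConfig(**kwargs)
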