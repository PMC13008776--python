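"""Slide/annotation/table I/O, coordinate conventions and stitching."""

import numpy as np
import pandas as pd
import pytest

from msq.coords import Bounds
from msq.core_io import (AnnotationSet, RunConfig, SlideImage,
                         read_annotations, read_config, read_region,
                         stitch_tiles, write_annotations, write_config,
                         write_features_table, read_features_table)
from msq.tiling import TileSpec


class TestSlideImage:
    def test_tiff_round_trip(self, tmp_path, rng):
        arr = rng.integers(0, 255, (64, 80, 3), dtype=np.uint8)
        slide = SlideImage.from_array(arr, mpp=0.5)
        slide.write_tiff(tmp_path / "s.tif")
        back = SlideImage.from_tiff(tmp_path / "s.tif")
        np.testing.assert_array_equal(back.levels[0], arr)
        assert back.mpp == pytest.approx(0.5)

    def test_pyramid_level_halves_dimensions(self, rng):
        arr = rng.integers(0, 255, (128, 96, 3), dtype=np.uint8)
        slide = SlideImage.from_array(arr, n_levels=2)
        assert slide.levels[1].shape[:2] == (64, 48)
        assert slide.downsamples == [1.0, 2.0]

    def test_read_region_origin_and_contents(self, rng):
        arr = rng.integers(0, 255, (50, 60, 3), dtype=np.uint8)
        slide = SlideImage.from_array(arr)
        full = read_region(slide, 0, Bounds(0, 0, 60, 50))
        np.testing.assert_array_equal(full, arr)
        sub = read_region(slide, 0, Bounds(10, 5, 20, 15))
        np.testing.assert_array_equal(sub, arr[5:15, 10:20])

    def test_read_region_errors(self):
        slide = SlideImage.from_array(np.zeros((20, 20, 3), dtype=np.uint8))
        with pytest.raises(ValueError):
            read_region(slide, 0, Bounds(0, 0, 0, 10))  # zero area
        with pytest.raises(ValueError):
            read_region(slide, 0, Bounds(10, 10, 30, 15))  # out of extent

    def test_invalid_mpp_rejected(self):
        with pytest.raises(ValueError):
            SlideImage(levels=[np.zeros((4, 4, 3), dtype=np.uint8)], mpp=0.0)


class TestAnnotations:
    def test_polygon_name_captured(self, tmp_path):
        ann = AnnotationSet(polygons=[
            ("tumour", np.array([[0, 0], [10, 0], [10, 10], [0, 10]],
                                dtype=float))])
        write_annotations(ann, tmp_path / "a.geojson")
        back = read_annotations(tmp_path / "a.geojson")
        assert back.names == ["tumour"]

    def test_round_trip_preserves_vertices_exactly(self, tmp_path, rng):
        ring = np.cumsum(rng.uniform(-5, 5, (7, 2)), axis=0)
        ring = np.vstack([ring, ring[:1]])
        pts = [("Cell", 1.25, 7.5), ("Cell", 3.0, 4.0), ("Cell", 9.125, 0.5)]
        ann = AnnotationSet(polygons=[("roi", ring)], points=pts)
        write_annotations(ann, tmp_path / "a.geojson")
        back = read_annotations(tmp_path / "a.geojson")
        np.testing.assert_array_equal(back.polygons[0][1], ring)
        assert back.points == pts

    def test_unsupported_geometry_warns_and_skips(self, tmp_path):
        doc = ('{"type":"FeatureCollection","features":['
               '{"type":"Feature","geometry":{"type":"LineString",'
               '"coordinates":[[0,0],[1,1]]},"properties":{}},'
               '{"type":"Feature","geometry":{"type":"Point",'
               '"coordinates":[2,3]},"properties":{}}]}')
        (tmp_path / "x.geojson").write_text(doc)
        with pytest.warns(UserWarning, match="LineString"):
            back = read_annotations(tmp_path / "x.geojson")
        assert back.polygons == []
        assert back.points == [("unlabelled", 2.0, 3.0)]


def _tile(row, col, x0, y0, size, margin, extent):
    core = Bounds(x0, y0, x0 + size, y0 + size)
    padded = core.expand(margin).clip(*extent)
    return TileSpec(row=row, col=col, core=core, padded=padded)


class TestStitch:
    def test_single_tile_equals_core(self, rng):
        raster = rng.integers(0, 255, (60, 60, 3), dtype=np.uint8)
        spec = _tile(0, 0, 0, 0, 50, 5, (50, 50))
        out = stitch_tiles([(spec, raster[:55, :55])])
        np.testing.assert_array_equal(out, raster[:50, :50])

    def test_2x2_mosaic_from_distinct_constant_tiles(self):
        tiles = []
        for r in range(2):
            for c in range(2):
                spec = _tile(r, c, c * 10, r * 10, 10, 2, (20, 20))
                val = 40 * (2 * r + c) + 10
                raster = np.full((spec.padded.height, spec.padded.width, 3),
                                 val, dtype=np.uint8)
                tiles.append((spec, raster))
        out = stitch_tiles(tiles)
        assert out.shape == (20, 20, 3)
        assert (out[:10, :10] == 10).all() and (out[:10, 10:] == 50).all()
        assert (out[10:, :10] == 90).all() and (out[10:, 10:] == 130).all()

    def test_stitch_reconstructs_tiled_raster_exactly(self, rng):
        """Padded overlaps never appear twice: cores partition the image."""
        base = rng.integers(0, 255, (30, 40, 3), dtype=np.uint8)
        tiles = []
        for r in range(3):
            for c in range(4):
                spec = _tile(r, c, c * 10, r * 10, 10, 3, (40, 30))
                p = spec.padded
                tiles.append((spec, base[p.y0:p.y1, p.x0:p.x1]))
        out = stitch_tiles(tiles)
        np.testing.assert_array_equal(out, base)

    def test_missing_tile_filled_white_with_warning(self, rng):
        spec = _tile(0, 0, 0, 0, 10, 0, (20, 10))
        raster = rng.integers(0, 200, (10, 10, 3), dtype=np.uint8)
        spec2 = _tile(0, 1, 10, 0, 10, 0, (20, 10))
        with pytest.warns(UserWarning, match="not fully covered"):
            out = stitch_tiles([(spec, raster)],
                               extent=Bounds(0, 0, 20, 10))
        assert (out[:, 10:] == 255).all()


class TestFeaturesTable:
    def test_empty_records_header_only(self, tmp_path):
        df = write_features_table(pd.DataFrame(columns=["cell_id", "x"]),
                                  tmp_path / "f.csv")
        back = read_features_table(tmp_path / "f.csv")
        assert list(back.columns) == ["cell_id", "x"]
        assert len(back) == 0

    def test_round_trip_full_precision(self, tmp_path, rng):
        df = pd.DataFrame({
            "cell_id": ["a", "b", "c"],
            "v": rng.standard_normal(3),
            "w": rng.standard_normal(3) * 1e-7})
        write_features_table(df, tmp_path / "f.csv")
        back = read_features_table(tmp_path / "f.csv")
        np.testing.assert_array_equal(back["v"].to_numpy(),
                                      df["v"].to_numpy())
        np.testing.assert_array_equal(back["w"].to_numpy(),
                                      df["w"].to_numpy())

    def test_duplicate_cell_ids_rejected(self, tmp_path):
        df = pd.DataFrame({"cell_id": ["a", "a"], "v": [1, 2]})
        with pytest.raises(ValueError, match="duplicate"):
            write_features_table(df, tmp_path / "f.csv")

    def test_per_stain_columns_schema(self, tmp_path):
        rows = [{"cell_id": f"c{i}",
                 "cd3_nucleus_chrom_mean": 0.1 * i,
                 "foxp3_nucleus_chrom_mean": 0.2 * i} for i in range(3)]
        df = write_features_table(pd.DataFrame(rows), tmp_path / "f.csv")
        assert len(df) == 3
        assert {"cd3_nucleus_chrom_mean",
                "foxp3_nucleus_chrom_mean"} <= set(df.columns)


class TestRunConfig:
    def test_defaults_match_protocol(self):
        cfg = RunConfig()
        assert cfg.tile_size == 1000
        assert cfg.overlap_frac == 0.10
        assert cfg.consensus_frac == 0.60
        assert cfg.match_radius_um == 3.0
        assert cfg.cytoplasm_px == 3
        assert cfg.pca_var == 0.90
        assert cfg.mpp == 0.5
        assert cfg.margin_px == 50
        assert cfg.match_radius_px == pytest.approx(6.0)

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            RunConfig(overlap_frac=0.5)
        with pytest.raises(ValueError):
            RunConfig(consensus_frac=0.0)

    def test_config_round_trip(self, tmp_path):
        cfg = RunConfig(stains=("cd3", "foxp3"), tile_size=512,
                        overlap_frac=0.2, seed=42, mpp=0.25)
        cfg.stain_matrices = {"cd3": np.eye(3)}
        write_config(cfg, tmp_path / "cfg.txt")
        back = read_config(tmp_path / "cfg.txt")
        assert back.stains == ("cd3", "foxp3")
        assert back.tile_size == 512
        assert back.seed == 42
        assert back.mpp == 0.25
        np.testing.assert_array_equal(back.stain_matrices["cd3"], np.eye(3))

    def test_unknown_config_key_warns_not_fails(self, tmp_path):
        (tmp_path / "cfg.txt").write_text("tile_size = 100\nbogus_key = 3\n")
        with pytest.warns(UserWarning, match="bogus_key"):
            cfg = read_config(tmp_path / "cfg.txt")
        assert cfg.tile_size == 100
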