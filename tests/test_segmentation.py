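import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from grasspix.features import build_feature_stack
from grasspix.geotiff import GeoReference, read_raster, write_kml_footprint, write_raster
from grasspix.labelling import DEFAULT_PALETTE, PixelDataset
from grasspix.model import BoostedPixelClassifier, train_classifier
from grasspix.segmentation import (
    SegmentationRaster,
    export_raster,
    extract_tile,
    predict_tile,
    render_segmentation,
    stitch_tiles,
    tile_orthomosaic,
)


class TestTiling:
    def test_survey_orthomosaic_tile_count(self):
        grid = tile_orthomosaic((44_800, 17_200), tile_size=400)
        assert grid.n_tiles == 4_816
        assert grid.shape == (112, 43)
        assert all(t.height == 400 and t.width == 400 for t in grid.tiles)

    def test_smaller_than_tile_input_is_one_tile(self):
        grid = tile_orthomosaic((100, 100), tile_size=400)
        assert grid.n_tiles == 1
        assert (grid.tiles[0].height, grid.tiles[0].width) == (100, 100)

    def test_stitch_round_trip_is_bit_exact(self, rng):
        raster = rng.integers(0, 256, (130, 215, 3), dtype=np.uint8)
        grid = tile_orthomosaic(raster, tile_size=64)
        tiles = [extract_tile(raster, t) for t in grid.tiles]
        assert np.array_equal(stitch_tiles(grid, tiles), raster)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(h=st.integers(1, 900), w=st.integers(1, 900),
           tile_size=st.integers(1, 400))
    def test_partition_property(self, h, w, tile_size):
        grid = tile_orthomosaic((h, w), tile_size=tile_size)
        assert grid.n_tiles == int(np.ceil(h / tile_size)) * int(
            np.ceil(w / tile_size)
        )
        covered = np.zeros((h, w), dtype=int)
        for t in grid.tiles:
            covered[t.window] += 1
        assert np.all(covered == 1)  # no gaps, no overlap

    def test_georeference_propagates_to_tile_windows(self):
        geo = GeoReference(500_000.0, 7_545_000.0, 0.01, 0.01, epsg=32_749)
        grid = tile_orthomosaic((800, 800), tile_size=400, geo=geo)
        last = grid.tiles[-1]
        assert last.geo.origin_x == pytest.approx(500_000.0 + 400 * 0.01)
        assert last.geo.origin_y == pytest.approx(7_545_000.0 - 400 * 0.01)

    def test_nonpositive_tile_size_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            tile_orthomosaic((10, 10), tile_size=0)


class TestPredictTile:
    def test_degenerate_model_paints_everything_its_class(self, rng):
        data = PixelDataset(rng.random((20, 10)), np.full(20, 2))
        model = train_classifier(data, seed=0)
        tile = rng.integers(0, 256, (9, 9, 3), dtype=np.uint8)
        seg = predict_tile(model, tile)
        assert np.all(seg.labels == 2)
        assert np.all(seg.render == DEFAULT_PALETTE.color(2))

    def test_matches_row_wise_prediction(self, rng, separable_data):
        model = train_classifier(separable_data, seed=0)
        tile = rng.integers(0, 256, (12, 12, 3), dtype=np.uint8)
        seg = predict_tile(model, tile)
        rows = build_feature_stack(tile).as_rows()
        one_at_a_time = np.array(
            [model.predict(rows[i: i + 1])[0] for i in range(rows.shape[0])]
        )
        assert np.array_equal(seg.labels.reshape(-1), one_at_a_time)

    def test_deterministic(self, rng, separable_data):
        model = train_classifier(separable_data, seed=0)
        tile = rng.integers(0, 256, (16, 16, 3), dtype=np.uint8)
        assert np.array_equal(
            predict_tile(model, tile).labels, predict_tile(model, tile).labels
        )

    def test_feature_layout_mismatch_refused(self, rng, separable_data):
        hsv_only = BoostedPixelClassifier(random_state=0)
        hsv_only.fit(separable_data.features[:, :3], separable_data.labels)
        tile = rng.integers(0, 256, (8, 8, 3), dtype=np.uint8)
        with pytest.raises(ValueError, match="feature"):
            predict_tile(hsv_only, tile)


class TestRender:
    def test_uniform_labels_give_uniform_colour(self):
        labels = np.full((6, 6), 4)
        rendered = render_segmentation(labels)
        assert np.all(rendered == DEFAULT_PALETTE.color(4))  # shadow colour

    def test_checkerboard_colour_counts_equal_label_counts(self):
        labels = np.indices((8, 8)).sum(axis=0) % 2 + 5  # codes 5 and 6
        rendered = render_segmentation(labels)
        for code in (5, 6):
            colour = np.array(DEFAULT_PALETTE.color(code))
            assert (rendered == colour).all(axis=-1).sum() == (labels == code).sum()


class TestExport:
    def test_plain_tif_round_trip(self, tmp_path, rng):
        labels = rng.integers(1, 7, (20, 20)).astype(np.uint8)
        seg = SegmentationRaster(labels, render_segmentation(labels))
        export_raster(seg, tmp_path / "labels.tif", tmp_path / "render.tif")
        back, geo = read_raster(tmp_path / "labels.tif")
        assert np.array_equal(back, labels)
        assert geo is None  # no geo tags invented for plain tiles
        render_back, _ = read_raster(tmp_path / "render.tif")
        assert np.array_equal(render_back, seg.render)

    def test_geotiff_transform_survives_round_trip(self, tmp_path, rng):
        labels = rng.integers(1, 7, (10, 10)).astype(np.uint8)
        geo = GeoReference(113.86, -22.19, 1e-4, 1e-4, epsg=4326,
                           geographic=True)
        seg = SegmentationRaster(labels, render_segmentation(labels), geo=geo)
        export_raster(seg, tmp_path / "tile.tif")
        back, geo_back = read_raster(tmp_path / "tile.tif")
        assert np.array_equal(back, labels)
        assert geo_back == geo

    def test_kml_footprint_contains_bounds(self, tmp_path):
        geo = GeoReference(113.86, -22.19, 1e-4, 1e-4, epsg=4326,
                           geographic=True)
        write_kml_footprint(tmp_path / "tile.kml", geo, 100, 100)
        text = (tmp_path / "tile.kml").read_text()
        assert "113.86" in text and "<coordinates>" in text

    def test_write_raster_rejects_nothing_but_reads_back_dtype(self, tmp_path):
        arr = np.arange(12, dtype=np.uint8).reshape(3, 4)
        write_raster(tmp_path / "a.tif", arr)
        back, _ = read_raster(tmp_path / "a.tif")
        assert back.dtype == np.uint8
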