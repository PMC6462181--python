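"""I/O, unit-conversion and tiling contracts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ihcdetect.imaging_io import (
    AnnotationFormatError,
    CountTableFormatError,
    Detection,
    ImageMetadata,
    InvalidMetadataError,
    PointAnnotation,
    RGBImage,
    image_area_mm2,
    px_to_um,
    read_annotations,
    read_detections,
    read_image,
    read_observer_counts,
    stitch_tiles,
    tile_image,
    um_to_px,
    write_annotations,
    write_detections,
    write_image,
)

META = ImageMetadata()  # 0.228 µm/px


class TestUnitConversion:
    @pytest.mark.parametrize(
        "um, expected_px",
        [(4.0, 4.0 / 0.228), (0.0, 0.0), (0.228, 1.0)],
    )
    def test_um_to_px(self, um, expected_px):
        assert um_to_px(um, META) == pytest.approx(expected_px, abs=1e-12)

    def test_four_micron_radius_is_about_17_5_px(self):
        # the nucleus radius bound used by the detector
        assert um_to_px(4.0, META) == pytest.approx(17.544, abs=1e-3)

    def test_invalid_pixel_size_rejected(self):
        with pytest.raises(InvalidMetadataError):
            ImageMetadata(pixel_size_um=0.0)
        with pytest.raises(InvalidMetadataError):
            ImageMetadata(pixel_size_um=-1.0)

    @given(st.floats(min_value=0, max_value=1e6, allow_nan=False))
    @settings(max_examples=50, deadline=None)
    def test_px_um_inverse_pair(self, v):
        assert px_to_um(um_to_px(v, META), META) == pytest.approx(v, rel=1e-12)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            um_to_px(-1.0, META)


class TestArea:
    def test_standard_validation_tile_is_0_2_mm2(self):
        # 2000×2000 px at 0.228 µm/px
        area = image_area_mm2(2000, 2000, META)
        assert area == pytest.approx(0.207936, abs=1e-9)
        assert round(area, 1) == 0.2

    def test_unit_square(self):
        assert image_area_mm2(1, 1, ImageMetadata(pixel_size_um=1000.0)) == 1.0

    def test_linear_in_pixel_count(self):
        full = image_area_mm2(2000, 2000, META)
        half = image_area_mm2(1000, 2000, META)
        assert half == pytest.approx(full / 2)
        assert half == pytest.approx(0.103968, abs=1e-9)


class TestAnnotationsCSV:
    def test_round_trip(self, tmp_path):
        anns = [
            PointAnnotation(10, 20, "positive", "img-a"),
            PointAnnotation(30.5, 40.5, "negative_region_sample", "img-a"),
            PointAnnotation(1, 2, "positive", "img-b"),
        ]
        p = tmp_path / "ann.csv"
        write_annotations(anns, p)
        back = read_annotations(p)
        assert back == anns

    def test_empty_file_with_header(self, tmp_path):
        p = tmp_path / "ann.csv"
        p.write_text("image_id,x,y,label\n")
        assert read_annotations(p) == []

    def test_missing_column_is_format_error(self, tmp_path):
        p = tmp_path / "ann.csv"
        p.write_text("image_id,x,y\nimg,1,2\n")
        with pytest.raises(AnnotationFormatError, match="label"):
            read_annotations(p)

    def test_non_numeric_coordinate_names_row(self, tmp_path):
        p = tmp_path / "ann.csv"
        p.write_text("image_id,x,y,label\nimg,abc,2,positive\n")
        with pytest.raises(AnnotationFormatError, match="row 2"):
            read_annotations(p)


class TestDetectionsCSV:
    def test_round_trip(self, tmp_path):
        dets = [
            Detection(x=10.5, y=20.25, score=0.125, component_size=12,
                      image_id="im0"),
            Detection(x=1, y=2, score=3.0, component_size=1, image_id="im1"),
        ]
        p = tmp_path / "det.csv"
        write_detections(dets, p)
        back = read_detections(p)
        assert len(back) == len(dets)
        for a, b in zip(back, dets):
            assert (a.x, a.y, a.score, a.component_size, a.image_id) == (
                b.x, b.y, b.score, b.component_size, b.image_id,
            )

    def test_invalid_detection_rejected(self):
        with pytest.raises(ValueError):
            Detection(x=0, y=0, score=0.0, component_size=1)
        with pytest.raises(ValueError):
            Detection(x=0, y=0, score=1.0, component_size=0)


class TestObserverCounts:
    def test_64_images_4_observers(self, tmp_path):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            rng.integers(0, 200, size=(64, 4)),
            columns=["A", "B", "C", "D"],
            index=[f"img-{i:03d}" for i in range(64)],
        )
        p = tmp_path / "counts.csv"
        df.to_csv(p, index_label="image_id")
        table = read_observer_counts(p)
        assert table.shape == (64, 4)
        pd.testing.assert_frame_equal(table, df, check_names=False)

    def test_duplicate_image_id_rejected(self, tmp_path):
        p = tmp_path / "counts.csv"
        p.write_text("image_id,A,B\nim0,1,2\nim0,3,4\n")
        with pytest.raises(CountTableFormatError, match="duplicate"):
            read_observer_counts(p)

    def test_missing_cell_rejected(self, tmp_path):
        p = tmp_path / "counts.csv"
        p.write_text("image_id,A,B\nim0,1,\nim1,3,4\n")
        with pytest.raises(CountTableFormatError, match="missing"):
            read_observer_counts(p)


class TestImageFiles:
    @pytest.mark.parametrize("name", ["img.png", "img.tif"])
    def test_round_trip_with_sidecar(self, tmp_path, name):
        px = np.random.default_rng(0).integers(0, 256, (32, 40, 3), np.uint8)
        img = RGBImage(px, ImageMetadata(marker="CD8", image_id="t1"))
        p = tmp_path / name
        write_image(img, p)
        back = read_image(p)
        np.testing.assert_array_equal(back.pixels, px)
        assert back.metadata.pixel_size_um == pytest.approx(0.228)
        assert back.metadata.marker == "CD8"
        assert back.metadata.image_id == "t1"


class TestTiling:
    def test_trimmed_cores_partition_the_grid(self):
        arr = np.arange(100 * 100).reshape(100, 100)
        tiles = tile_image(arr, tile=60, halo=10)
        covered = np.zeros_like(arr, dtype=int)
        for t in tiles:
            covered[t.core] += 1
        assert (covered == 1).all()

    def test_overlap_is_exactly_twice_halo(self):
        arr = np.zeros((100, 100))
        tiles = tile_image(arr, tile=60, halo=10)
        # interior neighbours in x: first core [0,40), second [40,80)
        row0 = [t for t in tiles if t.core[0].start == 0]
        a, b = row0[0], row0[1]
        overlap = (a.offset[1] + a.pixels.shape[1]) - b.offset[1]
        assert overlap == 20

    def test_tile_larger_than_image_gives_single_tile(self):
        arr = np.ones((46, 46, 3), np.uint8)
        tiles = tile_image(arr, tile=128, halo=23)
        assert len(tiles) == 1
        np.testing.assert_array_equal(tiles[0].pixels, arr)

    def test_tile_must_exceed_twice_halo(self):
        with pytest.raises(ValueError):
            tile_image(np.zeros((50, 50)), tile=20, halo=10)

    @given(
        h=st.integers(1, 80),
        w=st.integers(1, 80),
        halo=st.integers(0, 12),
        extra=st.integers(1, 40),
    )
    @settings(max_examples=60, deadline=None)
    def test_stitch_is_exact_identity(self, h, w, halo, extra):
        tile = 2 * halo + extra
        arr = np.random.default_rng(h * 81 + w).integers(
            0, 256, (h, w, 3), np.uint8
        )
        out = stitch_tiles(tile_image(arr, tile, halo), shape=arr.shape)
        np.testing.assert_array_equal(out, arr)
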