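"""Raster loading, circular-ROI extraction, grid detection, table parsing."""

import numpy as np
import pytest
from PIL import Image

from padquant import (
    ImageRaster,
    ZoneSpec,
    detect_zone_grid,
    extract_zone_mean,
    load_image,
    read_rgb_table,
    read_zone_layout,
    save_image,
)
from padquant.exceptions import (
    DetectionError,
    ImageFormatError,
    ImageReadError,
    ParseError,
    SchemaError,
    ZoneError,
)
from padquant.ingest import write_zone_layout
from padquant.synthetic import ResponseModel, ScanLayout, render_scan

from conftest import brute_force_zone_mean


def _uniform_raster(rgb, shape=(10, 10)):
    pixels = np.empty(shape + (3,), dtype=float)
    pixels[:, :] = rgb
    return ImageRaster(pixels)


class TestLoadImage:
    @pytest.mark.parametrize("ext", ["tiff", "png"])
    def test_lossless_roundtrip(self, tmp_path, ext):
        rng = np.random.default_rng(7)
        pixels = rng.integers(0, 256, size=(10, 12, 3)).astype(float)
        path = tmp_path / f"img.{ext}"
        save_image(ImageRaster(pixels), path)
        back = load_image(path)
        np.testing.assert_array_equal(back.pixels, pixels)
        assert back.height == 10 and back.width == 12

    def test_constant_pixel_roundtrip(self, tmp_path):
        path = tmp_path / "c.png"
        save_image(_uniform_raster((12, 34, 56)), path)
        back = load_image(path)
        assert np.all(back.pixels == np.array([12, 34, 56]))

    def test_16bit_rescaled_to_255(self, tmp_path):
        arr = np.full((6, 6), 65535, dtype=np.uint16)
        path = tmp_path / "deep.tiff"
        Image.fromarray(arr).save(path)
        back = load_image(path)
        assert back.bit_depth_original == 16
        np.testing.assert_allclose(back.pixels, 255.0)

    def test_greyscale_replicated(self, tmp_path):
        path = tmp_path / "grey.png"
        Image.fromarray(np.full((5, 5), 100, dtype=np.uint8), mode="L").save(path)
        back = load_image(path)
        assert np.all(back.pixels == 100.0)
        assert back.pixels.shape == (5, 5, 3)

    def test_alpha_discarded(self, tmp_path):
        rgba = np.zeros((4, 4, 4), dtype=np.uint8)
        rgba[..., :3] = (10, 20, 30)
        rgba[..., 3] = 128
        path = tmp_path / "a.png"
        Image.fromarray(rgba, mode="RGBA").save(path)
        back = load_image(path)
        assert back.pixels.shape == (4, 4, 3)
        assert np.all(back.pixels == np.array([10, 20, 30]))

    def test_missing_file_names_path(self, tmp_path):
        with pytest.raises(ImageReadError, match="nope.tiff"):
            load_image(tmp_path / "nope.tiff")

    def test_cmyk_rejected(self, tmp_path):
        path = tmp_path / "cmyk.jpg"
        Image.new("CMYK", (4, 4), (0, 0, 0, 0)).save(path)
        with pytest.raises(ImageFormatError, match="CMYK"):
            load_image(path)


class TestExtractZoneMean:
    def test_uniform_field(self):
        raster = _uniform_raster((100, 150, 200), shape=(40, 40))
        m = extract_zone_mean(raster, ZoneSpec("z1", 20, 20, 8))
        assert m.rgb == (100.0, 150.0, 200.0)
        assert m.n_pixels > 0

    def test_half_split_symmetry(self):
        # black/white halves split by the vertical line through a
        # non-integer centre: equal pixel counts on both sides
        pixels = np.zeros((64, 64, 3))
        pixels[:, 32:, :] = 255.0
        raster = ImageRaster(pixels)
        m = extract_zone_mean(raster, ZoneSpec("z1", 31.5, 31.5, 10))
        assert m.rgb == (127.5, 127.5, 127.5)

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(11)
        pixels = rng.uniform(0, 255, size=(64, 64, 3))
        raster = ImageRaster(pixels)
        zone = ZoneSpec("z1", 30.2, 33.7, 10)
        m = extract_zone_mean(raster, zone)
        expected, n = brute_force_zone_mean(pixels, 30.2, 33.7, 10)
        assert m.n_pixels == n
        np.testing.assert_allclose(m.rgb, expected, atol=1e-9)

    def test_translation_invariance(self):
        rng = np.random.default_rng(5)
        tile = rng.uniform(0, 255, size=(40, 40, 3))
        big = np.zeros((60, 60, 3))
        big[0:40, 0:40] = tile
        shifted = np.zeros((60, 60, 3))
        shifted[13:53, 9:49] = tile
        m0 = extract_zone_mean(ImageRaster(big), ZoneSpec("z", 20, 20, 9))
        m1 = extract_zone_mean(ImageRaster(shifted), ZoneSpec("z", 29, 33, 9))
        assert m0.rgb == m1.rgb

    def test_degenerate_zone(self):
        raster = _uniform_raster((1, 2, 3), shape=(8, 8))
        with pytest.raises(ZoneError):
            extract_zone_mean(raster, ZoneSpec("z1", 3.5, 3.5, 0.3))


class TestDetectZoneGrid:
    def test_recovers_rendered_layout(self):
        raster, truth, _ = render_scan(
            ScanLayout(rows=2, cols=3), ResponseModel(),
            concentrations=(0, 50, 100), replicates=2, seed=3,
        )
        detected = detect_zone_grid(raster, 2, 3, margin_frac=0.0)
        assert len(detected) == 6
        for d, t in zip(detected, truth):
            assert abs(d.center_x - t.center_x) <= 2
            assert abs(d.center_y - t.center_y) <= 2
            assert abs(d.radius - t.radius) / t.radius <= 0.05

    def test_blank_raster_errors(self):
        raster = _uniform_raster((255, 255, 255), shape=(50, 50))
        with pytest.raises(DetectionError, match="0"):
            detect_zone_grid(raster, 1, 1)

    def test_margin_shrinks_radius(self):
        raster, _, _ = render_scan(
            ScanLayout(rows=1, cols=1), ResponseModel(),
            concentrations=(0.0,), replicates=1, seed=0,
        )
        z0 = detect_zone_grid(raster, 1, 1, margin_frac=0.0)[0]
        z2 = detect_zone_grid(raster, 1, 1, margin_frac=0.2)[0]
        assert z0.center_x == z2.center_x and z0.center_y == z2.center_y
        assert abs(z2.radius - 0.8 * z0.radius) <= 1.0


class TestReadRgbTable:
    def test_native_row(self, tmp_path):
        path = tmp_path / "rgb.csv"
        path.write_text(
            "zone_id,concentration,replicate,R,G,B\n"
            "z1,60,1,186.07,206.16,216.87\n"
        )
        (m,) = read_rgb_table(path)
        assert m.zone_id == "z1"
        assert m.concentration == 60.0
        assert m.rgb == (186.07, 206.16, 216.87)

    def test_empty_data_section(self, tmp_path):
        path = tmp_path / "rgb.csv"
        path.write_text("zone_id,concentration,replicate,R,G,B\n")
        assert read_rgb_table(path) == []

    def test_missing_column_named(self, tmp_path):
        path = tmp_path / "rgb.csv"
        path.write_text("zone_id,concentration,replicate,G,B\nz1,0,1,2,3\n")
        with pytest.raises(SchemaError, match="'R'"):
            read_rgb_table(path)

    def test_non_numeric_reports_row(self, tmp_path):
        path = tmp_path / "rgb.csv"
        path.write_text(
            "zone_id,concentration,replicate,R,G,B\n"
            "z1,0,1,10,20,30\nz2,5,1,oops,20,30\n"
        )
        with pytest.raises(ParseError, match="row 2"):
            read_rgb_table(path)

    def test_imagej_suffixed_labels(self, tmp_path):
        path = tmp_path / "ij.csv"
        path.write_text(
            " ,Label,Mean\n"
            "1,z1:60:1 (red),186.07\n"
            "2,z1:60:1 (green),206.16\n"
            "3,z1:60:1 (blue),216.87\n"
        )
        (m,) = read_rgb_table(path, dialect="imagej")
        assert m.zone_id == "z1" and m.concentration == 60.0 and m.replicate == 1
        assert m.rgb == (186.07, 206.16, 216.87)

    def test_imagej_split_stack_triples(self, tmp_path):
        path = tmp_path / "ij.csv"
        path.write_text(
            " ,Label,Mean\n"
            "1,z1:60,186.07\n2,z1:60,206.16\n3,z1:60,216.87\n"
            "4,z2:65,183.10\n5,z2:65,204.23\n6,z2:65,215.87\n"
        )
        ms = read_rgb_table(path, dialect="imagej")
        assert [m.zone_id for m in ms] == ["z1", "z2"]
        assert ms[1].rgb == (183.10, 204.23, 215.87)


def test_zone_layout_roundtrip(tmp_path):
    zones = [
        ZoneSpec("a", 10, 12, 5, concentration=0.0, unit="mg/L", replicate=1),
        ZoneSpec("b", 30, 12, 5, concentration=20.0, unit="mg/L", replicate=2),
    ]
    path = tmp_path / "layout.csv"
    write_zone_layout(zones, path)
    back = read_zone_layout(path)
    assert [(z.zone_id, z.center_x, z.concentration, z.replicate) for z in back] == [
        ("a", 10.0, 0.0, 1), ("b", 30.0, 20.0, 2)
    ]
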