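"""Pixel classification, time-series extraction and texture chips."""

import numpy as np
import pytest
from shapely.geometry import box

from pitt.features import (
    RasterStack,
    classify_pixels,
    extract_chip,
    extract_timeseries,
    mean_standardize,
    zscore,
)
from pitt.geometry import Parcel
from pitt.grids import GridSpec

GRID = GridSpec(0, 100, 10, 10, 10)


def make_stack(data):
    data = np.asarray(data, dtype=float)
    return RasterStack(dates=tuple(range(1, data.shape[0] + 1)), data=data, grid=GRID)


class TestClassifyPixels:
    def test_3x3_block_one_interior(self):
        interior, edge, empty = classify_pixels(Parcel("p", box(10, 40, 40, 70)), GRID)
        assert len(interior) == 1 and len(edge) == 8 and not empty

    def test_5x5_block(self):
        interior, edge, _ = classify_pixels(Parcel("p", box(10, 20, 60, 70)), GRID)
        assert len(interior) == 9 and len(edge) == 16

    def test_subpixel_polygon_empty_with_warning(self):
        # polygon inside one pixel but missing its center
        interior, edge, empty = classify_pixels(Parcel("p", box(11, 61, 14, 64)), GRID)
        assert interior == [] and edge == [] and empty


class TestExtractTimeseries:
    def test_constant_raster_any_method(self):
        stack = make_stack(np.full((4, 10, 10), 3.5))
        p = Parcel("p", box(10, 20, 60, 70))
        for method in ("full", "edge_excluded", "central_k"):
            rec = extract_timeseries(p, stack, method)
            assert np.allclose(rec.values, 3.5)

    def test_interior_vs_full_means(self):
        data = np.ones((2, 10, 10))
        p = Parcel("p", box(10, 40, 40, 70))
        interior, edge, _ = classify_pixels(p, GRID)
        for r, c in interior:
            data[:, r, c] = 5.0
        stack = make_stack(data)
        assert np.allclose(extract_timeseries(p, stack, "edge_excluded").values, 5.0)
        assert np.allclose(
            extract_timeseries(p, stack, "full").values, (5 + 8 * 1) / 9
        )

    def test_central_9_equals_inner_block_on_symmetric_parcel(self):
        data = np.zeros((1, 10, 10))
        data[0] = np.arange(100).reshape(10, 10)
        p = Parcel("p", box(10, 20, 60, 70))  # 5x5 block
        stack = make_stack(data)
        rec = extract_timeseries(p, stack, "central_k", central_k=9)
        interior, _, _ = classify_pixels(p, GRID)
        rows = [rc[0] for rc in interior]
        cols = [rc[1] for rc in interior]
        assert rec.values[0] == pytest.approx(data[0, rows, cols].mean())

    def test_full_is_count_weighted_combination(self, rng):
        data = rng.normal(size=(5, 10, 10))
        p = Parcel("p", box(10, 20, 60, 70))
        stack = make_stack(data)
        interior, edge, _ = classify_pixels(p, GRID)
        full = extract_timeseries(p, stack, "full").values
        inner = extract_timeseries(p, stack, "edge_excluded").values
        edge_mean = data[:, [rc[0] for rc in edge], [rc[1] for rc in edge]].mean(axis=1)
        ni, ne = len(interior), len(edge)
        assert np.allclose(full, (ni * inner + ne * edge_mean) / (ni + ne))

    def test_edge_noise_does_not_touch_interior_series(self, rng):
        data = np.ones((3, 10, 10))
        p = Parcel("p", box(10, 20, 60, 70))
        _, edge, _ = classify_pixels(p, GRID)
        before = extract_timeseries(p, make_stack(data), "edge_excluded").values
        noisy = data.copy()
        for r, c in edge:
            noisy[:, r, c] += rng.normal(size=3)
        after = extract_timeseries(p, make_stack(noisy), "edge_excluded").values
        assert np.array_equal(before, after)

    def test_fallback_to_full_when_no_interior(self):
        stack = make_stack(np.ones((2, 10, 10)))
        # covers 4 pixel centers but no full pixel footprint
        rec = extract_timeseries(Parcel("p", box(12, 42, 28, 58)), stack, "edge_excluded")
        assert rec.fallback

    def test_uncovered_parcel_error_names_parcel(self):
        stack = make_stack(np.ones((2, 10, 10)))
        with pytest.raises(ValueError, match="lost"):
            extract_timeseries(Parcel("lost", box(11, 61, 14, 64)), stack)


class TestMeanStandardize:
    def test_zscore_arithmetic(self):
        rec = extract_timeseries(
            Parcel("p", box(10, 40, 40, 70)),
            make_stack(np.array([np.full((10, 10), v) for v in (1.0, 2.0, 3.0)])),
        )
        z = mean_standardize(rec)
        assert z.values == pytest.approx([-1.2247, 0.0, 1.2247], abs=1e-4)
        assert z.raw_mean_level == pytest.approx(2.0)

    def test_constant_series_degenerate(self):
        rec = extract_timeseries(
            Parcel("p", box(10, 40, 40, 70)), make_stack(np.full((3, 10, 10), 4.0))
        )
        z = mean_standardize(rec)
        assert np.array_equal(z.values, np.zeros(3)) and z.degenerate

    def test_idempotent(self, rng):
        rec = extract_timeseries(
            Parcel("p", box(10, 40, 40, 70)), make_stack(rng.normal(size=(6, 10, 10)))
        )
        once = mean_standardize(rec)
        twice = mean_standardize(once)
        assert np.allclose(once.values, twice.values, atol=1e-9)

    def test_center_mode(self, rng):
        rec = extract_timeseries(
            Parcel("p", box(10, 40, 40, 70)), make_stack(rng.normal(size=(6, 10, 10)))
        )
        centered = mean_standardize(rec, mode="center")
        assert abs(centered.values.mean()) < 1e-9
        assert centered.values.std() != pytest.approx(1.0)


HIRES = GridSpec(0, 200, 2, 100, 100)


class TestExtractChip:
    def test_uniform_image_uniform_chip(self):
        img = np.full((100, 100, 3), 0.7)
        chip = extract_chip(Parcel("p", box(60, 60, 140, 140)), img, HIRES, side=32)
        assert np.allclose(chip.pixels, 0.7)

    def test_small_chip_resize_replicates_4x4(self, rng):
        img = rng.random((100, 100, 3))
        chip = extract_chip(Parcel("p", box(60, 60, 140, 140)), img, HIRES, side=8)
        assert chip.resized_to == 32
        up = chip.model_pixels
        assert up.shape == (32, 32, 3)
        assert np.array_equal(up, np.repeat(np.repeat(chip.pixels, 4, 0), 4, 1))

    def test_border_chip_zero_padded(self):
        img = np.ones((100, 100, 3))
        chip = extract_chip(Parcel("p", box(0, 90, 8, 110)), img, HIRES, side=96)
        assert chip.pixels.shape == (96, 96, 3)
        assert np.all(chip.pixels[:, 0] == 0)  # left margin outside image
        assert chip.pixels.sum() > 0

    def test_invalid_side_rejected(self):
        with pytest.raises(ValueError):
            extract_chip(Parcel("p", box(60, 60, 140, 140)), np.ones((100, 100, 3)), HIRES, side=20)

    def test_translation_equivariance(self, rng):
        img = rng.random((100, 100, 3))
        p1 = Parcel("a", box(40, 100, 80, 140))
        chip1 = extract_chip(p1, img, HIRES, side=16)
        # shift parcel by 10 hires pixels right/down and roll the image
        p2 = Parcel("b", box(60, 80, 100, 120))
        img2 = np.roll(np.roll(img, 10, axis=1), 10, axis=0)
        chip2 = extract_chip(p2, img2, HIRES, side=16)
        assert np.array_equal(chip1.pixels, chip2.pixels)

    def test_masked_chip_zeroes_outside_polygon(self):
        img = np.ones((100, 100, 3))
        chip = extract_chip(
            Parcel("p", box(80, 80, 120, 120)), img, HIRES, side=32, masked=True
        )
        assert chip.pixels[16, 16].sum() > 0  # centre inside
        assert chip.pixels[0, 0].sum() == 0   # corner outside parcel


def test_zscore_rows_zero_mean_unit_sd(rng):
    X = rng.normal(size=(8, 12)) * 5 + 3
    Z = zscore(X)
    assert np.allclose(Z.mean(axis=1), 0, atol=1e-12)
    assert np.allclose(Z.std(axis=1), 1, atol=1e-12)
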