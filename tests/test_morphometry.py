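"""Geometry core: boundary polygons, minFeret calipers vs sweep, filters."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from myosize.morphometry import (
    FilterSpec,
    apply_filters,
    measure_mask,
    min_feret,
    min_feret_sweep,
    object_polygon,
)
from myosize.segmentation import LabelMask

from conftest import random_convex_polygon


def shoelace(p):
    x, y = p[:, 0], p[:, 1]
    return 0.5 * (np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))


class TestObjectPolygon:
    def test_single_pixel_is_unit_square(self):
        mask = LabelMask(np.array([[1]]), pixel_size=1.0)
        poly = object_polygon(mask, 1)
        assert shoelace(poly) == pytest.approx(1.0)
        assert set(map(tuple, poly)) == {(0, 0), (1, 0), (1, 1), (0, 1)}

    def test_rectangle_scales_with_pixel_size(self):
        data = np.zeros((7, 9), dtype=int)
        data[2:5, 2:7] = 1  # 3 rows x 5 cols
        poly = object_polygon(LabelMask(data, pixel_size=2.0), 1)
        w = poly[:, 0].max() - poly[:, 0].min()
        h = poly[:, 1].max() - poly[:, 1].min()
        assert (w, h) == (10.0, 6.0)
        assert shoelace(poly) == pytest.approx(60.0)

    def test_polygon_area_at_least_pixel_area(self):
        rng = np.random.default_rng(2)
        data = (rng.random((30, 30)) < 0.6).astype(int)
        from scipy import ndimage as ndi

        lab, _ = ndi.label(data, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
        mask = LabelMask(lab, pixel_size=1.0)
        for lid in mask.labels[:10]:
            area = shoelace(object_polygon(mask, int(lid)))
            assert area >= np.sum(lab == lid) - 1e-9

    def test_missing_label_raises(self):
        with pytest.raises(KeyError):
            object_polygon(LabelMask(np.array([[1]])), 99)


class TestMinFeret:
    @pytest.mark.parametrize(
        "poly,expected",
        [
            (np.array([[0, 0], [10, 0], [10, 10], [0, 10]], float), 10.0),
            (np.array([[0, 0], [20, 0], [20, 5], [0, 5]], float), 5.0),
        ],
    )
    def test_rectangles(self, poly, expected):
        assert min_feret(poly) == pytest.approx(expected)

    def test_regular_hexagon_side_one(self):
        ang = np.linspace(0, 2 * np.pi, 7)[:-1]
        hexagon = np.column_stack([np.cos(ang), np.sin(ang)])  # side 1
        assert min_feret(hexagon) == pytest.approx(math.sqrt(3), rel=1e-12)

    def test_degenerate_collinear_warns_and_returns_zero(self):
        line = np.array([[0, 0], [1, 1], [2, 2]], float)
        with pytest.warns(UserWarning, match="degenerate"):
            assert min_feret(line) == 0.0

    def test_calipers_equals_fine_sweep_on_random_polygons(self):
        """Rotating calipers agrees with the brute-force angle sweep: a
        fine (0.02°) sweep to within 1e-3 relative on arbitrary random
        hulls, and a 0.1° sweep to within its geometric error bound
        (aspect ratio x tan of the half-step)."""
        rng = np.random.default_rng(314)
        half_step = math.tan(math.radians(0.05))
        for _ in range(200):
            poly = random_convex_polygon(rng, n=rng.integers(4, 30))
            exact = min_feret(poly)
            fine = min_feret_sweep(poly, 0.02)
            coarse = min_feret_sweep(poly, 0.1)
            assert fine >= exact - 1e-9  # sweep is an upper bound
            assert fine == pytest.approx(exact, rel=1e-3)
            diameter = max(
                float(np.hypot(*(p - q))) for p in poly for q in poly
            )
            assert coarse - exact <= diameter * half_step + 1e-9

    def test_sweep_on_near_circle(self):
        ang = np.linspace(0, 2 * np.pi, 361)[:-1]
        circle = 5.0 * np.column_stack([np.cos(ang), np.sin(ang)])
        assert min_feret_sweep(circle, 1.0) == pytest.approx(10.0, abs=1e-3)

    def test_sweep_square_attained_at_axis(self):
        sq = np.array([[0, 0], [10, 0], [10, 10], [0, 10]], float)
        assert min_feret_sweep(sq, 1.0) == pytest.approx(10.0)

    @given(scale=st.floats(0.01, 100), angle=st.floats(0, np.pi))
    def test_scale_equivariance_and_rotation_invariance(self, scale, angle):
        rng = np.random.default_rng(99)
        poly = random_convex_polygon(rng)
        base = min_feret(poly)
        rot = np.array([[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]])
        assert min_feret(poly * scale) == pytest.approx(base * scale, rel=1e-9)
        assert min_feret(poly @ rot.T) == pytest.approx(base, rel=1e-9)


class TestMaskMeasurementConsistency:
    def test_mask_minferet_tracks_true_polygon(self, section, measured_truth):
        """Measured minFeret on the rasterized mask tracks the true
        polygon's within pixel-quantization limits."""
        truth = section["truth"].records
        gt = truth[truth["is_fiber"]].set_index("label_id")["minferet_um"]
        got = measured_truth.set_index("label_id")["minferet_um"]
        err = (got - gt).dropna()
        ps = section["mask"].pixel_size
        assert abs(err.mean()) < 0.5 * ps
        assert (err.abs() <= ps).mean() >= 0.97
        assert err.abs().max() <= 1.5 * ps

    def test_minferet_below_maxferet(self, measured_truth, section):
        from skimage.measure import regionprops

        props = {p.label: p.feret_diameter_max for p in regionprops(section["mask"].data)}
        ps = section["mask"].pixel_size
        for row in measured_truth.itertuples():
            assert row.minferet_um <= props[row.label_id] * ps + ps


class TestFilters:
    def test_area_bounds_inclusive(self):
        df = pd.DataFrame(
            {"label_id": range(5), "area_um2": [49, 50, 25_000, 50_000, 50_001],
             "minferet_um": [10.0] * 5}
        )
        out = apply_filters(df, FilterSpec())
        assert sorted(out["area_um2"]) == [50, 25_000, 50_000]
        assert out["passed_area_filter"].all()

    def test_cohort_minferet_bounds(self):
        df = pd.DataFrame(
            {"label_id": range(4), "area_um2": [100.0] * 4,
             "minferet_um": [1.0, 2.0, 120.0, 121.0]}
        )
        out = apply_filters(df, FilterSpec(), "2 years")
        assert sorted(out["minferet_um"]) == [2.0, 120.0]

    def test_empty_input_gives_empty_output(self):
        df = pd.DataFrame(columns=["label_id", "area_um2", "minferet_um"])
        out = apply_filters(df, FilterSpec())
        assert out.empty

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {"label_id": range(100), "area_um2": rng.uniform(10, 60_000, 100),
             "minferet_um": rng.uniform(0.5, 150, 100)}
        )
        once = apply_filters(df, FilterSpec(), "5 years")
        twice = apply_filters(once, FilterSpec(), "5 years")
        pd.testing.assert_frame_equal(once, twice)

    def test_unknown_cohort_rejected(self):
        df = pd.DataFrame({"label_id": [1], "area_um2": [100.0], "minferet_um": [10.0]})
        with pytest.raises(KeyError):
            apply_filters(df, FilterSpec(), "30 years")

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            FilterSpec(area_min=100, area_max=50)


class TestMeasureMask:
    def test_empty_mask(self):
        out = measure_mask(LabelMask(np.zeros((5, 5), dtype=int)))
        assert out.empty

    def test_square_object(self):
        data = np.zeros((20, 20), dtype=int)
        data[5:15, 5:15] = 3
        out = measure_mask(LabelMask(data, pixel_size=0.5))
        row = out.iloc[0]
        assert row["label_id"] == 3
        assert row["area_um2"] == pytest.approx(100 * 0.25)
        assert row["minferet_um"] == pytest.approx(10 * 0.5)
        assert row["x_um"] == pytest.approx(10 * 0.5)
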