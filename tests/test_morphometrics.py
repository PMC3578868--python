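"""The nine shape descriptors against analytic geometry and brute-force
raster oracles."""

import math

import numpy as np
import pandas as pd
import pytest
import shapely

from conftest import (oracle_calipers, oracle_inner_radius, polygon_calipers,
                      rasterize_polygon, superellipse_polygon)
from osteomorph.morphometrics import (FEATURE_NAMES, cleanse_noise,
                                      fiber_dimensions, measure_object,
                                      measure_objects, standardize_objects)
from scipy import ndimage as ndi


def disk_mask(r, pad=4):
    size = 2 * r + 2 * pad
    yy, xx = np.mgrid[0:size, 0:size]
    y, x = yy - size / 2 + 0.5, xx - size / 2 + 0.5
    return x ** 2 + y ** 2 <= r ** 2


class TestAnalyticCases:
    def test_fiber_model_exact_for_continuous_rectangle(self):
        # 10 x 2 rectangle: A = 20, P = 24
        L, B, clamped = fiber_dimensions(24.0, 20.0)
        assert (L, B, clamped) == (10.0, 2.0, False)

    def test_fiber_discriminant_clamps_for_disk(self):
        # continuous disk: P^2 = 4*pi*A < 16*A
        L, B, clamped = fiber_dimensions(2 * math.pi * 10, math.pi * 100)
        assert clamped and L == B == pytest.approx(math.pi * 5)

    def test_digital_disk(self):
        r = 20
        f = measure_object(disk_mask(r))
        assert f.shape_factor == pytest.approx(1.0, abs=0.05)
        assert f.elliptical_form_factor == pytest.approx(1.0, abs=0.03)
        assert f.inner_radius == pytest.approx(r, abs=0.8)
        assert f.breadth == pytest.approx(2 * r, rel=0.03)
        assert f.hole_area == 0.0

    def test_annulus_relative_hole_area(self):
        size = 52
        yy, xx = np.mgrid[0:size, 0:size]
        y, x = yy - size / 2 + 0.5, xx - size / 2 + 0.5
        r2 = x ** 2 + y ** 2
        ring = (r2 <= 20 ** 2) & (r2 > 10 ** 2)
        f = measure_object(ring)
        assert f.relative_hole_area == pytest.approx(0.25, abs=0.01)
        assert f.total_area == pytest.approx(math.pi * 400, rel=0.01)
        assert f.hole_area == pytest.approx(math.pi * 100, rel=0.03)

    def test_axis_aligned_rectangle_calipers(self):
        rect = np.zeros((40, 60), bool)
        rect[10:20, 5:45] = True  # 10 x 40 pixel block
        f = measure_object(rect)
        assert f.breadth == pytest.approx(10.0, abs=0.1)
        assert f.elliptical_form_factor == pytest.approx(10 / 40, rel=0.04)
        assert f.inner_radius == pytest.approx(5.0, abs=0.6)

    def test_empty_and_single_pixel(self):
        with pytest.raises(ValueError):
            measure_object(np.zeros((4, 4), bool))
        one = np.zeros((3, 3), bool)
        one[1, 1] = True
        f = measure_object(one)
        assert "single_pixel" in f.flags
        assert f.total_area == 1.0

    def test_total_area_convention_switch(self):
        ring = disk_mask(10) & ~disk_mask(4, pad=10)
        filled = measure_object(ring, total_area_filled=True)
        fg_only = measure_object(ring, total_area_filled=False)
        assert filled.total_area > fg_only.total_area
        assert filled.total_area == pytest.approx(fg_only.total_area
                                                  + filled.hole_area)


class TestRasterOracles:
    def test_areas_match_exhaustive_pixel_count(self, random_fixture_shapes):
        for mask, _poly in random_fixture_shapes[:30]:
            f = measure_object(mask)
            filled = ndi.binary_fill_holes(mask)
            assert f.total_area == filled.sum()
            assert f.hole_area == filled.sum() - mask.sum()

    def test_calipers_match_bruteforce_rotation(self, random_fixture_shapes):
        for mask, _poly in random_fixture_shapes[:30]:
            f = measure_object(mask)
            o_max, o_min = oracle_calipers(mask)
            assert f.breadth == pytest.approx(o_min, rel=0.02)
            assert f.elliptical_form_factor == pytest.approx(o_min / o_max, rel=0.02)

    def test_inner_radius_matches_bruteforce_distance(self, random_fixture_shapes):
        for mask, _poly in random_fixture_shapes[:12]:
            f = measure_object(mask)
            assert f.inner_radius == pytest.approx(oracle_inner_radius(mask),
                                                   abs=1e-6)


class TestContinuousGeometry:
    def test_caliper_features_track_polygon_truth(self, random_fixture_shapes):
        # relative digitization error bounded by ~1 px on each caliper
        for mask, poly in random_fixture_shapes:
            f = measure_object(mask)
            L_t, B_t = polygon_calipers(poly)
            assert abs(f.breadth - B_t) <= 0.12 * B_t + 1.5
            assert f.elliptical_form_factor == pytest.approx(B_t / L_t,
                                                             rel=0.12, abs=0.03)

    def test_perimeter_derived_features_track_polygon_truth(self):
        # larger, elongated fixtures where the fiber model is stable
        rng = np.random.default_rng(7)
        for _ in range(40):
            a = rng.uniform(35, 60)
            aspect = rng.uniform(2.5, 4.0)
            m = rng.uniform(1.5, 3.0)
            poly = superellipse_polygon(a, a / aspect, m, rng.uniform(0, 180))
            mask = rasterize_polygon(poly)
            f = measure_object(mask)
            fl_t, fb_t, _ = fiber_dimensions(poly.length, poly.area)
            sf_t = 4 * math.pi * poly.area / poly.length ** 2
            assert f.shape_factor == pytest.approx(sf_t, rel=0.035)
            assert f.fiber_length == pytest.approx(fl_t, rel=0.035)
            assert f.fiber_breadth == pytest.approx(fb_t, rel=0.035)

    def test_scale_equivariance(self):
        base = superellipse_polygon(18, 7, 2.0, 25.0)
        big = shapely.affinity.scale(base, 2.0, 2.0)
        f1 = measure_object(rasterize_polygon(base))
        f2 = measure_object(rasterize_polygon(big))
        for name in ("breadth", "fiber_length", "fiber_breadth", "inner_radius"):
            assert getattr(f2, name) == pytest.approx(2 * getattr(f1, name), rel=0.05)
        assert f2.total_area == pytest.approx(4 * f1.total_area, rel=0.05)
        for name in ("elliptical_form_factor", "shape_factor"):
            assert getattr(f2, name) == pytest.approx(getattr(f1, name), rel=0.04)

    def test_rotation_invariance_convex_shape(self):
        vals = {name: [] for name in FEATURE_NAMES}
        for deg in np.arange(0, 180, 15):
            poly = superellipse_polygon(30, 12, 2.0, float(deg))
            f = measure_object(rasterize_polygon(poly))
            for name in FEATURE_NAMES:
                vals[name].append(getattr(f, name))
        for name, v in vals.items():
            v = np.array(v)
            if name in ("hole_area", "relative_hole_area"):
                assert (v == 0).all()
                continue
            spread = (v.max() - v.min()) / np.median(v)
            assert spread <= 0.07, f"{name} varies {spread:.3f} across rotations"


class TestStandardizeAndCleanse:
    def _table(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({f: rng.normal(10, 2, n) for f in FEATURE_NAMES})

    def test_standardized_moments(self):
        z, flags = standardize_objects(self._table())
        assert np.allclose(z.mean(), 0, atol=1e-9)
        assert np.allclose(z.std(ddof=0), 1, atol=1e-9)
        assert not any(flags.values())

    def test_constant_feature_flagged_zero(self):
        t = self._table()
        t["breadth"] = 5.0
        z, flags = standardize_objects(t)
        assert flags["breadth"] and (z["breadth"] == 0).all()

    def test_affine_invariance(self):
        t = self._table()
        z1, _ = standardize_objects(t)
        z2, _ = standardize_objects(t * 3.7 + 11.0)
        assert np.allclose(z1.to_numpy(), z2.to_numpy(), atol=1e-9)

    def test_requires_two_objects(self):
        with pytest.raises(ValueError):
            standardize_objects(self._table(n=1))

    def test_cleanse_identity_without_outliers(self):
        # bounded (uniform) populations cannot produce robust-z far outliers
        t = self._table()
        rng = np.random.default_rng(1)
        t["total_area"] = rng.uniform(250, 350, len(t))
        t["shape_factor"] = rng.uniform(0.5, 0.7, len(t))
        kept, removed = cleanse_noise(t, 3.5)
        assert len(kept) == len(t) and len(removed) == 0
        kept_inf, _ = cleanse_noise(t, 1e12)
        assert len(kept_inf) == len(t)

    def test_cleanse_removes_injected_debris(self):
        rng = np.random.default_rng(2)
        cells = pd.DataFrame({f: rng.normal(10, 1, 60) for f in FEATURE_NAMES})
        cells["total_area"] = rng.normal(320, 60, 60)
        cells["shape_factor"] = rng.uniform(0.3, 0.8, 60)
        debris = cells.iloc[:10].copy()
        debris["total_area"] = rng.uniform(52, 65, 10)   # just past particle filter
        debris["shape_factor"] = rng.uniform(0.88, 0.97, 10)
        debris["is_debris"] = True
        pool = pd.concat([cells.assign(is_debris=False), debris], ignore_index=True)
        kept, removed = cleanse_noise(pool, 3.5)
        assert removed["is_debris"].mean() >= 0.9       # >= 90% of removals are debris
        assert (~kept["is_debris"]).sum() >= 0.95 * 60  # <= 5% true cells lost
        assert removed["is_debris"].sum() >= 9

    def test_cleanse_rejects_nonpositive_cut(self):
        with pytest.raises(ValueError):
            cleanse_noise(self._table(), 0.0)


def test_measure_objects_table_schema():
    from osteomorph.segmentation import extract_objects
    from osteomorph.config import SegmentationConfig

    raster = np.zeros((64, 64), bool)
    raster[5:25, 5:25] = True
    raster[40:58, 30:60] = True
    objset = extract_objects(raster, SegmentationConfig())
    df = measure_objects(objset, meta={"well_id": "w1", "timepoint": 3})
    assert len(df) == 2
    assert list(df.columns[:1]) == ["object_id"]
    assert set(FEATURE_NAMES) <= set(df.columns)
    assert (df["well_id"] == "w1").all()
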