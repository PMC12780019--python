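"""Geometry of mask morphometry checked against independent naive oracles."""

import math

import numpy as np
import pytest

from endoquant.morphometry import (convex_hull, extract_boundary,
                                   label_instances, max_pixel_distance,
                                   measure_mask, point_in_hull)
from endoquant.calibration import CalibrationModel
from endoquant.synthetic import ShapeSpec, make_mask

from conftest import (all_pairs_max_distance, boundary_scan,
                      brute_force_hull_vertices, flood_fill_components)


def random_blob_mask(seed, h=64, w=64, p=0.35, smooth=2):
    """Random blobby mask by thresholding smoothed noise (test helper)."""
    from scipy import ndimage
    rng = np.random.default_rng(seed)
    field = ndimage.uniform_filter(rng.random((h, w)), size=2 * smooth + 1)
    return field > np.quantile(field, 1 - p)


class TestLabelInstances:
    def test_empty_mask_yields_no_instances(self):
        assert label_instances(np.zeros((10, 10), bool), 0) == []

    def test_two_disjoint_squares(self):
        m = np.zeros((10, 10), bool)
        m[1:4, 1:4] = True
        m[6:9, 6:9] = True
        inst = label_instances(m, 0)
        assert [i.id for i in inst] == [1, 2]
        assert [i.area_px for i in inst] == [9, 9]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_flood_fill_oracle(self, seed):
        m = random_blob_mask(seed)
        inst = label_instances(m, 0)
        oracle = flood_fill_components(m)
        assert len(inst) == len(oracle)
        got = {frozenset(map(tuple, i.pixels.tolist())) for i in inst}
        assert got == {frozenset(c) for c in oracle}

    def test_min_area_filters_small_components(self):
        m = np.zeros((12, 12), bool)
        m[0:3, 0:3] = True     # area 9
        m[5:8, 5:8] = True     # area 9
        m[10, 10:12] = True    # area 2
        assert len(label_instances(m, 5)) == 2
        assert len(label_instances(m, 0)) == 3

    def test_scan_order_labelling(self):
        m = np.zeros((10, 10), bool)
        m[7:9, 0:2] = True     # lower-left, later in scan order
        m[0:2, 7:9] = True     # upper-right, first pixel earlier
        inst = label_instances(m, 0)
        assert tuple(inst[0].pixels[0]) == (0, 7)
        assert tuple(inst[1].pixels[0]) == (7, 0)

    def test_count_conservation(self):
        m = random_blob_mask(7)
        inst = label_instances(m, 0)
        assert sum(i.area_px for i in inst) == int(m.sum())


class TestExtractBoundary:
    def test_single_pixel(self):
        m = np.zeros((10, 10), bool)
        m[5, 5] = True
        inst = label_instances(m, 0)[0]
        assert inst.boundary == [(5, 5)]

    def test_solid_square_perimeter(self):
        m = np.zeros((5, 5), bool)
        m[0:3, 0:3] = True
        inst = label_instances(m, 0)[0]
        assert set(inst.boundary) == {(r, c) for r in range(3) for c in range(3)
                                      if (r, c) != (1, 1)}
        assert len(inst.boundary) == 8
        # clockwise screen order starting at the raster-first pixel
        assert inst.boundary[:3] == [(0, 0), (0, 1), (0, 2)]

    @pytest.mark.parametrize("seed", [1, 3, 5])
    def test_matches_neighbour_scan_oracle(self, seed):
        m = random_blob_mask(seed)
        for inst in label_instances(m, 0):
            got = set(extract_boundary(inst, m))
            want = boundary_scan(m, map(tuple, inst.pixels.tolist()))
            assert got == want
            # no duplicates in the ordered trace
            assert len(inst.boundary) == len(set(inst.boundary))

    def test_mask_with_hole_includes_inner_contour(self):
        m = np.zeros((9, 9), bool)
        m[1:8, 1:8] = True
        m[3:6, 3:6] = False     # 3x3 hole
        inst = label_instances(m, 0)[0]
        got = set(inst.boundary)
        want = boundary_scan(m, map(tuple, inst.pixels.tolist()))
        assert got == want
        assert (2, 3) in got    # pixel bordering the hole


class TestConvexHull:
    def test_triangle(self):
        pts = [(0, 0), (4, 0), (0, 3)]
        assert set(convex_hull(pts)) == {(0.0, 0.0), (4.0, 0.0), (0.0, 3.0)}

    def test_interior_point_excluded(self):
        pts = [(0, 0), (0, 1), (1, 0), (1, 1), (0.5, 0.5)]
        assert set(convex_hull(pts)) == {(0.0, 0.0), (0.0, 1.0),
                                         (1.0, 0.0), (1.0, 1.0)}

    def test_duplicates_tolerated_and_empty_rejected(self):
        assert convex_hull([(2, 2), (2, 2)]) == [(2.0, 2.0)]
        with pytest.raises(ValueError, match="no points"):
            convex_hull([])

    def test_collinear_reduces_to_endpoints(self):
        assert convex_hull([(0, i) for i in range(10)]) == [(0.0, 0.0), (0.0, 9.0)]

    def test_counter_clockwise_and_strict_turns(self, rng):
        pts = rng.integers(0, 50, size=(80, 2))
        hull = convex_hull(pts)
        n = len(hull)
        assert n >= 3
        for i in range(n):
            o, a, b = hull[i], hull[(i + 1) % n], hull[(i + 2) % n]
            cross = (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])
            assert cross > 0   # strictly CCW, no collinear triples

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 40))
        pts = rng.integers(0, 30, size=(n, 2))
        assert set(convex_hull(pts)) == brute_force_hull_vertices(pts)

    def test_containment_of_all_inputs(self, rng):
        for _ in range(20):
            pts = rng.normal(size=(60, 2)) * 10
            hull = convex_hull(pts)
            assert all(point_in_hull(p, hull) for p in pts)


class TestMaxPixelDistance:
    def test_unit_square_diagonal(self):
        d, ends = max_pixel_distance(convex_hull([(0, 0), (0, 1), (1, 0), (1, 1)]))
        assert d == pytest.approx(math.sqrt(2))
        assert ends == ((0.0, 0.0), (1.0, 1.0))   # lexicographic tie-break

    def test_collinear_segment(self):
        d, ends = max_pixel_distance(convex_hull([(0, i) for i in range(10)]))
        assert d == 9.0
        assert ends == ((0.0, 0.0), (0.0, 9.0))

    def test_single_vertex(self):
        d, ends = max_pixel_distance([(3, 4)])
        assert d == 0.0 and ends[0] == ends[1]

    @pytest.mark.parametrize("seed", [3, 4, 5, 6])
    def test_calipers_equals_all_pairs_over_all_points(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.integers(0, 200, size=(150, 2))
        d, ends = max_pixel_distance(convex_hull(pts))
        d_oracle, ends_oracle = all_pairs_max_distance(pts)
        assert d == d_oracle          # same floating arithmetic, exact
        assert ends == ends_oracle

    def test_scale_equivariance(self, rng):
        pts = rng.integers(0, 40, size=(50, 2))
        d1, _ = max_pixel_distance(convex_hull(pts))
        for k in (2, 3, 7):
            dk, _ = max_pixel_distance(convex_hull(pts * k))
            assert dk == pytest.approx(k * d1, rel=1e-12)


class TestMeasureMask:
    def test_calibrated_fields_and_sphere_volume(self):
        m = np.zeros((20, 20), bool)
        m[5, 5:16] = True      # 1x11 bar -> max diameter 10 px
        cal = CalibrationModel(slope=0.5, intercept=0.0, r_squared=1.0, n=2)
        rec = measure_mask(m, 0, calibration=cal)[0]
        assert rec.max_diameter_px == 10.0
        assert rec.max_diameter_phys == pytest.approx(5.0)
        assert rec.est_volume_phys == pytest.approx(math.pi / 6 * 125)
        assert rec.area_phys == pytest.approx(0.25 * 11)

    def test_no_calibration_leaves_physical_fields_absent(self):
        m = np.zeros((10, 10), bool)
        m[2:5, 2:5] = True
        rec = measure_mask(m, 0)[0]
        assert rec.max_diameter_phys is None and rec.est_volume_phys is None

    def test_count_after_area_filter(self):
        m = np.zeros((16, 16), bool)
        m[0:3, 0:3] = True
        m[6:9, 6:9] = True
        m[12, 12:14] = True
        assert len(measure_mask(m, 5)) == 2

    def test_ellipse_diameter_within_discretization_bound(self):
        spec = ShapeSpec("ellipse", (32, 32), {"a": 20, "b": 10,
                                               "rotation_deg": 25.0})
        mask, truth = make_mask(64, 64, [spec], seed=4)
        rec = measure_mask(mask, 0)[0]
        assert abs(rec.max_diameter_px - truth.diameters[0]) <= 1.5

    def test_diameter_attained_on_hull(self):
        m = random_blob_mask(11)
        for inst in label_instances(m, 0):
            d_hull, _ = max_pixel_distance(convex_hull(inst.boundary))
            d_all, _ = all_pairs_max_distance(inst.pixels)
            assert d_hull == pytest.approx(d_all, abs=1e-12)

    def test_rotation_invariance_within_discretization(self):
        diams = []
        for rot in (0.0, 37.0):
            spec = ShapeSpec("ellipse", (40, 40),
                             {"a": 18, "b": 9, "rotation_deg": rot})
            mask, _ = make_mask(80, 80, [spec], seed=0)
            diams.append(measure_mask(mask, 0)[0].max_diameter_px)
        assert abs(diams[0] - diams[1]) <= 2.0
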