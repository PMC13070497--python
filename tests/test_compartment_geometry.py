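import numpy as np
import pytest

import orgoquant as oq
from orgoquant.compartment_geometry import (
    ClusterContour,
    Ellipse,
    NoNeckError,
    decompose_ellipses,
    ellipse_region,
    find_neck_points,
    fit_ellipse,
)
from orgoquant.imaging_io import PlanarImage
from orgoquant.segmentation import ClusterMask, extract_contour, region_grow

from oracles import ellipse_pixel_count

# analytic intersection points of the snowman circles (r=40 @ (50,70), r=30 @ (105,70))
_D = 55.0
_NECK_X = 50 + (_D**2 + 40**2 - 30**2) / (2 * _D)
_NECK_Y = np.sqrt(40**2 - ((_D**2 + 40**2 - 30**2) / (2 * _D)) ** 2)


def _snowman_contour(mask):
    img = PlanarImage(np.where(mask, 200.0, 10.0), 1.0)
    return extract_contour(region_grow(img, (70, 50), 20))


class TestNeckDetection:
    def test_snowman_necks_near_analytic_intersections(self, snowman):
        contour = _snowman_contour(snowman)
        neck = find_neck_points(contour)
        step = neck.contour.perimeter_px / neck.contour.n_vertices
        pts = neck.contour.vertices[[neck.i, neck.j]]
        analytic = np.array([[_NECK_X, 70 - _NECK_Y], [_NECK_X, 70 + _NECK_Y]])
        for p in pts:
            d = np.hypot(analytic[:, 0] - p[0], analytic[:, 1] - p[1]).min()
            assert d <= 3 * step

    def test_convex_ellipse_has_no_neck(self):
        e = Ellipse((50, 50), 40, 28, 0.4)
        contour = ClusterContour(e.point_at(np.linspace(0, 2 * np.pi, 300, endpoint=False)))
        with pytest.raises(NoNeckError):
            find_neck_points(contour)

    def test_neck_stable_under_boundary_jitter(self, snowman):
        clean = find_neck_points(_snowman_contour(snowman))
        rng = np.random.default_rng(9)
        verts = clean.contour.vertices + rng.normal(0, 0.7, size=(clean.contour.n_vertices, 2))
        noisy = find_neck_points(ClusterContour(verts))
        step = clean.contour.perimeter_px / clean.contour.n_vertices
        for pi in (noisy.i, noisy.j):
            p = noisy.contour.vertices[pi]
            d = min(
                np.hypot(*(clean.contour.vertices[clean.i] - p)),
                np.hypot(*(clean.contour.vertices[clean.j] - p)),
            )
            assert d <= 5 * step


class TestEllipseFit:
    @pytest.mark.parametrize(
        "center, a, b, rot",
        [((10, 20), 40, 25, 0.7), ((0, 0), 60, 58, 2.4), ((-5, 33), 100, 30, 0.0)],
    )
    def test_noiseless_arc_recovery(self, center, a, b, rot):
        e = Ellipse(center, a, b, rot)
        pts = e.point_at(np.linspace(0.3, 4.0, 200))
        fit, rms = fit_ellipse(pts)
        assert rms < 1e-6
        assert np.hypot(fit.center[0] - center[0], fit.center[1] - center[1]) < 0.5
        assert abs(fit.semi_major - max(a, b)) / max(a, b) < 0.01
        assert abs(fit.semi_minor - min(a, b)) / min(a, b) < 0.01
        dr = abs(fit.rotation - e.rotation)
        assert min(dr, np.pi - dr) < np.deg2rad(1.0) or abs(a - b) / a < 0.05

    def test_collinear_points_raise(self):
        pts = np.column_stack([np.arange(20.0), 2 * np.arange(20.0)])
        with pytest.raises(oq.compartment_geometry.EllipseFitError):
            fit_ellipse(pts)


class TestDecomposition:
    def test_snowman_recovers_generating_circles(self, snowman):
        contour = _snowman_contour(snowman)
        pair = decompose_ellipses(contour, (50, 70), (105, 70), frame_shape=snowman.shape)
        # tumor hint sits in the small lobe
        for e, (cx, cy, r) in ((pair.brain, (50, 70, 40)), (pair.tumor, (105, 70, 30))):
            assert np.hypot(e.center[0] - cx, e.center[1] - cy) <= 2.0
            assert abs(e.semi_major - r) / r <= 0.03
            assert abs(e.semi_minor - r) / r <= 0.03
        assert pair.overlap_area_px2 > 0

    def test_invariant_to_start_vertex_and_direction(self, snowman):
        contour = _snowman_contour(snowman)
        pair0 = decompose_ellipses(contour, (50, 70), (105, 70), frame_shape=snowman.shape)
        rolled = ClusterContour(np.roll(contour.vertices, 57, axis=0))
        reversed_ = ClusterContour(contour.vertices[::-1])
        for other in (rolled, reversed_):
            pair = decompose_ellipses(other, (50, 70), (105, 70), frame_shape=snowman.shape)
            np.testing.assert_allclose(pair.brain.center, pair0.brain.center, atol=1e-8)
            np.testing.assert_allclose(
                [pair.brain.semi_major, pair.tumor.semi_major],
                [pair0.brain.semi_major, pair0.tumor.semi_major],
                rtol=1e-8,
            )

    def test_gfp_mask_assigns_tumor_identity(self):
        """Over 20 seeded scenes the GFP-filled lobe is called tumor."""
        for seed in range(20):
            stack, truth = oq.render_scene(oq.SceneSpec(seed=200 + seed))
            ref = oq.max_intensity_projection(stack, "BF")
            gfp = oq.max_intensity_projection(stack, "GFP")
            cluster = region_grow(ref, (int(truth.brain_center_xy[1]),
                                        int(truth.brain_center_xy[0])), 35)
            contour = extract_contour(cluster)
            gmask = oq.tumor_mask(gfp, cluster)
            pair = decompose_ellipses(contour, truth.brain_center_xy,
                                      truth.tumor_center_xy, gfp_mask=gmask)
            d_tumor = np.hypot(pair.tumor.center[0] - truth.tumor_center_xy[0],
                               pair.tumor.center[1] - truth.tumor_center_xy[1])
            d_brain = np.hypot(pair.tumor.center[0] - truth.brain_center_xy[0],
                               pair.tumor.center[1] - truth.brain_center_xy[1])
            assert d_tumor < d_brain

    def test_no_neck_falls_back_to_seeded_split(self):
        e = Ellipse((60, 60), 45, 30, 0.0)
        contour = ClusterContour(e.point_at(np.linspace(0, 2 * np.pi, 300, endpoint=False)))
        pair = decompose_ellipses(contour, (40, 60), (80, 60), frame_shape=(120, 120))
        assert pair.brain.center[0] < pair.tumor.center[0]

    def test_hints_outside_contour_rejected(self, snowman):
        contour = _snowman_contour(snowman)
        with pytest.raises(ValueError):
            decompose_ellipses(contour, (2, 2), (105, 70), frame_shape=snowman.shape)


class TestEllipseRegion:
    def test_circle_matches_exhaustive_pixel_count(self):
        e = Ellipse((31.3, 32.7), 10.5, 10.5, 0.0)
        region = ellipse_region(e, (64, 64))
        assert region.sum() == ellipse_pixel_count(31.3, 32.7, 10.5, 10.5, 0.0, (64, 64))

    def test_rotated_ellipse_matches_exhaustive_count(self):
        e = Ellipse((30, 25), 18, 9, 0.9)
        region = ellipse_region(e, (60, 70))
        assert region.sum() == ellipse_pixel_count(30, 25, 18, 9, 0.9, (60, 70))

    def test_ellipse_outside_frame_is_empty(self):
        e = Ellipse((500, 500), 20, 10, 0.0)
        assert not ellipse_region(e, (64, 64)).any()

    def test_circle_mask_is_rotation_invariant(self):
        m0 = ellipse_region(Ellipse((32, 32), 12, 12, 0.0), (64, 64))
        m1 = ellipse_region(Ellipse((32, 32), 12, 12, np.pi / 3), (64, 64))
        np.testing.assert_array_equal(m0, m1)

    @pytest.mark.parametrize("a, b", [(15, 15), (20, 16), (40, 22), (33, 15)])
    def test_pixel_area_approaches_analytic(self, a, b):
        e = Ellipse((64, 64), a, b, 0.4)
        count = ellipse_region(e, (128, 128)).sum()
        assert abs(count - np.pi * a * b) / (np.pi * a * b) < 0.015


def test_ellipse_pair_serialization_roundtrip():
    pair = oq.EllipsePair(
        Ellipse((10, 12), 30, 20, 0.3), Ellipse((40, 12), 22, 18, 1.1),
        overlap_area_px2=55.0, fit_residual_px={"brain": 0.2, "tumor": 0.4},
    )
    back = oq.EllipsePair.from_dict(pair.to_dict())
    assert back.brain.semi_major == pair.brain.semi_major
    assert back.overlap_area_px2 == 55.0
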