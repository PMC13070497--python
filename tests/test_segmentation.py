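import numpy as np
import pytest

import orgoquant as oq
from orgoquant.imaging_io import PlanarImage
from orgoquant.segmentation import (
    ClusterMask,
    classify_components,
    extract_contour,
    region_grow,
    tumor_mask,
)

from oracles import flood_fill_oracle, shoelace_area


def _img(arr, px=1.0):
    return PlanarImage(np.asarray(arr, dtype=float), px)


class TestRegionGrow:
    def test_two_level_image_segments_exactly_one_level(self):
        arr = np.full((8, 8), 10.0)
        arr[:, :4] = 100.0
        mask = region_grow(_img(arr), (3, 1), tolerance=20).member
        expected = np.zeros((8, 8), bool)
        expected[:, :4] = True
        np.testing.assert_array_equal(mask, expected)

    def test_uniform_image_fills_frame_at_zero_tolerance(self):
        mask = region_grow(_img(np.full((12, 9), 7.0)), (5, 5), 0).member
        assert mask.all()

    def test_out_of_bounds_seed(self):
        with pytest.raises(IndexError):
            region_grow(_img(np.zeros((4, 4))), (9, 0), 1)

    def test_isolated_seed_yields_singleton(self):
        arr = np.zeros((5, 5))
        arr[2, 2] = 500.0
        mask = region_grow(_img(arr), (2, 2), tolerance=10).member
        assert mask.sum() == 1 and mask[2, 2]

    def test_matches_independent_flood_fill_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            arr = rng.uniform(0, 255, size=(32, 32))
            seed = (int(rng.integers(32)), int(rng.integers(32)))
            tol = float(rng.uniform(5, 50))
            got = region_grow(_img(arr), seed, tol).member
            np.testing.assert_array_equal(got, flood_fill_oracle(arr, seed, tol))

    def test_invariant_to_constant_intensity_shift(self):
        rng = np.random.default_rng(5)
        arr = rng.uniform(0, 200, size=(24, 24))
        m1 = region_grow(_img(arr), (12, 12), 25).member
        m2 = region_grow(_img(arr + 137.0), (12, 12), 25).member
        np.testing.assert_array_equal(m1, m2)


class TestExtractContour:
    def test_square_mask_area_matches_shoelace_oracle(self):
        mask = np.zeros((14, 14), bool)
        mask[2:12, 3:13] = True  # 10x10 block
        contour = extract_contour(ClusterMask(mask, (5, 5)))
        assert not contour.degenerate
        assert contour.signed_area_px2 > 0  # counter-clockwise
        # pixel-center outline of a 10x10 block encloses a 9x9 square
        assert shoelace_area(contour.vertices) == pytest.approx(81.0)
        assert contour.area_px2 == pytest.approx(shoelace_area(contour.vertices))

    def test_interior_hole_is_filled(self):
        mask = np.zeros((20, 20), bool)
        mask[4:16, 4:16] = True
        holey = mask.copy()
        holey[8:12, 8:12] = False
        c_full = extract_contour(ClusterMask(mask, (5, 5)))
        c_hole = extract_contour(ClusterMask(holey, (5, 5)))
        np.testing.assert_allclose(c_full.vertices, c_hole.vertices)

    def test_single_pixel_mask_flagged_degenerate(self):
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True
        contour = extract_contour(ClusterMask(mask, (2, 2)))
        assert contour.degenerate

    def test_largest_component_wins(self):
        mask = np.zeros((20, 20), bool)
        mask[2:12, 2:12] = True
        mask[15:17, 15:17] = True  # small distractor
        contour = extract_contour(ClusterMask(mask, (5, 5)))
        assert contour.vertices[:, 0].max() < 13


class TestTumorMask:
    def test_fixed_threshold_selects_high_level_inside_cluster(self):
        arr = np.full((10, 10), 50.0)
        arr[:, 5:] = 200.0
        cluster = ClusterMask(np.ones((10, 10), bool), (0, 0))
        got = tumor_mask(_img(arr), cluster, "fixed:128")
        expected = arr > 128
        np.testing.assert_array_equal(got, expected)

    def test_pixels_outside_cluster_always_false(self):
        arr = np.full((10, 10), 200.0)
        member = np.zeros((10, 10), bool)
        member[:5] = True
        got = tumor_mask(_img(arr), ClusterMask(member, (0, 0)), "fixed:100")
        assert not got[5:].any()

    def test_otsu_recovers_generated_blobs(self):
        rng = np.random.default_rng(7)
        arr = rng.normal(10, 2, size=(64, 64))
        truth = np.zeros((64, 64), bool)
        for cy, cx in ((16, 16), (40, 45), (50, 20)):
            yy, xx = np.mgrid[0:64, 0:64]
            truth |= (yy - cy) ** 2 + (xx - cx) ** 2 <= 36
        arr[truth] = rng.normal(200, 5, size=truth.sum())
        cluster = ClusterMask(np.ones((64, 64), bool), (0, 0))
        got = tumor_mask(_img(arr), cluster, "otsu")
        jaccard = (got & truth).sum() / (got | truth).sum()
        assert jaccard >= 0.95

    def test_flat_background_gives_empty_mask(self):
        arr = np.full((8, 8), 10.0)
        cluster = ClusterMask(np.ones((8, 8), bool), (0, 0))
        assert not tumor_mask(_img(arr), cluster, "otsu").any()


def _blob(mask, r0, c0, h, w):
    mask[r0 : r0 + h, c0 : c0 + w] = True


class TestClassifyComponents:
    def test_core_plus_three_singles(self):
        mask = np.zeros((60, 60), bool)
        _blob(mask, 5, 5, 20, 20)  # core at anchor
        for r, c in ((40, 5), (40, 25), (40, 45)):
            _blob(mask, r, c, 4, 4)
        seg = classify_components(mask, (10, 10), min_object_um2=4, pixel_size_um=1)
        assert seg.component_labels[10, 10] == seg.core_label
        assert len(seg.single_cell_labels) == 3

    def test_diagonal_touch_merges_into_core(self):
        mask = np.zeros((20, 20), bool)
        _blob(mask, 2, 2, 6, 6)
        mask[8, 8] = True  # touches (7,7) corner diagonally
        _blob(mask, 8, 8, 3, 3)
        seg = classify_components(mask, (3, 3), min_object_um2=1, pixel_size_um=1)
        assert len(seg.single_cell_labels) == 0
        assert seg.component_labels[9, 9] == seg.core_label

    def test_generator_debris_below_filter_is_discarded(self, scene_hints):
        spec = oq.SceneSpec(seed=21, n_debris_cells=4, debris_area_px=6)
        stack, truth = oq.render_scene(spec)
        res = oq.quantify_image(stack, scene_hints(truth), min_object_um2=20.0)
        assert len(res.segmentation.single_cell_labels) == truth.n_single_cells == 12

    def test_labels_partition_filtered_mask(self):
        rng = np.random.default_rng(2)
        mask = rng.random((40, 40)) > 0.7
        seg = classify_components(mask, (20, 20), min_object_um2=3, pixel_size_um=1)
        labeled = seg.component_labels != 0
        assert not (labeled & ~seg.gfp_mask).any()
        union = seg.core_mask | seg.single_cell_mask
        np.testing.assert_array_equal(union, labeled)
        # background + labeled pixels tile the frame exactly
        assert labeled.sum() + (~labeled).sum() == mask.size

    def test_raising_size_filter_never_adds_singles(self):
        rng = np.random.default_rng(3)
        mask = rng.random((50, 50)) > 0.65
        counts = [
            len(classify_components(mask, (25, 25), t, 1.0).single_cell_labels)
            for t in (1, 4, 9, 16, 36)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_nothing_survives_filter_flags_empty(self):
        mask = np.zeros((10, 10), bool)
        mask[4, 4] = True
        seg = classify_components(mask, (4, 4), min_object_um2=50, pixel_size_um=1)
        assert seg.empty
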