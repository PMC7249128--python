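"""Segmentation operators against brute-force oracles on small frames."""

import numpy as np
import pytest

from salixmap.geometry import CameraModel, ThresholdPlane, build_threshold_plane
from salixmap.segmentation import (
    FloodParams,
    FramePair,
    HistogramParams,
    background_removed,
    depth_mask,
    dynamic_histogram_threshold,
    equalize_clahe,
    find_seed_points,
    flood_fill_segment,
    median_filter_depth,
    segment,
)
from salixmap.synthetic import SceneSpec, generate_scene

from oracles import (
    clahe_ref,
    depth_mask_ref,
    flood_fill_ref,
    hist_threshold_ref,
    median_filter_ref,
    seed_points_ref,
)


class TestMedianFilter:
    def test_constant_array_unchanged(self):
        a = np.full((7, 7), 42, dtype=np.uint16)
        assert np.array_equal(median_filter_depth(a, 5), a)

    def test_single_impulse_removed(self):
        a = np.zeros((9, 9), dtype=np.uint16)
        a[4, 4] = 1000
        assert median_filter_depth(a, 3).max() == 0

    @pytest.mark.parametrize("kernel", [3, 5])
    def test_matches_nested_loop_oracle(self, kernel, rng):
        a = rng.integers(0, 4000, (9, 9)).astype(np.uint16)
        assert np.array_equal(median_filter_depth(a, kernel), median_filter_ref(a, kernel))

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            median_filter_depth(np.zeros((4, 4)), 4)


class TestDepthMask:
    def _plane(self, values):
        return ThresholdPlane(np.asarray(values, dtype=float))

    def test_all_beyond_plane_masked_out(self, camera):
        plane = build_threshold_plane(camera)
        depth = np.full((camera.frame_height, 4), 5000, dtype=np.uint16)
        assert depth_mask(depth, plane, camera).sum() == 0

    def test_all_in_front_fully_kept(self, camera):
        plane = build_threshold_plane(camera)
        z = int(camera.bottom_plane_distance / camera.depth_scale / 2)
        depth = np.full((camera.frame_height, 4), z, dtype=np.uint16)
        assert depth_mask(depth, plane, camera).all()

    def test_zero_depth_is_invalid(self, camera):
        plane = self._plane([2.0, 2.0])
        depth = np.array([[0, 500], [0, 500]], dtype=np.uint16)
        out = depth_mask(depth, plane, camera)
        assert np.array_equal(out, [[0, 1], [0, 1]])

    def test_matches_elementwise_oracle(self, camera, rng):
        plane = self._plane([2.0, 2.0, 1.5, 1.5])
        depth = rng.integers(0, 3000, (4, 4)).astype(np.uint16)
        out = depth_mask(depth, plane, camera)
        ref = depth_mask_ref(depth, plane.per_row_threshold, camera.depth_scale)
        assert np.array_equal(out, ref)

    def test_anti_monotone_in_depth(self, camera, rng):
        plane = self._plane(np.linspace(2.0, 1.2, 8))
        depth = rng.integers(0, 3000, (8, 8)).astype(np.uint16)
        base = depth_mask(depth, plane, camera)
        bumped = depth.copy()
        bumped[rng.integers(0, 8), rng.integers(0, 8)] += 500
        after = depth_mask(bumped, plane, camera)
        assert not np.any(after > base)


class TestClahe:
    def test_constant_image_stays_constant(self):
        out = equalize_clahe(np.full((32, 32), 120, dtype=np.uint8))
        assert len(np.unique(out)) == 1

    def test_output_is_valid_uint8(self, rng):
        out = equalize_clahe(rng.integers(0, 256, (40, 56)).astype(np.uint8), tiles=(4, 4))
        assert out.dtype == np.uint8 and out.shape == (40, 56)

    @pytest.mark.parametrize("tiles", [(1, 2), (2, 2), (3, 4)])
    def test_matches_clipped_cdf_oracle(self, tiles, rng):
        gray = (np.linspace(0, 255, 24 * 24).reshape(24, 24)).astype(np.uint8)
        assert np.array_equal(
            equalize_clahe(gray, 40.0, tiles), clahe_ref(gray, 40.0, tiles)
        )
        noisy = rng.integers(0, 256, (24, 24)).astype(np.uint8)
        assert np.array_equal(
            equalize_clahe(noisy, 40.0, tiles), clahe_ref(noisy, 40.0, tiles)
        )

    def test_grid_larger_than_frame_rejected(self):
        with pytest.raises(ValueError):
            equalize_clahe(np.zeros((4, 4), dtype=np.uint8), tiles=(8, 8))


class TestDynamicHistogramThreshold:
    def test_single_intensity_spike(self):
        gray = np.full((8, 8), 77, dtype=np.uint8)
        mask = np.ones_like(gray)
        out = dynamic_histogram_threshold(gray, mask, HistogramParams(50, 10, 50))
        assert out.tolist() == [77]

    def test_vacuous_count_difference_keeps_whole_band(self, rng):
        # every intensity 100..139 present, so with the threshold fully
        # open the clipped candidate band is returned in full
        gray = rng.integers(100, 140, (32, 32)).astype(np.uint8)
        gray.flat[:40] = np.arange(100, 140)  # guarantee all bins occupied
        out = dynamic_histogram_threshold(gray, None, HistogramParams(255, 10, 255))
        peak = int(np.argmax(np.bincount(gray.ravel(), minlength=256)))
        lo, hi = max(10, peak - 127), min(255, peak + 127)
        expected = [v for v in range(lo, hi + 1) if (gray == v).any()]
        assert out.tolist() == expected
        assert set(range(100, 140)) <= set(out.tolist())

    def test_empty_mask_gives_empty_list(self):
        gray = np.zeros((4, 4), dtype=np.uint8)
        out = dynamic_histogram_threshold(gray, np.zeros_like(gray), HistogramParams())
        assert out.size == 0

    @pytest.mark.parametrize("params", [(6, 0, 50), (50, 10, 200), (20, 30, 120)])
    def test_matches_exhaustive_per_bin_oracle(self, params, rng):
        peak_range, low_limit, cd = params
        # two intensity populations plus sparse noise
        gray = np.concatenate(
            [
                rng.normal(60, 5, 160).astype(int),
                rng.normal(150, 10, 80).astype(int),
                rng.integers(0, 256, 16),
            ]
        ).clip(0, 255).astype(np.uint8).reshape(16, 16)
        mask = (rng.random((16, 16)) < 0.8).astype(np.uint8)
        hp = HistogramParams(peak_range, low_limit, cd)
        out = dynamic_histogram_threshold(gray, mask, hp)
        assert out.tolist() == hist_threshold_ref(gray, mask, peak_range, low_limit, cd)


class TestBackgroundRemovedAndSeeds:
    def test_all_one_mask_is_identity(self, rng):
        gray = rng.integers(0, 256, (6, 6)).astype(np.uint8)
        assert np.array_equal(background_removed(gray, np.ones_like(gray)), gray)

    def test_all_zero_mask_blanks_frame(self, rng):
        gray = rng.integers(0, 256, (6, 6)).astype(np.uint8)
        assert background_removed(gray, np.zeros_like(gray)).sum() == 0

    def test_checkerboard_mask_elementwise(self, rng):
        gray = rng.integers(1, 256, (8, 8)).astype(np.uint8)
        mask = np.indices((8, 8)).sum(0) % 2
        out = background_removed(gray, mask)
        assert np.array_equal(out, gray * mask.astype(np.uint8))

    def test_empty_intensity_list_no_seeds(self, rng):
        gray = rng.integers(0, 256, (8, 8)).astype(np.uint8)
        assert find_seed_points(gray, []).shape == (0, 2)

    def test_uniform_image_all_coordinates(self):
        gray = np.full((4, 5), 9, dtype=np.uint8)
        seeds = find_seed_points(gray, [9])
        assert seeds.shape == (20, 2)
        # row-major order
        assert np.array_equal(seeds, np.argwhere(np.ones((4, 5), dtype=bool)))

    def test_zero_never_seeds_even_if_listed(self):
        gray = np.zeros((3, 3), dtype=np.uint8)
        assert find_seed_points(gray, [0]).shape == (0, 2)

    def test_matches_double_loop_oracle(self, rng):
        gray = rng.integers(0, 40, (8, 8)).astype(np.uint8)
        wanted = [0, 3, 7, 12, 39]
        out = find_seed_points(gray, wanted)
        assert [tuple(p) for p in out] == seed_points_ref(gray, wanted)


class TestFloodFill:
    def test_uniform_image_single_seed_fills_frame(self):
        gray = np.full((6, 6), 50, dtype=np.uint8)
        mask, flooded = flood_fill_segment(gray, [(2, 3)], FloodParams(10, 30, 4))
        assert mask.all() and flooded == 1

    def test_isolated_bright_pixel_stays_alone(self):
        gray = np.zeros((5, 5), dtype=np.uint8)
        gray[2, 2] = 200
        mask, flooded = flood_fill_segment(gray, [(2, 2)], FloodParams(10, 30, 4))
        assert mask.sum() == 1 and mask[2, 2] == 1

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_bfs_oracle_with_skip_rule(self, connectivity, rng):
        gray = rng.integers(0, 60, (10, 10)).astype(np.uint8)
        gray[:, 5:] += 120  # two populations
        seeds = [tuple(s) for s in np.argwhere(np.ones((10, 10), bool))[:: 7]]
        params = FloodParams(10, 30, connectivity)
        mask, flooded = flood_fill_segment(gray, seeds, params)
        ref_mask, ref_flooded = flood_fill_ref(gray, seeds, 10, 30, connectivity)
        assert np.array_equal(mask, ref_mask)
        assert flooded == ref_flooded

    def test_interior_seeds_are_skipped(self):
        gray = np.full((4, 4), 10, dtype=np.uint8)
        mask, flooded = flood_fill_segment(
            gray, [(0, 0), (2, 2), (3, 3)], FloodParams(5, 5, 4)
        )
        assert mask.all() and flooded == 1

    def test_output_covers_all_flooded_seeds(self, rng):
        gray = rng.integers(0, 256, (12, 12)).astype(np.uint8)
        seeds = [tuple(s) for s in rng.integers(0, 12, (20, 2))]
        mask, _ = flood_fill_segment(gray, seeds, FloodParams(10, 30, 4))
        for r, c in seeds:
            assert mask[r, c] == 1

    def test_out_of_bounds_seed_rejected(self):
        with pytest.raises(ValueError):
            flood_fill_segment(np.zeros((4, 4), dtype=np.uint8), [(4, 0)], FloodParams())


class TestSegmentPipeline:
    def test_all_background_depth_gives_empty_mask(self, camera):
        h, w = camera.frame_height, camera.frame_width
        frame = FramePair(
            gray=np.full((h, w), 120, dtype=np.uint8),
            depth=np.full((h, w), 5000, dtype=np.uint16),
        )
        seg = segment(frame, camera)
        assert seg.binary_mask.sum() == 0
        assert len(seg.seed_points) == 0

    def test_single_stem_frame_mostly_covered(self, camera):
        spec = SceneSpec(n_stems=1, seed=11)
        frame, truth = generate_scene(spec, camera)
        seg = segment(frame, camera)
        stem_pixels = frame.depth == truth[0].depth_raw
        coverage = seg.binary_mask[stem_pixels].mean()
        assert coverage >= 0.8

    def test_eight_stem_frame_has_enough_components(self, camera):
        from scipy import ndimage

        frame, truth = generate_scene(SceneSpec(n_stems=8, seed=5), camera)
        seg = segment(frame, camera)
        _, n = ndimage.label(seg.binary_mask)
        assert n >= 8

    def test_deterministic(self, camera):
        frame, _ = generate_scene(SceneSpec(n_stems=2, seed=3), camera)
        a = segment(frame, camera)
        b = segment(frame, camera)
        assert np.array_equal(a.binary_mask, b.binary_mask)
        assert np.array_equal(a.intensity_list, b.intensity_list)
        assert a.seeds_flooded == b.seeds_flooded

    def test_seed_points_lie_inside_depth_mask(self, camera):
        frame, _ = generate_scene(SceneSpec(n_stems=3, seed=9), camera)
        seg = segment(frame, camera)
        assert len(seg.seed_points) > 0
        rows, cols = seg.seed_points[:, 0], seg.seed_points[:, 1]
        assert seg.depth_mask[rows, cols].all()
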