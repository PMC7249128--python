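"""Mask clean-up, contour extraction, filtering and ID assignment."""

import numpy as np
import pytest

from salixmap.detection import (
    DetectionParams,
    detect,
    filter_contours,
    find_contours,
    morphological_close,
)
from salixmap.segmentation import segment
from salixmap.synthetic import SceneSpec, generate_scene

from oracles import closing_ref, component_areas_ref


class TestMorphologicalClose:
    def test_empty_mask_stays_empty(self):
        assert morphological_close(np.zeros((10, 10), dtype=np.uint8)).sum() == 0

    def test_bridges_sub_kernel_vertical_gap(self):
        from scipy import ndimage

        mask = np.zeros((20, 6), dtype=np.uint8)
        mask[2:8, 2:4] = 1
        mask[11:18, 2:4] = 1  # 3-row gap, kernel is 15 rows tall
        closed = morphological_close(mask, (15, 2))
        _, n = ndimage.label(closed)
        assert n == 1

    @pytest.mark.parametrize("kernel", [(3, 3), (15, 2), (2, 5)])
    def test_matches_minkowski_set_oracle(self, kernel, rng):
        mask = (rng.random((20, 20)) < 0.25).astype(np.uint8)
        assert np.array_equal(morphological_close(mask, kernel), closing_ref(mask, kernel))

    def test_zero_iterations_is_identity(self, rng):
        mask = (rng.random((8, 8)) < 0.5).astype(np.uint8)
        assert np.array_equal(morphological_close(mask, (15, 2), 0), mask)


class TestFindContours:
    def test_filled_square_area(self):
        mask = np.zeros((10, 10), dtype=np.uint8)
        mask[2:6, 3:7] = 1
        (contour,) = find_contours(mask)
        assert contour.area == 16
        assert contour.bbox == (2, 3, 4, 4)
        assert not contour.touches_bottom

    def test_empty_mask_gives_no_contours(self):
        assert find_contours(np.zeros((5, 5), dtype=np.uint8)) == []

    def test_two_blobs_areas_match_labelling_oracle(self, rng):
        mask = np.zeros((16, 16), dtype=np.uint8)
        mask[1:5, 1:5] = 1
        mask[10:16, 8:12] = 1
        contours = find_contours(mask)
        assert sorted(c.area for c in contours) == sorted(component_areas_ref(mask))
        assert [c.touches_bottom for c in sorted(contours, key=lambda c: c.bbox[0])] == [
            False,
            True,
        ]

    def test_interior_holes_are_filled_into_area(self):
        mask = np.ones((7, 7), dtype=np.uint8)
        mask[3, 3] = 0
        (contour,) = find_contours(mask)
        assert contour.area == 49

    def test_random_masks_match_oracle_areas(self, rng):
        from oracles import filled_component_areas_ref

        for density in (0.3, 0.5):
            for _ in range(4):
                mask = (rng.random((12, 12)) < density).astype(np.uint8)
                areas = sorted(c.area for c in find_contours(mask))
                assert areas == sorted(filled_component_areas_ref(mask))


class TestFilterContours:
    def _contours(self, mask):
        return find_contours(np.asarray(mask, dtype=np.uint8))

    def test_sub_area_contour_removed_even_touching_bottom(self):
        # 599 px touching the bottom row: below the 600 floor
        mask = np.zeros((700, 10), dtype=np.uint8)
        mask[-599:, 4] = 1
        (contour,) = self._contours(mask)
        assert contour.area == 599 and contour.touches_bottom
        assert filter_contours([contour], 600) == []

    def test_large_floating_contour_removed(self):
        mask = np.zeros((200, 100), dtype=np.uint8)
        mask[10:110, 10:60] = 1  # area 5000, nowhere near bottom
        (contour,) = self._contours(mask)
        assert filter_contours([contour], 600) == []

    def test_mixed_list_matches_predicate_oracle(self, rng):
        mask = np.zeros((50, 120), dtype=np.uint8)
        mask[-30:, 0:30] = 1      # area 900, bottom
        mask[-10:, 40:45] = 1     # area 50, bottom
        mask[0:40, 60:80] = 1     # area 800, floating
        contours = self._contours(mask)
        kept = filter_contours(contours, 600)
        ref = [c for c in contours if c.area >= 600 and c.touches_bottom]
        assert kept == ref and len(kept) == 1

    def test_monotone_in_min_area(self, rng):
        mask = (rng.random((40, 40)) < 0.4).astype(np.uint8)
        contours = self._contours(mask)
        counts = [len(filter_contours(contours, a)) for a in (0, 5, 20, 100)]
        assert counts == sorted(counts, reverse=True)


class TestDetect:
    def test_empty_mask_detects_nothing(self):
        assert detect(np.zeros((100, 100), dtype=np.uint8)) == []

    def test_clean_eight_stem_frame_detects_exactly_eight(self, camera):
        frame, truth = generate_scene(SceneSpec(n_stems=8, seed=17), camera)
        seg = segment(frame, camera)
        trees = detect(seg.binary_mask)
        assert len(trees) == 8

    def test_ids_run_left_to_right(self, camera):
        frame, truth = generate_scene(SceneSpec(n_stems=4, seed=2), camera)
        seg = segment(frame, camera)
        trees = detect(seg.binary_mask)
        lefts = [t.contour.bbox[1] for t in trees]
        assert [t.tree_id for t in trees] == list(range(1, len(trees) + 1))
        assert lefts == sorted(lefts)

    def test_sub_area_blob_ignored(self):
        mask = np.zeros((720, 300), dtype=np.uint8)
        mask[:, 50:70] = 1      # full-height stem, area 14400
        mask[-20:, 150:160] = 1  # 200-px blob on the bottom row
        trees = detect(mask)
        assert len(trees) == 1
        assert trees[0].contour.bbox == (0, 50, 720, 20)

    def test_count_invariant_under_horizontal_mirror(self, camera):
        frame, _ = generate_scene(SceneSpec(n_stems=5, seed=31), camera)
        seg = segment(frame, camera)
        trees = detect(seg.binary_mask)
        mirrored = detect(seg.binary_mask[:, ::-1])
        assert len(trees) == len(mirrored)
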