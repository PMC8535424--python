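import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import octavg as og
from octavg.averaging import AveragedImage
from octavg.change_analysis import SLAB_THRESHOLDS, box_montage

img8 = hnp.arrays(np.uint8, (24, 24), elements=st.integers(0, 255))


def _avg(px):
    px = np.asarray(px, dtype=np.uint8)
    return AveragedImage(pixels=px, n_frames=5, source_ids=(),
                         validity_mask=np.ones(px.shape, bool))


class TestSubtractPositive:
    def test_equal_images_give_zero(self, rng):
        a = rng.integers(0, 256, (20, 20), dtype=np.uint8)
        assert not og.subtract_positive(a, a).any()

    def test_one_sided(self):
        a = np.array([[50]], np.uint8)
        b = np.array([[30]], np.uint8)
        assert og.subtract_positive(a, b)[0, 0] == 20
        assert og.subtract_positive(b, a)[0, 0] == 0

    @given(a=img8, b=img8)
    def test_difference_of_positive_parts_is_signed_difference(self, a, b):
        gain = og.subtract_positive(a, b).astype(np.int16)
        loss = og.subtract_positive(b, a).astype(np.int16)
        assert np.array_equal(gain - loss, a.astype(np.int16) - b.astype(np.int16))

    @given(a=img8, b=img8)
    def test_gain_and_loss_supports_are_disjoint(self, a, b):
        gain = og.binarize(og.subtract_positive(a, b), 1)
        loss = og.binarize(og.subtract_positive(b, a), 1)
        assert not (gain & loss).any()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            og.subtract_positive(np.zeros((2, 2), np.uint8), np.zeros((3, 3), np.uint8))


class TestBinarize:
    def test_boundary_value_is_foreground(self):
        assert og.binarize(np.array([[40]], np.uint8), 40)[0, 0]

    def test_threshold_zero_selects_everything(self, rng):
        m = rng.integers(0, 256, (10, 10), dtype=np.uint8)
        assert og.binarize(m, 0).all()

    def test_threshold_above_max_selects_nothing(self):
        assert not og.binarize(np.full((4, 4), 254, np.uint8), 255).any()

    def test_foreground_count_non_increasing_in_threshold(self, rng):
        m = rng.integers(0, 256, (30, 30), dtype=np.uint8)
        counts = [og.binarize(m, t).sum() for t in range(0, 256, 17)]
        assert all(c1 >= c2 for c1, c2 in zip(counts, counts[1:]))

    def test_slab_defaults(self):
        m = np.array([[45]], np.uint8)
        assert og.binarize(m, slab="SVP")[0, 0]
        assert not og.binarize(m, slab="DVC")[0, 0]
        assert SLAB_THRESHOLDS == {"SVP": 40, "DVC": 60, "FULL": 40}


class TestOverlay:
    def test_empty_mask_replicates_base(self, rng):
        base = rng.integers(0, 256, (8, 8), dtype=np.uint8)
        rgb = og.make_overlay(base, np.zeros((8, 8), bool))
        assert np.array_equal(rgb[..., 0], base)
        assert np.array_equal(rgb[..., 1], base)
        assert np.array_equal(rgb[..., 2], base)

    def test_full_mask_is_uniform_red(self):
        rgb = og.make_overlay(np.zeros((5, 5), np.uint8), np.ones((5, 5), bool))
        assert np.all(rgb == [255, 0, 0])

    def test_checker_mask_paints_exactly_the_checker(self):
        base = np.full((6, 6), 99, np.uint8)
        mask = np.indices((6, 6)).sum(axis=0) % 2 == 0
        rgb = og.make_overlay(base, mask)
        assert np.all(rgb[mask] == [255, 0, 0])
        assert np.all(rgb[~mask] == [99, 99, 99])


class TestBoxScores:
    def test_empty_masks_score_zero(self):
        grid = og.BoxGrid(box_side=8, n_rows=3, n_cols=3)
        g, l = og.score_boxes(np.zeros((24, 24), bool), np.zeros((24, 24), bool), grid)
        assert g.score == 0 and l.score == 0
        assert not g.counts.any()

    def test_full_mask_counts_box_area(self):
        grid = og.BoxGrid()  # 3x3 of 172
        full = np.ones((516, 516), bool)
        g, _ = og.score_boxes(full, np.zeros_like(full), grid)
        assert np.all(g.counts == 29584)  # 172^2
        assert g.score == 9

    @given(seed=st.integers(0, 50))
    def test_box_counts_conserve_total(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((24, 24)) < 0.3
        grid = og.BoxGrid(box_side=8, n_rows=3, n_cols=3)
        g, _ = og.score_boxes(mask, np.zeros_like(mask), grid)
        # independent recount over the tiled region
        assert g.counts.sum() == mask[:24, :24].sum()

    def test_grid_overflow_rejected(self):
        with pytest.raises(ValueError):
            og.score_boxes(np.zeros((20, 20), bool), np.zeros((20, 20), bool),
                           og.BoxGrid(box_side=8, n_rows=3, n_cols=3))

    def test_validity_mask_excludes_border_fill(self):
        grid = og.BoxGrid(box_side=8, n_rows=1, n_cols=1)
        mask = np.ones((8, 8), bool)
        validity = np.zeros((8, 8), bool)
        validity[:4] = True
        g, _ = og.score_boxes(mask, np.zeros_like(mask), grid, min_pixels=1,
                              validity_mask=validity)
        assert g.counts[0] == 32


class TestSurrogateGrading:
    grid = og.BoxGrid(box_side=10, n_rows=2, n_cols=2)

    def test_noise_only_gain_is_not_vessel_gain(self):
        gain = np.ones((20, 20), bool)
        gt = np.zeros((20, 20), bool)
        assert not og.surrogate_grade_gain(gain, gt, self.grid, min_pixels=1).any()

    def test_gt_everywhere_matches_plain_scores(self, rng):
        gain = rng.random((20, 20)) < 0.4
        gt = np.ones((20, 20), bool)
        flags = og.surrogate_grade_gain(gain, gt, self.grid, min_pixels=20)
        plain, _ = og.score_boxes(gain, np.zeros_like(gain), self.grid, min_pixels=20)
        assert np.array_equal(flags, plain.flags)

    def test_restored_dropout_segment_is_flagged(self):
        # a capillary absent from the single frame, restored by averaging
        single = np.full((20, 20), 20, np.uint8)
        averaged = single.copy()
        gt = np.zeros((20, 20), bool)
        gt[2:4, 1:9] = True
        averaged[2:4, 1:9] = 120
        gain = og.binarize(og.subtract_positive(averaged, single), slab="SVP")
        flags = og.surrogate_grade_gain(gain, gt, self.grid, min_pixels=10)
        assert flags[0] and not flags[1:].any()

    def test_attenuation_without_detection_loss_is_not_loss(self):
        single = np.full((20, 20), 20, np.uint8)
        gt = np.zeros((20, 20), bool)
        gt[5:7, :] = True
        single[5:7, :] = 180
        dimmed = single.copy()
        dimmed[5:7, :] = 120  # still detectable, just dimmer
        loss = og.binarize(og.subtract_positive(single, dimmed), slab="SVP")
        assert loss.any()
        flags = og.surrogate_grade_loss(loss, dimmed, gt, self.grid, slab="SVP",
                                        min_pixels=5)
        assert not flags.any()

    def test_true_erasure_is_flagged_as_loss(self):
        single = np.full((20, 20), 20, np.uint8)
        gt = np.zeros((20, 20), bool)
        gt[5:7, :] = True
        single[5:7, :] = 180
        erased = np.full((20, 20), 20, np.uint8)  # vessel gone entirely
        loss = og.binarize(og.subtract_positive(single, erased), slab="SVP")
        flags = og.surrogate_grade_loss(loss, erased, gt, self.grid, slab="SVP",
                                        min_pixels=5)
        assert flags.any()

    def test_missing_ground_truth_rejected(self):
        with pytest.raises(ValueError):
            og.surrogate_grade_gain(np.zeros((20, 20), bool), None, self.grid)


class TestDiffPipeline:
    def test_identical_pair_has_no_change(self, rng):
        px = rng.integers(0, 256, (516, 516), dtype=np.uint8)
        res = og.diff_pipeline(_avg(px), og.EnFaceImage(pixels=px))
        assert res.gain_scores.score == 0 and res.loss_scores.score == 0
        assert not res.difference.gain_map.any()

    def test_uniform_brightening_is_pure_gain(self):
        single = np.full((516, 516), 60, np.uint8)
        res = og.diff_pipeline(_avg(single + 50), og.EnFaceImage(pixels=single),
                               slab="SVP")
        assert res.difference.gain_mask.all()
        assert not res.difference.loss_mask.any()
        assert res.gain_scores.score == 9 and res.loss_scores.score == 0

    def test_box_counts_match_independent_recount(self, rng):
        a = rng.integers(0, 256, (60, 60), dtype=np.uint8)
        s = rng.integers(0, 256, (60, 60), dtype=np.uint8)
        grid = og.BoxGrid(box_side=20, n_rows=3, n_cols=3)
        res = og.diff_pipeline(_avg(a), og.EnFaceImage(pixels=s), slab="SVP",
                               grid=grid)
        for idx, rs, cs in grid.boxes():
            gain_ref = int(
                ((a[rs, cs].astype(int) - s[rs, cs].astype(int)) >= 40).sum()
            )
            assert res.gain_scores.counts[idx] == gain_ref

    def test_small_image_needs_custom_grid(self):
        px = np.zeros((100, 100), np.uint8)
        with pytest.raises(ValueError):
            og.diff_pipeline(_avg(px), og.EnFaceImage(pixels=px))

    def test_montage_layout(self, rng):
        px = rng.integers(0, 256, (60, 60), dtype=np.uint8)
        grid = og.BoxGrid(box_side=20, n_rows=3, n_cols=3)
        m = box_montage(px, px, grid, pad=2)
        assert m.shape == (9 * 22 - 2, 42)
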