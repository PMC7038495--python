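"""Background modelling, segmentation and element extraction."""

from datetime import datetime

import numpy as np
import pytest

from benthoscan.config import SegmentConfig
from benthoscan.detection import (
    binarize,
    clean_mask,
    daily_background,
    detect_pipeline,
    enhance,
    enhance_background,
    find_elements,
    subtract_background,
)
from benthoscan.io import Frame

from conftest import box_iou


def _frame(pixels, image_id="f", hour=0, day=1):
    return Frame(image_id=image_id, timestamp=datetime(2024, 1, day, hour),
                 pixels=np.asarray(pixels, np.uint8))


class TestDailyBackground:
    def test_mean_of_identical_frames(self):
        frames = [_frame(np.full((6, 6), 100), hour=h) for h in range(24)]
        bg = daily_background(frames)
        assert np.allclose(bg.pixels, 100)
        assert bg.n_frames_used == 24

    def test_two_frame_pixel_average(self):
        a = np.full((4, 4), 10)
        b = np.full((4, 4), 30)
        bg = daily_background([_frame(a, hour=0), _frame(b, hour=1)])
        assert np.allclose(bg.pixels, 20)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        frames = [
            _frame(rng.integers(0, 256, (8, 8), dtype=np.uint8), hour=h)
            for h in range(6)
        ]
        fwd = daily_background(frames).pixels
        rev = daily_background(frames[::-1]).pixels
        assert np.array_equal(fwd, rev)

    def test_mixed_days_fatal(self):
        with pytest.raises(ValueError, match="day"):
            daily_background([_frame(np.zeros((4, 4)), day=1),
                              _frame(np.zeros((4, 4)), day=2)])

    def test_mixed_dims_fatal(self):
        with pytest.raises(ValueError, match="dim"):
            daily_background([_frame(np.zeros((4, 4)), hour=0),
                              _frame(np.zeros((5, 4)), hour=1)])

    def test_empty_fatal(self):
        with pytest.raises(ValueError):
            daily_background([])


class TestSubtract:
    def test_self_subtraction_is_zero(self):
        f = _frame(np.full((6, 6), 140))
        bg = daily_background([f])
        assert subtract_background(f, bg).max() == 0

    def test_absolute_difference_convention(self):
        bg = daily_background([_frame(np.full((4, 4), 100))])
        brighter = subtract_background(_frame(np.full((4, 4), 130)), bg)
        darker = subtract_background(_frame(np.full((4, 4), 70)), bg)
        assert np.all(brighter == 30) and np.all(darker == 30)

    def test_dim_mismatch_fatal(self):
        bg = daily_background([_frame(np.zeros((4, 4)))])
        with pytest.raises(ValueError):
            subtract_background(_frame(np.zeros((5, 5))), bg)


class TestBinarize:
    def test_all_below_threshold_gives_empty_mask(self):
        assert not binarize(np.full((5, 5), 10, np.uint8), 25).any()

    def test_strictly_greater_semantics(self):
        diff = np.array([[0, 10, 40]], np.uint8)
        assert binarize(diff, 25).tolist() == [[False, False, True]]
        assert binarize(diff, 0).tolist() == [[False, True, True]]

    @pytest.mark.parametrize("t_lo,t_hi", [(0, 10), (25, 26), (100, 255)])
    def test_monotone_in_threshold(self, t_lo, t_hi):
        rng = np.random.default_rng(2)
        diff = rng.integers(0, 256, (20, 20)).astype(np.uint8)
        lo, hi = binarize(diff, t_lo), binarize(diff, t_hi)
        assert np.all(hi <= lo)  # raising the threshold never adds pixels


class TestCleanMask:
    def test_empty_mask_stays_empty(self):
        mask = np.zeros((8, 8), bool)
        out = clean_mask(mask, [("closing", 3, 1), ("opening", 3, 1), ("dilation", 3, 1)])
        assert not out.any()

    def test_opening_removes_isolated_pixel(self):
        mask = np.zeros((8, 8), bool)
        mask[4, 4] = True
        assert not clean_mask(mask, [("opening", 3, 1)]).any()

    def test_closing_fills_interior_hole(self):
        mask = np.zeros((9, 9), bool)
        mask[2:7, 2:7] = True
        mask[4, 4] = False
        out = clean_mask(mask, [("closing", 3, 1)])
        assert out[4, 4]
        assert np.all(out >= mask)  # closing is extensive

    @pytest.mark.parametrize("op", ["opening", "closing"])
    def test_idempotence(self, op):
        rng = np.random.default_rng(4)
        mask = rng.random((24, 24)) > 0.6
        once = clean_mask(mask, [(op, 3, 1)])
        twice = clean_mask(once, [(op, 3, 1)])
        assert np.array_equal(once, twice)

    def test_unknown_op_fatal(self):
        with pytest.raises(ValueError, match="unknown"):
            clean_mask(np.zeros((4, 4), bool), [("shrink", 3, 1)])

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            clean_mask(np.zeros((4, 4), bool), [("opening", 4, 1)])


class TestFindElements:
    def test_empty_mask_no_detections(self):
        f = _frame(np.zeros((10, 10)))
        assert find_elements(np.zeros((10, 10), bool), f, 1) == []

    def test_two_blobs_boxes_match_planted_extents(self):
        mask = np.zeros((16, 16), bool)
        mask[2:6, 3:7] = True     # blob A
        mask[10:14, 9:13] = True  # blob B
        f = _frame(np.zeros((16, 16)))
        dets = sorted(find_elements(mask, f, 1), key=lambda d: d.box[1])
        assert len(dets) == 2
        assert dets[0].box == (3, 2, 7, 6)
        assert dets[1].box == (9, 10, 13, 14)
        assert dets[0].area == 16
        assert dets[0].crop.shape[:2] == (4, 4)

    def test_min_area_filters_small_components(self):
        mask = np.zeros((8, 8), bool)
        mask[1, 1:4] = True  # area 3
        f = _frame(np.zeros((8, 8)))
        assert find_elements(mask, f, 10) == []

    def test_detection_areas_bounded_by_mask(self):
        rng = np.random.default_rng(6)
        mask = rng.random((32, 32)) > 0.5
        f = _frame(np.zeros((32, 32)))
        dets = find_elements(mask, f, 1)
        assert sum(d.area for d in dets) <= mask.sum()


class TestDetectPipeline:
    def test_frame_equal_to_background_yields_nothing(self):
        px = np.full((96, 96), 80, np.uint8)
        f = _frame(px)
        bg = daily_background([f])
        assert detect_pipeline(f, bg) == []

    def test_saturated_threshold_yields_nothing(self, small_scene):
        _, frames, _ = small_scene
        bg = daily_background(frames)
        sp = SegmentConfig(threshold=255)
        assert detect_pipeline(frames[0], bg, segment_params=sp) == []

    def test_planted_objects_recovered(self, small_scene):
        spec, frames, records = small_scene
        bg = enhance_background(daily_background(frames))
        f = frames[0]
        truth = [r for r in records if r.image_id == f.image_id]
        dets = detect_pipeline(f, bg)
        matched = sum(
            1 for r in truth
            if max((box_iou(r.box, d.box) for d in dets), default=0.0) >= 0.3
        )
        assert matched >= len(truth) - 1  # all five planted objects, one slack
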