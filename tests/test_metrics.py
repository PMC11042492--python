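import math

import numpy as np
import pytest
from scipy import ndimage
from skimage.metrics import structural_similarity

import specreflow as sr
from specreflow.metrics import (
    aggregate_finite_mean,
    confusion_counts,
    detection_metrics,
    full_frame_metrics,
    mpsnr,
    mssim,
    sr_bounding_boxes,
)


def _random_mask(rng, shape=(32, 32), p=0.3):
    return rng.random(shape) < p


class TestDetectionMetrics:
    def test_perfect_prediction(self):
        m = np.zeros((8, 8), bool)
        m[2:5, 2:5] = True
        assert detection_metrics(m, m) == (1.0, 1.0, 1.0)

    def test_disjoint_masks(self):
        a = np.zeros((8, 8), bool); a[0, 0] = True
        b = np.zeros((8, 8), bool); b[7, 7] = True
        assert detection_metrics(a, b) == (0.0, 0.0, 0.0)

    def test_partial_overlap_counts(self):
        gt = np.zeros((8, 8), bool); gt[0, 0:4] = True
        pred = np.zeros((8, 8), bool); pred[0, 2:6] = True
        dice, iou, sens = detection_metrics(pred, gt)
        assert dice == pytest.approx(0.5)
        assert iou == pytest.approx(1 / 3)
        assert sens == pytest.approx(0.5)

    def test_empty_conventions(self):
        empty = np.zeros((4, 4), bool)
        some = np.zeros((4, 4), bool); some[0, 0] = True
        assert detection_metrics(empty, empty) == (1.0, 1.0, 1.0)
        dice, iou, sens = detection_metrics(some, empty)
        assert dice == 0.0 and iou == 0.0 and math.isnan(sens)

    def test_dice_iou_identity_on_random_masks(self, rng):
        """Dice = 2*IoU / (1 + IoU) algebraically, for 1000 random pairs."""
        for _ in range(1000):
            pred, gt = _random_mask(rng, (16, 16)), _random_mask(rng, (16, 16))
            dice, iou, _ = detection_metrics(pred, gt)
            assert dice == pytest.approx(2 * iou / (1 + iou), abs=1e-12)

    def test_confusion_counts_sum(self, rng):
        pred, gt = _random_mask(rng), _random_mask(rng)
        c = confusion_counts(pred, gt)
        assert c.total == pred.size


class TestMPSNR:
    def test_perfect_restoration_is_infinite(self, tissue_frame):
        mask = np.zeros(tissue_frame.shape[:2], bool)
        mask[10:20, 10:20] = True
        assert mpsnr(tissue_frame, tissue_frame.copy(), mask) == math.inf

    def test_closed_form_single_pixel(self):
        """Normalized frames, one masked pixel, per-channel error 0.1:
        mMSE = 0.01 so mPSNR = 20 dB."""
        orig = np.zeros((4, 4, 3)); rest = orig.copy()
        rest[1, 1] = 0.1
        mask = np.zeros((4, 4), bool); mask[1, 1] = True
        assert mpsnr(orig, rest, mask) == pytest.approx(20.0, abs=1e-12)

    def test_full_mask_reduces_to_psnr(self, rng):
        orig = rng.integers(0, 255, (32, 32, 3), dtype=np.uint8)
        rest = rng.integers(0, 255, (32, 32, 3), dtype=np.uint8)
        full = np.ones((32, 32), bool)
        psnr, _ = full_frame_metrics(orig, rest)
        assert mpsnr(orig, rest, full) == pytest.approx(psnr, abs=1e-9)

    def test_error_outside_mask_ignored(self, rng):
        orig = rng.integers(0, 255, (16, 16, 3), dtype=np.uint8)
        rest = orig.copy()
        mask = np.zeros((16, 16), bool); mask[2:4, 2:4] = True
        rest[10:14, 10:14] = 0  # error strictly off-mask
        assert mpsnr(orig, rest, mask) == math.inf

    def test_shrinking_error_never_decreases_mpsnr(self):
        orig = np.full((8, 8, 3), 100, dtype=np.uint8)
        mask = np.ones((8, 8), bool)
        prev = -math.inf
        for err in (32, 16, 8, 4):
            rest = orig.copy(); rest[mask] = 100 + err
            val = mpsnr(orig, rest, mask)
            assert val > prev
            prev = val

    def test_empty_mask_rejected(self, tissue_frame):
        with pytest.raises(ValueError):
            mpsnr(tissue_frame, tissue_frame, np.zeros(tissue_frame.shape[:2], bool))


class TestBoundingBoxes:
    def test_single_center_pixel_grows_to_8x8(self):
        mask = np.zeros((100, 100), bool)
        mask[50, 50] = True
        (box,) = sr_bounding_boxes(mask)
        assert box.height == 8 and box.width == 8
        assert box.row_min <= 50 < box.row_max
        assert box.col_min <= 50 < box.col_max
        assert box.sr_pixel_count == 1

    def test_large_component_unchanged(self):
        mask = np.zeros((64, 64), bool)
        mask[10:20, 10:22] = True  # 10 x 12
        (box,) = sr_bounding_boxes(mask)
        assert (box.row_min, box.row_max, box.col_min, box.col_max) == (10, 20, 10, 22)

    def test_border_clamping_pushes_deficit_inward(self):
        mask = np.zeros((64, 64), bool)
        mask[0, 0] = True
        (box,) = sr_bounding_boxes(mask)
        assert (box.row_min, box.col_min) == (0, 0)
        assert box.height == 8 and box.width == 8

    def test_components_match_labeling_oracle(self, rng):
        for _ in range(20):
            mask = _random_mask(rng, (40, 40), p=0.05)
            boxes = sr_bounding_boxes(mask)
            _, n = ndimage.label(mask, structure=np.ones((3, 3)))
            assert len(boxes) == n

    def test_empty_mask_gives_empty_list(self):
        assert sr_bounding_boxes(np.zeros((16, 16), bool)) == []


class TestMSSIM:
    def test_identical_frames_score_one(self, corrupted_frame_and_mask):
        frame, mask = corrupted_frame_and_mask
        assert mssim(frame, frame.copy(), mask) == pytest.approx(1.0, abs=1e-12)

    def test_single_region_equals_boxed_ssim(self, tissue_frame, rng):
        mask = np.zeros(tissue_frame.shape[:2], bool)
        mask[20:35, 25:45] = True
        rest = tissue_frame.copy()
        rest[22:30, 28:40] = rng.integers(0, 255, (8, 12, 3), dtype=np.uint8)
        (box,) = sr_bounding_boxes(mask)
        rs, cs = box.slices()
        ref = structural_similarity(
            tissue_frame[rs, cs], rest[rs, cs], win_size=7, data_range=255.0,
            gaussian_weights=False, channel_axis=-1,
        )
        assert mssim(tissue_frame, rest, mask) == pytest.approx(ref, abs=1e-12)

    def test_two_regions_weighted_average(self, tissue_frame, rng):
        """Two well-separated regions of 30 and 10 mask pixels combine as
        0.75*s1 + 0.25*s2."""
        mask = np.zeros(tissue_frame.shape[:2], bool)
        mask[5:10, 5:11] = True  # 30 px
        mask[40:45, 40:42] = True  # 10 px
        rest = tissue_frame.copy()
        rest[5:10, 5:11] = 255
        rest[40:45, 40:42] = 0
        boxes = sr_bounding_boxes(mask)
        scores = {}
        for box in boxes:
            rs, cs = box.slices()
            scores[box.sr_pixel_count] = structural_similarity(
                tissue_frame[rs, cs], rest[rs, cs], win_size=7, data_range=255.0,
                gaussian_weights=False, channel_axis=-1,
            )
        expected = 0.75 * scores[30] + 0.25 * scores[10]
        assert mssim(tissue_frame, rest, mask) == pytest.approx(expected, abs=1e-12)

    def test_weights_sum_to_one_with_overlapping_boxes(self, tissue_frame):
        # two single-pixel components 4 px apart: their 8x8 boxes overlap
        mask = np.zeros(tissue_frame.shape[:2], bool)
        mask[30, 30] = True
        mask[30, 34] = True
        val = mssim(tissue_frame, tissue_frame.copy(), mask)
        assert val == pytest.approx(1.0, abs=1e-12)

    def test_empty_mask_rejected(self, tissue_frame):
        with pytest.raises(ValueError):
            mssim(tissue_frame, tissue_frame, np.zeros(tissue_frame.shape[:2], bool))


class TestFullFrameMetrics:
    def test_identical_frames(self, tissue_frame):
        psnr, ssim = full_frame_metrics(tissue_frame, tissue_frame.copy())
        assert psnr == math.inf
        assert ssim == pytest.approx(1.0, abs=1e-12)

    def test_uniform_offset_closed_form(self):
        """Constant error of 16 on the 8-bit scale: 10*log10(255^2/256)."""
        a = np.full((32, 32, 3), 100, dtype=np.uint8)
        b = np.full((32, 32, 3), 116, dtype=np.uint8)
        psnr, _ = full_frame_metrics(a, b)
        assert psnr == pytest.approx(10 * math.log10(255**2 / 256), abs=1e-12)
        assert psnr == pytest.approx(24.0484, abs=5e-4)

    def test_ssim_bounded(self, rng):
        a = rng.integers(0, 255, (32, 32, 3), dtype=np.uint8)
        b = (255 - a).astype(np.uint8)  # anti-correlated
        _, ssim = full_frame_metrics(a, b)
        assert -1.0 <= ssim <= 1.0

    def test_dim_mismatch_rejected(self):
        with pytest.raises(ValueError):
            full_frame_metrics(np.zeros((8, 8, 3), np.uint8), np.zeros((8, 9, 3), np.uint8))


def test_aggregate_excludes_infinities():
    mean, n_inf = aggregate_finite_mean([10.0, math.inf, 20.0])
    assert mean == 15.0 and n_inf == 1
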