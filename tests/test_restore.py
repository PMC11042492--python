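import numpy as np
import pytest

import specreflow as sr
from specreflow.restore import (
    FlowField,
    RestorerSpec,
    complete_flow_in_mask,
    estimate_flow_pair,
    harmonic_fill,
    homography_replace_baseline,
    inpaint_residual,
    propagate_pixels,
    restore_sequence,
)


def _textured_frame(seed, shape=(64, 96)):
    cfg = sr.SceneConfig(height=shape[0], width=shape[1], n_frames=1,
                         motion_model="static", noise_sigma=0, seed=seed)
    return sr.generate_tissue_sequence(cfg)[0]


def _shifted_pair(seed, shift=3):
    cfg = sr.SceneConfig(height=64, width=96, n_frames=2,
                         motion_model="translation", motion_magnitude=shift,
                         noise_sigma=0, seed=seed)
    frames = sr.generate_tissue_sequence(cfg)
    return frames[0], frames[1]


class TestFlowEstimation:
    def test_identical_frames_give_zero_flow(self):
        frame = _textured_frame(0)
        flow = estimate_flow_pair(frame, frame)
        assert np.abs(flow.displacement).max() < 0.1

    def test_known_shift_recovered(self):
        """A 3 px horizontal pan: content at (r, c) in frame 0 sits at
        (r, c - 3) in frame 1, so the median flow should be (0, -3)."""
        a, b = _shifted_pair(1, shift=3)
        flow = estimate_flow_pair(a, b)
        interior = flow.displacement[10:-10, 10:-10]
        med = np.median(interior.reshape(-1, 2), axis=0)
        assert abs(med[0] - 0.0) < 0.5
        assert abs(med[1] - (-3.0)) < 0.5

    def test_exclusion_invalidates_pixels(self):
        frame = _textured_frame(2)
        full = np.ones(frame.shape[:2], bool)
        flow = estimate_flow_pair(frame, frame, exclude=full)
        assert not flow.valid.any()

    def test_dim_mismatch_rejected(self):
        with pytest.raises(ValueError):
            estimate_flow_pair(np.zeros((8, 8, 3), np.uint8), np.zeros((8, 9, 3), np.uint8))


class TestFlowCompletion:
    def test_constant_field_filled_with_constant(self):
        disp = np.full((32, 32, 2), 1.5)
        mask = np.zeros((32, 32), bool); mask[10:20, 10:20] = True
        flow = FlowField(disp.copy(), ~mask)
        out = complete_flow_in_mask(flow, mask)
        assert np.allclose(out.displacement, 1.5, atol=1e-9)
        assert out.valid.all()

    def test_linear_ramp_reproduced(self):
        """Harmonic interpolation reproduces an affine flow field exactly."""
        rows, cols = np.mgrid[0:32, 0:32].astype(float)
        disp = np.stack([0.1 * rows + 0.02 * cols, -0.05 * cols], axis=-1)
        mask = np.zeros((32, 32), bool); mask[8:22, 12:26] = True
        corrupted = disp.copy(); corrupted[mask] = 99.0
        out = complete_flow_in_mask(FlowField(corrupted, ~mask), mask)
        assert np.abs(out.displacement - disp).max() < 1e-3

    def test_empty_mask_is_identity(self):
        disp = np.random.default_rng(0).random((16, 16, 2))
        flow = FlowField(disp.copy(), np.ones((16, 16), bool))
        out = complete_flow_in_mask(flow, np.zeros((16, 16), bool))
        assert np.array_equal(out.displacement, disp)

    def test_full_mask_rejected(self):
        disp = np.zeros((8, 8, 2))
        with pytest.raises(ValueError):
            complete_flow_in_mask(FlowField(disp, np.zeros((8, 8), bool)),
                                  np.ones((8, 8), bool))


class TestPropagation:
    def _static_setup(self, n=4, masked_frame=1):
        frame = _textured_frame(3)
        frames = np.repeat(frame[None], n, axis=0)
        masks = np.zeros((n, *frame.shape[:2]), bool)
        masks[masked_frame, 20:30, 30:45] = True
        corrupted = frames.copy()
        corrupted[masked_frame][masks[masked_frame]] = 255
        h, w = frame.shape[:2]
        zero = lambda: FlowField(np.zeros((h, w, 2)), np.ones((h, w), bool))
        flows = [zero() for _ in range(n - 1)]
        return frames, corrupted, masks, flows

    def test_static_fill_is_exact_with_empty_residual(self):
        frames, corrupted, masks, flows = self._static_setup()
        out, residual = propagate_pixels(corrupted, masks, flows, flows)
        assert not residual.any()
        assert np.array_equal(out[1], frames[1])

    def test_everywhere_masked_pixel_lands_in_residual(self):
        frames, corrupted, masks, flows = self._static_setup()
        masks[:, 25, 35] = True  # same pixel masked in every frame
        out, residual = propagate_pixels(corrupted, masks, flows, flows)
        assert residual[:, 25, 35].all()
        assert (out[0, 25, 35] == corrupted[0, 25, 35]).all()

    def test_known_translation_fill_error_small(self):
        cfg = sr.SceneConfig(height=64, width=96, n_frames=5,
                             motion_model="translation", motion_magnitude=2,
                             noise_sigma=0, seed=8)
        clean = sr.generate_tissue_sequence(cfg)
        masks = np.zeros((5, 64, 96), bool)
        masks[2, 25:35, 40:60] = True
        corrupted = clean.copy(); corrupted[2][masks[2]] = 255
        out = restore_sequence(corrupted, masks, RestorerSpec("flow", "flow-propagation"))
        err = np.abs(out[2].astype(int) - clean[2].astype(int))[masks[2]]
        assert err.max() <= 2

    def test_length_mismatch_rejected(self):
        frames, corrupted, masks, flows = self._static_setup()
        with pytest.raises(ValueError):
            propagate_pixels(corrupted, masks, flows[:-1], flows)


class TestInpaint:
    def test_empty_residual_is_identity(self, tissue_frame):
        out = inpaint_residual(tissue_frame, np.zeros(tissue_frame.shape[:2], bool))
        assert np.array_equal(out, tissue_frame)

    def test_constant_frame_hole_filled_with_constant(self):
        frame = np.full((32, 32, 3), 80, dtype=np.uint8)
        hole = np.zeros((32, 32), bool); hole[10:20, 10:20] = True
        corrupted = frame.copy(); corrupted[hole] = 255
        out = inpaint_residual(corrupted, hole)
        assert (out == 80).all()

    def test_linear_gradient_reproduced(self):
        """A diffusion fill of a hole in a horizontal ramp matches the ramp."""
        ramp = np.tile(np.arange(64, dtype=np.uint8) * 3, (32, 1))
        frame = np.stack([ramp] * 3, axis=-1)
        hole = np.zeros((32, 64), bool); hole[12:20, 25:35] = True
        corrupted = frame.copy(); corrupted[hole] = 0
        out = inpaint_residual(corrupted, hole)
        assert np.abs(out.astype(int) - frame.astype(int))[hole].max() <= 2

    def test_full_frame_residual_rejected(self, tissue_frame):
        with pytest.raises(ValueError):
            inpaint_residual(tissue_frame, np.ones(tissue_frame.shape[:2], bool))


class TestRestoreSequence:
    def test_empty_masks_identity(self):
        frames = np.repeat(_textured_frame(5)[None], 3, axis=0)
        masks = np.zeros((3, *frames.shape[1:3]), bool)
        for kind in ("flow-propagation", "diffusion-inpaint", "identity"):
            out = restore_sequence(frames, masks, RestorerSpec("r", kind))
            assert np.array_equal(out, frames)

    def test_static_exact_recovery(self):
        """Every masked pixel visible in another frame of a static sequence
        is recovered exactly (the flow chain finds a perfect donor)."""
        frame = _textured_frame(6)
        clean = np.repeat(frame[None], 5, axis=0)
        masks = np.zeros((5, *frame.shape[:2]), bool)
        masks[1, 10:25, 20:40] = True
        masks[3, 30:45, 50:70] = True
        corrupted = clean.copy()
        for t in (1, 3):
            corrupted[t][masks[t]] = 255
        out = restore_sequence(corrupted, masks, RestorerSpec("flow", "flow-propagation"))
        assert np.array_equal(out, clean)
        assert sr.mssim(clean[1], out[1], masks[1]) == pytest.approx(1.0, abs=1e-6)

    def test_unmasked_pixels_bit_identical(self):
        frame = _textured_frame(7)
        frames = np.repeat(frame[None], 3, axis=0)
        masks = np.zeros((3, *frame.shape[:2]), bool)
        masks[1, 5:15, 5:15] = True
        corrupted = frames.copy(); corrupted[1][masks[1]] = 255
        for kind in ("flow-propagation", "diffusion-inpaint", "homography-replace"):
            out = restore_sequence(corrupted, masks, RestorerSpec("r", kind))
            assert (out[~masks] == corrupted[~masks]).all()

    def test_unknown_engine_rejected(self):
        with pytest.raises(ValueError):
            RestorerSpec("x", "magic")


class TestHomographyBaseline:
    def test_identical_frames_exact_recovery(self):
        frame = _textured_frame(9)
        clean = np.repeat(frame[None], 3, axis=0)
        masks = np.zeros((3, *frame.shape[:2]), bool)
        masks[1, 20:32, 30:50] = True
        corrupted = clean.copy(); corrupted[1][masks[1]] = 255
        out = homography_replace_baseline(corrupted, masks)
        assert np.array_equal(out[1], clean[1])

    def test_translation_recovered_within_tolerance(self):
        cfg = sr.SceneConfig(height=96, width=128, n_frames=4,
                             motion_model="translation", motion_magnitude=2,
                             noise_sigma=0, seed=10)
        clean = sr.generate_tissue_sequence(cfg)
        masks = np.zeros((4, 96, 128), bool)
        masks[1, 40:56, 60:84] = True
        corrupted = clean.copy(); corrupted[1][masks[1]] = 255
        out = homography_replace_baseline(corrupted, masks)
        err = np.abs(out[1].astype(int) - clean[1].astype(int))[masks[1]]
        assert err.max() <= 2

    def test_brightness_step_copied_verbatim_unlike_flow_engine(self):
        """When the donor frame is globally brighter, direct replacement
        leaves a bright patch (error near the step size); that is the
        failure mode the flow engine is meant to avoid on real footage."""
        frame = _textured_frame(11, shape=(96, 128))
        step = 40
        bright = np.clip(frame.astype(int) + step, 0, 255).astype(np.uint8)
        clean = np.stack([frame, frame, bright])
        masks = np.zeros((3, 96, 128), bool)
        masks[0, 40:56, 60:84] = True
        masks[1, 40:56, 60:84] = True  # same region hidden in both dark frames
        corrupted = clean.copy()
        for t in (0, 1):
            corrupted[t][masks[t]] = 255
        out = homography_replace_baseline(corrupted, masks, max_search=2)
        fill_err = (out[0].astype(int) - clean[0].astype(int))[masks[0]].mean()
        assert fill_err > step / 2  # donor brightness retained

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            homography_replace_baseline(np.zeros((1, 64, 64, 3), np.uint8),
                                        np.zeros((1, 64, 64), bool))


def test_temporal_consistency_flow_vs_homography():
    """On a static corrupted sequence the flow engine's restored pixels vary
    (strictly: vary no more) across frames than the homography baseline's."""
    cfg = sr.SceneConfig(height=64, width=96, n_frames=5, motion_model="static",
                         noise_sigma=0, seed=12)
    clean = sr.generate_tissue_sequence(cfg)
    rng = np.random.default_rng(0)
    masks = np.zeros((5, 64, 96), bool)
    for t in range(1, 4):
        r, c = rng.integers(10, 40), rng.integers(10, 70)
        masks[t, r : r + 12, c : c + 14] = True
    corrupted = clean.copy()
    corrupted[masks] = 255
    region = masks.any(axis=0)
    flow_out = restore_sequence(corrupted, masks, RestorerSpec("f", "flow-propagation"))
    homo_out = restore_sequence(corrupted, masks, RestorerSpec("h", "homography-replace"))
    var_flow = flow_out[:, region].astype(float).var(axis=0).mean()
    var_homo = homo_out[:, region].astype(float).var(axis=0).mean()
    assert var_flow <= var_homo


def test_harmonic_fill_reproduces_plane():
    rows, cols = np.mgrid[0:24, 0:24].astype(float)
    plane = 3.0 + 0.5 * rows - 0.25 * cols
    mask = np.zeros((24, 24), bool); mask[6:18, 6:18] = True
    corrupted = plane.copy(); corrupted[mask] = -50
    out = harmonic_fill(corrupted, mask)
    assert np.abs(out - plane).max() < 1e-6
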