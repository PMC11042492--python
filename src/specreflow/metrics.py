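"""Detection and restoration quality metrics.

Detection masks are scored with the usual pixel-overlap measures (Dice,
IoU/Jaccard, sensitivity).  Restorations are scored with two masked-region
variants of the standard full-frame measures:

mPSNR
    PSNR whose mean-squared error runs only over highlight pixels: the
    per-pixel squared error is gated by a binary weight (1 on mask, 0 off)
    and averaged over the ``S`` mask pixels and ``C`` channels,

        mMSE = (1/C)(1/S) * sum_c sum_ij (I - K)^2 * w,
        mPSNR = 10 * log10(MAX^2 / mMSE).

    With a full-frame mask this reduces exactly to ordinary PSNR.

mSSIM
    SSIM evaluated per connected highlight region: each region's bounding
    box is grown symmetrically to at least 8 px per side (so a 7x7 sliding
    window fits), SSIM is computed on the boxed crops, and the box scores
    are averaged with weights proportional to the number of mask pixels in
    each box.

Both masked metrics are undefined for an empty mask and raise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage.metrics import structural_similarity

__all__ = [
    "ConfusionCounts",
    "SRBoundingBox",
    "confusion_counts",
    "detection_metrics",
    "full_frame_metrics",
    "mpsnr",
    "mssim",
    "sr_bounding_boxes",
]


# ---------------------------------------------------------------------------
# detection metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _as_bool(mask: np.ndarray) -> np.ndarray:
    m = np.asarray(mask)
    if m.dtype == bool:
        return m
    return m > 0


def confusion_counts(pred: np.ndarray, gt: np.ndarray) -> ConfusionCounts:
    """Pixelwise confusion counts between a predicted and a reference mask."""
    p, g = _as_bool(pred), _as_bool(gt)
    if p.shape != g.shape:
        raise ValueError(f"mask shape mismatch: {p.shape} vs {g.shape}")
    tp = int(np.count_nonzero(p & g))
    fp = int(np.count_nonzero(p & ~g))
    fn = int(np.count_nonzero(~p & g))
    tn = int(np.count_nonzero(~p & ~g))
    return ConfusionCounts(tp, fp, fn, tn)


def detection_metrics(pred: np.ndarray, gt: np.ndarray) -> tuple[float, float, float]:
    """Dice, IoU and sensitivity of ``pred`` against ``gt``.

    Conventions for empty denominators: if both masks are empty the overlap
    is perfect (dice = iou = sensitivity = 1); if only the reference is
    empty, sensitivity is undefined and reported as NaN.
    """
    c = confusion_counts(pred, gt)
    if c.tp + c.fp + c.fn == 0:
        return 1.0, 1.0, 1.0
    dice = 2.0 * c.tp / (2.0 * c.tp + c.fp + c.fn)
    iou = c.tp / (c.tp + c.fp + c.fn)
    sensitivity = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else math.nan
    return dice, iou, sensitivity


# ---------------------------------------------------------------------------
# masked PSNR
# ---------------------------------------------------------------------------

def _max_intensity(frame: np.ndarray, max_val: Optional[float]) -> float:
    if max_val is not None:
        return float(max_val)
    return 255.0 if frame.dtype == np.uint8 else 1.0


def _check_pair(original: np.ndarray, restored: np.ndarray) -> None:
    if original.shape != restored.shape:
        raise ValueError(
            f"frame shape mismatch: {original.shape} vs {restored.shape}"
        )


def mpsnr(
    original: np.ndarray,
    restored: np.ndarray,
    mask: np.ndarray,
    max_val: Optional[float] = None,
) -> float:
    """Masked PSNR in decibels; ``math.inf`` for a perfect restoration.

    The squared error is averaged only over the ``S`` mask pixels (and the
    color channels), so pixels outside the highlight mask contribute
    nothing.  ``max_val`` defaults to 255 for uint8 input and 1.0 otherwise.
    """
    _check_pair(original, restored)
    m = _as_bool(mask)
    if m.shape != original.shape[:2]:
        raise ValueError(f"mask shape {m.shape} does not match frame {original.shape[:2]}")
    s = int(np.count_nonzero(m))
    if s == 0:
        raise ValueError("mPSNR is undefined for an empty mask")
    max_i = _max_intensity(original, max_val)
    diff = original.astype(np.float64) - restored.astype(np.float64)
    if diff.ndim == 2:
        diff = diff[:, :, None]
    n_channels = diff.shape[2]
    sq = (diff ** 2) * m[:, :, None]
    mmse = sq.sum() / (n_channels * s)
    if mmse == 0.0:
        return math.inf
    return 10.0 * math.log10(max_i ** 2 / mmse)


# ---------------------------------------------------------------------------
# bounding boxes and masked SSIM
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SRBoundingBox:
    """Half-open, 0-based bounding box of one highlight region."""

    row_min: int
    row_max: int
    col_min: int
    col_max: int
    sr_pixel_count: int

    @property
    def height(self) -> int:
        return self.row_max - self.row_min

    @property
    def width(self) -> int:
        return self.col_max - self.col_min

    def slices(self) -> tuple[slice, slice]:
        return slice(self.row_min, self.row_max), slice(self.col_min, self.col_max)


def _grow_interval(lo: int, hi: int, min_size: int, limit: int) -> tuple[int, int]:
    """Grow [lo, hi) symmetrically to at least ``min_size``, clamped to [0, limit).

    A deficit created by clamping at one border is pushed to the opposite
    side; if the image itself is smaller than ``min_size`` the interval is
    the whole axis.
    """
    need = min_size - (hi - lo)
    if need > 0:
        lo -= need // 2
        hi += need - need // 2
    if lo < 0:
        hi += -lo
        lo = 0
    if hi > limit:
        lo -= hi - limit
        hi = limit
    lo = max(lo, 0)
    return lo, hi


def sr_bounding_boxes(
    mask: np.ndarray,
    min_size: int = 8,
    connectivity: int = 2,
) -> list[SRBoundingBox]:
    """One grown bounding box per connected highlight region.

    ``connectivity=2`` (8-connected) is the default; ``1`` selects
    4-connectivity.  Each box side is expanded symmetrically to at least
    ``min_size`` pixels and clamped inside the image.  ``sr_pixel_count``
    is the number of mask pixels inside the final (expanded) box.
    """
    m = _as_bool(mask)
    if m.ndim != 2:
        raise ValueError("mask must be 2-D")
    structure = ndimage.generate_binary_structure(2, connectivity)
    labels, n = ndimage.label(m, structure=structure)
    boxes: list[SRBoundingBox] = []
    for sl in ndimage.find_objects(labels):
        if sl is None:
            continue
        r0, r1 = _grow_interval(sl[0].start, sl[0].stop, min_size, m.shape[0])
        c0, c1 = _grow_interval(sl[1].start, sl[1].stop, min_size, m.shape[1])
        count = int(np.count_nonzero(m[r0:r1, c0:c1]))
        boxes.append(SRBoundingBox(r0, r1, c0, c1, count))
    return boxes


def _boxed_ssim(
    original: np.ndarray,
    restored: np.ndarray,
    win_size: int,
    max_i: float,
) -> float:
    kwargs = dict(win_size=win_size, data_range=max_i, gaussian_weights=False)
    if original.ndim == 3:
        kwargs["channel_axis"] = -1
    return float(structural_similarity(original, restored, **kwargs))


def mssim(
    original: np.ndarray,
    restored: np.ndarray,
    mask: np.ndarray,
    min_size: int = 8,
    win_size: int = 7,
    max_val: Optional[float] = None,
    connectivity: int = 2,
) -> float:
    """Highlight-region SSIM: SSIM per expanded bounding box, weighted by
    the mask pixel count of each box (weights normalized to sum to one)."""
    _check_pair(original, restored)
    m = _as_bool(mask)
    boxes = sr_bounding_boxes(m, min_size=min_size, connectivity=connectivity)
    if not boxes:
        raise ValueError("mSSIM is undefined for an empty mask")
    max_i = _max_intensity(original, max_val)
    scores = np.empty(len(boxes))
    weights = np.empty(len(boxes))
    for k, box in enumerate(boxes):
        rs, cs = box.slices()
        scores[k] = _boxed_ssim(original[rs, cs], restored[rs, cs], win_size, max_i)
        weights[k] = box.sr_pixel_count
    weights = weights / weights.sum()
    return float(np.dot(weights, scores))


# ---------------------------------------------------------------------------
# full-frame metrics
# ---------------------------------------------------------------------------

def full_frame_metrics(
    original: np.ndarray,
    restored: np.ndarray,
    win_size: int = 7,
    max_val: Optional[float] = None,
) -> tuple[float, float]:
    """Standard whole-frame (PSNR, SSIM) with a uniform 7x7 SSIM window."""
    _check_pair(original, restored)
    max_i = _max_intensity(original, max_val)
    diff = original.astype(np.float64) - restored.astype(np.float64)
    mse = float(np.mean(diff ** 2))
    psnr = math.inf if mse == 0.0 else 10.0 * math.log10(max_i ** 2 / mse)
    ssim = _boxed_ssim(original, restored, win_size, max_i)
    return psnr, ssim


def aggregate_finite_mean(values: Sequence[float]) -> tuple[float, int]:
    """Mean over finite entries, plus the number of non-finite ones excluded.

    Perfect restorations yield infinite mPSNR; averaging them with finite
    scores would be degenerate, so they are excluded and counted.
    """
    arr = np.asarray(values, dtype=np.float64)
    finite = arr[np.isfinite(arr)]
    n_excluded = int(arr.size - finite.size)
    mean = float(finite.mean()) if finite.size else math.nan
    return mean, n_excluded
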