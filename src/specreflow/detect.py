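"""Stage 2 — hybrid specular-highlight detection.

Two complementary detectors are fused:

* the Light U-net (:mod:`specreflow.unet`), which excels at small,
  scattered highlights;
* strict value-channel thresholding (``V > 194`` by default), which
  reliably captures large saturated regions that compact networks miss.

Both run on the saturation-enhanced frame (stage 1); their masks are
combined by pixelwise union — each detector contributes the regions the
other is blind to — and the fused mask is dilated once with a 5x5
elliptical structuring element so the slightly-degraded rim around each
highlight is also scheduled for restoration.  The undilated variant is
available by toggling ``dilate`` off.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from .preprocess import enhance_frame
from .unet import LightUNet, predict_unet_mask

__all__ = [
    "DetectionConfig",
    "threshold_mask",
    "combine_masks",
    "elliptical_footprint",
    "dilate_mask",
    "detect_frame",
    "detect_sequence",
]


@dataclass(frozen=True)
class DetectionConfig:
    """Knobs of the detection stage.

    ``threshold`` is applied strictly (``V > threshold``) to the HSV value
    channel; ``prob_cutoff`` binarizes the U-net probability map;
    ``apply_enhancement`` runs stage 1 first; ``dilate`` applies the final
    elliptical dilation (kernel side must be odd).
    """

    threshold: int = 194
    prob_cutoff: float = 0.5
    apply_enhancement: bool = True
    dilate: bool = True
    dilation_kernel_size: int = 5

    def __post_init__(self) -> None:
        if not (0 <= self.threshold <= 255):
            raise ValueError("threshold must lie in [0, 255]")
        if not (0.0 <= self.prob_cutoff <= 1.0):
            raise ValueError("prob_cutoff must lie in [0, 1]")
        if self.dilation_kernel_size % 2 == 0:
            raise ValueError("dilation kernel must be odd-sized")


def threshold_mask(frame: np.ndarray, threshold: int = 194) -> np.ndarray:
    """Pixels whose HSV value channel strictly exceeds ``threshold``.

    For RGB input the value channel is the per-pixel channel maximum.
    """
    if not (0 <= threshold <= 255):
        raise ValueError("threshold must lie in [0, 255]")
    frame = np.asarray(frame)
    value = frame.max(axis=2) if frame.ndim == 3 else frame
    return value > threshold


def combine_masks(unet_mask: np.ndarray, thresh_mask: np.ndarray) -> np.ndarray:
    """Pixelwise union of the two detector masks."""
    a = np.asarray(unet_mask).astype(bool)
    b = np.asarray(thresh_mask).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shape mismatch: {a.shape} vs {b.shape}")
    return a | b


def elliptical_footprint(size: int = 5) -> np.ndarray:
    """Odd-sized elliptical (here circular) structuring element.

    A pixel belongs to the footprint when its center lies within the
    ellipse inscribed in the ``size x size`` square, i.e.
    ``(r/a)^2 + (c/a)^2 <= 1`` with ``a = size // 2``.
    """
    if size % 2 == 0 or size < 1:
        raise ValueError("structuring element must be odd-sized and positive")
    a = size // 2
    if a == 0:
        return np.ones((1, 1), dtype=bool)
    r = np.arange(-a, a + 1)
    return (r[:, None] ** 2 + r[None, :] ** 2) <= a ** 2 + 1e-9


def dilate_mask(mask: np.ndarray, footprint: Optional[np.ndarray] = None) -> np.ndarray:
    """Morphological dilation; output is always a superset of the input."""
    m = np.asarray(mask).astype(bool)
    if footprint is None:
        footprint = elliptical_footprint(5)
    footprint = np.asarray(footprint).astype(bool)
    if any(s % 2 == 0 for s in footprint.shape):
        raise ValueError("structuring element must be odd-sized")
    return ndimage.binary_dilation(m, structure=footprint)


def detect_frame(
    model: Optional[LightUNet],
    frame: np.ndarray,
    config: DetectionConfig = DetectionConfig(),
) -> np.ndarray:
    """Full detection stage for one frame.

    enhancement (optional) -> U-net mask  union  threshold mask ->
    elliptical dilation (optional).  ``model=None`` gives the
    threshold-only detector (useful before training, and as a guaranteed
    floor: synthetic highlight cores always exceed the threshold).
    """
    work = enhance_frame(frame) if config.apply_enhancement else frame
    tmask = threshold_mask(work, config.threshold)
    if model is not None:
        umask = predict_unet_mask(model, work, config.prob_cutoff)
        mask = combine_masks(umask, tmask)
    else:
        mask = tmask
    if config.dilate:
        mask = dilate_mask(mask, elliptical_footprint(config.dilation_kernel_size))
    return mask


def detect_sequence(
    model: Optional[LightUNet],
    frames: np.ndarray,
    config: DetectionConfig = DetectionConfig(),
) -> np.ndarray:
    """Apply :func:`detect_frame` to every frame; returns ``(T, H, W)`` bool."""
    return np.stack([detect_frame(model, f, config) for f in frames])
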