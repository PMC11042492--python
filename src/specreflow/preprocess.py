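"""Stage 1 — saturation-based contrast enhancement.

Each RGB channel is multiplied pointwise by ``1 - S``, where ``S`` is the
HSV saturation plane of the frame.  Chromatic (tissue-colored) pixels have
high saturation and are darkened; achromatic pixels — in particular the
blown-out white cores of specular reflections — have ``S == 0`` and are
left untouched.  The net effect is a wider gap in the value-channel
histogram between highlights and everything else, which makes the
downstream thresholding detector far more selective.

HSV convention: ``S = (max - min) / max`` with ``S = 0`` when the maximum
channel is zero (the convention used by every mainstream imaging library).
The float product is rounded half-away-from-zero back to 8 bits so results
are bit-reproducible.
"""

from __future__ import annotations

import numpy as np

__all__ = ["enhance_frame", "saturation_plane"]


def _require_rgb(frame: np.ndarray) -> None:
    if frame.ndim != 3 or frame.shape[2] != 3:
        raise ValueError(f"expected an RGB frame of shape (H, W, 3), got {frame.shape}")


def saturation_plane(frame: np.ndarray) -> np.ndarray:
    """HSV saturation of an 8-bit RGB frame as float in [0, 1].

    ``S = (max - min) / max`` per pixel; pixels with ``max == 0`` (pure
    black) get ``S = 0``.
    """
    _require_rgb(frame)
    f = frame.astype(np.float64)
    cmax = f.max(axis=2)
    cmin = f.min(axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(cmax > 0, (cmax - cmin) / np.maximum(cmax, 1e-300), 0.0)
    return s


def enhance_frame(frame: np.ndarray) -> np.ndarray:
    """Multiply each RGB channel by ``1 - S`` and round back to uint8.

    Parameters
    ----------
    frame:
        8-bit RGB image, shape ``(H, W, 3)``.

    Returns
    -------
    numpy.ndarray
        Enhanced uint8 frame of the same shape.  Channelwise the output
        never exceeds the input (``1 - S`` lies in [0, 1]); equality holds
        exactly on achromatic pixels.
    """
    _require_rgb(frame)
    if frame.dtype != np.uint8:
        raise ValueError(f"expected uint8 pixels, got dtype {frame.dtype}")
    inv_s = 1.0 - saturation_plane(frame)
    product = frame.astype(np.float64) * inv_s[:, :, None]
    # values are non-negative, so floor(x + 0.5) == round half away from zero
    return np.floor(product + 0.5).astype(np.uint8)
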