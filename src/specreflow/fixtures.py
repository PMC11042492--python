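"""Synthetic endoscopy-like fixtures.

Real specular-reflection (SR) benchmarks are built from surgical video that
cannot ship with a library, so every other module here is exercised on
generated data that reproduces the features the pipeline actually depends
on:

* smooth, tissue-colored backgrounds with low-frequency shading and enough
  mid-frequency texture for optical flow and keypoint matching to latch on;
* dark curvilinear vessel-like structures (random cubic Bezier curves,
  darkened by 30-50%), whose recovery by the restoration stage is visually
  and numerically checkable;
* saturated achromatic SR cores (value channel raised to a configurable
  level above the detection threshold) surrounded by a halo of raised value
  and reduced saturation;
* inter-frame camera motion: static, constant-velocity translation, or a
  slowly drifting projective (homography) warp.

Frames are 8-bit RGB arrays ``(H, W, 3)``; sequences are ``(T, H, W, 3)``
arrays; masks are boolean ``(H, W)`` (written to disk as 0/255 PNG).  Every
generator is a pure function of its config and seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage.transform import ProjectiveTransform, resize, warp

__all__ = [
    "SceneConfig",
    "SRArtifactConfig",
    "MaskLibrary",
    "generate_tissue_sequence",
    "synthesize_sr_artifacts",
    "generate_mask_library",
    "sample_overlay_masks",
    "augment_training_pairs",
    "paint_sr",
    "train_val_test_split",
]

#: radius ranges (pixels) for the three SR morphology classes
SIZE_CLASS_RADII = {"small": (2.0, 4.0), "medium": (5.0, 9.0), "large": (10.0, 16.0)}


class GenerationError(RuntimeError):
    """Raised when a fixture request cannot be satisfied."""


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of a synthetic tissue sequence.

    ``motion_magnitude`` is the camera displacement per frame in pixels;
    translation is a pure horizontal pan, homography adds a slow projective
    drift on top of the pan.  ``vessel_density`` is the number of vessel
    curves drawn on the (panoramic) background canvas.
    """

    height: int = 96
    width: int = 128
    n_frames: int = 100
    motion_model: str = "translation"  # static | translation | homography
    motion_magnitude: float = 1.0
    vessel_density: int = 8
    base_color: tuple[int, int, int] = (168, 82, 72)
    noise_sigma: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 64 or self.width < 64:
            raise GenerationError("frame dimensions must be at least 64x64")
        if self.n_frames < 1:
            raise GenerationError("need at least one frame")
        if self.noise_sigma < 0:
            raise GenerationError("noise_sigma must be non-negative")
        if self.motion_model not in ("static", "translation", "homography"):
            raise GenerationError(f"unknown motion model {self.motion_model!r}")


@dataclass(frozen=True)
class SRArtifactConfig:
    """Parameters of synthetic specular highlights.

    ``core_intensity`` is the value-channel level of the saturated core; it
    must stay above 195 so synthetic cores always exceed the detection
    threshold (strict ``> 194``).  The halo raises the value channel and
    drops saturation over ``halo_width`` pixels around each core.
    """

    n_regions: int = 3
    size_classes: tuple[str, ...] = ("small", "medium", "large")
    core_intensity: int = 255
    halo_width: int = 3
    halo_saturation_drop: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (195 <= self.core_intensity <= 255):
            raise GenerationError("core_intensity must lie in [195, 255]")
        if self.halo_width < 0:
            raise GenerationError("halo_width must be non-negative")
        if self.n_regions < 0:
            raise GenerationError("n_regions must be non-negative")
        for cls in self.size_classes:
            if cls not in SIZE_CLASS_RADII:
                raise GenerationError(f"unknown size class {cls!r}")


@dataclass
class MaskLibrary:
    """A pool of binary SR masks sharing one source resolution."""

    masks: list[np.ndarray]
    source_size: tuple[int, int]

    def __post_init__(self) -> None:
        if not self.masks:
            raise GenerationError("mask library must be non-empty")
        for m in self.masks:
            if m.shape != self.source_size:
                raise GenerationError(
                    f"mask of shape {m.shape} does not match library size {self.source_size}"
                )

    def __len__(self) -> int:
        return len(self.masks)


# ---------------------------------------------------------------------------
# background canvas
# ---------------------------------------------------------------------------

def _bezier_points(ctrl: np.ndarray, n: int) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n)[:, None]
    b = (
        (1 - t) ** 3 * ctrl[0]
        + 3 * (1 - t) ** 2 * t * ctrl[1]
        + 3 * (1 - t) * t ** 2 * ctrl[2]
        + t ** 3 * ctrl[3]
    )
    return b


def _draw_vessels(canvas: np.ndarray, n_vessels: int, rng: np.random.Generator) -> None:
    """Darken random cubic Bezier curves in-place by 30-50%."""
    h, w = canvas.shape[:2]
    for _ in range(n_vessels):
        ctrl = np.column_stack(
            [rng.uniform(0, h, size=4), rng.uniform(0, w, size=4)]
        )
        pts = _bezier_points(ctrl, max(200, 2 * (h + w)))
        thickness = rng.integers(1, 3)
        darken = rng.uniform(0.30, 0.50)
        vessel = np.zeros((h, w), dtype=bool)
        rr = np.clip(np.round(pts[:, 0]).astype(int), 0, h - 1)
        cc = np.clip(np.round(pts[:, 1]).astype(int), 0, w - 1)
        vessel[rr, cc] = True
        if thickness > 1:
            vessel = ndimage.binary_dilation(vessel, iterations=int(thickness) - 1)
        # soften the edge so the vessel has a sub-pixel gradient for flow
        profile = ndimage.gaussian_filter(vessel.astype(np.float64), 0.7)
        profile /= max(profile.max(), 1e-12)
        canvas *= (1.0 - darken * profile)[:, :, None]


def _make_canvas(config: SceneConfig, rng: np.random.Generator,
                 extra_cols: int, extra_rows: int) -> np.ndarray:
    """Panoramic float canvas the moving camera window slides over."""
    h = config.height + extra_rows
    w = config.width + extra_cols
    low = ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma=14.0)
    mid = ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma=2.5)
    low /= max(np.abs(low).max(), 1e-12)
    mid /= max(np.abs(mid).max(), 1e-12)
    shading = 1.0 + 0.22 * low + 0.10 * mid
    canvas = np.asarray(config.base_color, dtype=np.float64)[None, None, :] * shading[:, :, None]
    # slight per-channel variation keeps the tissue chromatic, never gray
    chroma = ndimage.gaussian_filter(rng.standard_normal((h, w, 3)), sigma=(6.0, 6.0, 0))
    chroma /= max(np.abs(chroma).max(), 1e-12)
    canvas *= 1.0 + 0.06 * chroma
    _draw_vessels(canvas, config.vessel_density, rng)
    return np.clip(canvas, 0.0, 235.0)


def generate_tissue_sequence(config: SceneConfig) -> np.ndarray:
    """Generate a synthetic clean tissue sequence, shape ``(T, H, W, 3)`` uint8.

    Translation pans the camera window horizontally by
    ``round(t * motion_magnitude)`` pixels at frame ``t``, so consecutive
    frames are exact integer shifts of one another (before sensor noise)
    whenever the magnitude is an integer.  Homography composes the pan with
    a slowly accumulating projective distortion.  Deterministic per seed.
    """
    rng = np.random.default_rng(config.seed)
    t_idx = np.arange(config.n_frames)
    if config.motion_model == "static":
        offsets = np.zeros(config.n_frames, dtype=int)
    else:
        offsets = np.round(t_idx * config.motion_magnitude).astype(int)
    extra_cols = int(offsets.max()) if config.n_frames > 1 else 0
    canvas = _make_canvas(config, rng, extra_cols=extra_cols, extra_rows=0)

    if config.motion_model == "homography":
        # fixed small distortion direction; accumulates linearly with t
        drift = rng.uniform(-1.0, 1.0, size=(3, 3))
        drift[2, 2] = 0.0
        drift *= np.array(
            [
                [3e-4, 3e-4, 0.0],
                [3e-4, 3e-4, 0.05],
                [3e-6, 3e-6, 0.0],
            ]
        ) * config.motion_magnitude

    frames = np.empty((config.n_frames, config.height, config.width, 3), dtype=np.uint8)
    noise_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
    for t in range(config.n_frames):
        off = offsets[t]
        if config.motion_model == "homography":
            # skimage transforms act on (x=col, y=row); the pan goes on x
            matrix = np.eye(3) + t * drift
            matrix[0, 2] += off
            tform = ProjectiveTransform(matrix=matrix)
            view = warp(canvas, tform, output_shape=(config.height, config.width),
                        order=1, mode="reflect", preserve_range=True)
        else:
            view = canvas[: config.height, off : off + config.width]
        frame = view.copy()
        if config.noise_sigma > 0:
            frame = frame + noise_rng.normal(0.0, config.noise_sigma, size=frame.shape)
        frames[t] = np.clip(np.round(frame), 0, 255).astype(np.uint8)
    return frames


# ---------------------------------------------------------------------------
# SR artifacts
# ---------------------------------------------------------------------------

def _blob_mask(shape: tuple[int, int], center: tuple[float, float],
               radius: float, rng: np.random.Generator) -> np.ndarray:
    """Irregular elliptical blob: an ellipse whose radius wobbles with angle."""
    h, w = shape
    aspect = rng.uniform(0.6, 1.0)
    theta0 = rng.uniform(0, np.pi)
    amp = rng.uniform(0.0, 0.25, size=3)
    phase = rng.uniform(0, 2 * np.pi, size=3)

    r0 = int(np.ceil(radius / aspect)) + 2
    rr = np.arange(max(0, int(center[0]) - r0), min(h, int(center[0]) + r0 + 1))
    cc = np.arange(max(0, int(center[1]) - r0), min(w, int(center[1]) + r0 + 1))
    if rr.size == 0 or cc.size == 0:
        return np.zeros(shape, dtype=bool)
    dy = rr[:, None] - center[0]
    dx = cc[None, :] - center[1]
    # rotate into the ellipse frame
    u = np.cos(theta0) * dy + np.sin(theta0) * dx
    v = -np.sin(theta0) * dy + np.cos(theta0) * dx
    rad = np.sqrt((u / 1.0) ** 2 + (v / aspect) ** 2)
    ang = np.arctan2(v, u)
    wobble = 1.0 + sum(a * np.sin((k + 2) * ang + p) for k, (a, p) in enumerate(zip(amp, phase)))
    local = rad <= radius * wobble
    mask = np.zeros(shape, dtype=bool)
    mask[np.ix_(rr, cc)] = local
    return mask


def paint_sr(
    frame: np.ndarray,
    core_mask: np.ndarray,
    core_intensity: int = 255,
    halo_width: int = 3,
    halo_saturation_drop: float = 0.5,
) -> np.ndarray:
    """Overlay a specular highlight given its core mask.

    Core pixels become achromatic at ``core_intensity`` in every channel
    (so their HSV value channel equals ``core_intensity`` exactly).  A halo
    of width ``halo_width`` blends each surrounding pixel toward the core
    color, raising its value and lowering its saturation with distance.
    """
    out = frame.astype(np.float64).copy()
    core = core_mask.astype(bool)
    if halo_width > 0 and core.any():
        dist = ndimage.distance_transform_edt(~core)
        ring = (dist > 0) & (dist <= halo_width)
        blend = np.zeros_like(dist)
        blend[ring] = halo_saturation_drop * (1.0 - (dist[ring] - 1.0) / halo_width)
        out += blend[:, :, None] * (float(core_intensity) - out)
    out[core] = float(core_intensity)
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def synthesize_sr_artifacts(
    frames: np.ndarray, config: SRArtifactConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Overlay random specular highlights on every frame.

    Returns ``(corrupted_frames, core_masks)``; the ground-truth mask marks
    core pixels only (the halo is degraded-but-informative, like the
    high-saturation rims around real highlights).  Blob placement is
    re-drawn per frame, so masks vary frame to frame.  Deterministic per
    config seed.
    """
    if len(frames) == 0:
        raise GenerationError("empty frame sequence")
    t_count, h, w = frames.shape[:3]
    mean_area = (
        np.mean([np.pi * np.mean(SIZE_CLASS_RADII[c]) ** 2 for c in config.size_classes])
        if config.size_classes else 0.0
    )
    if config.n_regions * mean_area > 0.6 * h * w:
        raise GenerationError(
            f"{config.n_regions} regions of class {config.size_classes} exceed frame capacity"
        )
    out = frames.copy()
    masks = np.zeros((t_count, h, w), dtype=bool)
    seeds = np.random.SeedSequence(config.seed).spawn(t_count)
    for t in range(t_count):
        rng = np.random.default_rng(seeds[t])
        core = np.zeros((h, w), dtype=bool)
        for _ in range(config.n_regions):
            cls = config.size_classes[rng.integers(len(config.size_classes))]
            lo, hi = SIZE_CLASS_RADII[cls]
            radius = rng.uniform(lo, hi)
            margin = radius + config.halo_width + 2
            center = (rng.uniform(margin, h - margin), rng.uniform(margin, w - margin))
            core |= _blob_mask((h, w), center, radius, rng)
        if config.n_regions > 0:
            out[t] = paint_sr(
                frames[t], core, config.core_intensity,
                config.halo_width, config.halo_saturation_drop,
            )
        masks[t] = core
    return out, masks


# ---------------------------------------------------------------------------
# mask library
# ---------------------------------------------------------------------------

def generate_mask_library(
    n_masks: int = 200,
    source_size: tuple[int, int] = (288, 384),
    seed: int = 0,
) -> MaskLibrary:
    """A library of random SR-shaped binary masks (1-4 blobs each)."""
    if n_masks < 1:
        raise GenerationError("n_masks must be positive")
    rng = np.random.default_rng(seed)
    h, w = source_size
    masks = []
    classes = tuple(SIZE_CLASS_RADII)
    for _ in range(n_masks):
        mask = np.zeros(source_size, dtype=bool)
        for _ in range(rng.integers(1, 5)):
            cls = classes[rng.integers(len(classes))]
            lo, hi = SIZE_CLASS_RADII[cls]
            radius = rng.uniform(lo, hi) * min(h, w) / 96.0  # scale to library resolution
            margin = radius + 2
            center = (rng.uniform(margin, h - margin), rng.uniform(margin, w - margin))
            mask |= _blob_mask(source_size, center, radius, rng)
        masks.append(mask)
    return MaskLibrary(masks=masks, source_size=source_size)


def sample_overlay_masks(
    library: MaskLibrary,
    n: int,
    target_size: tuple[int, int],
    seed: int,
    exclude: Optional[np.ndarray] = None,
) -> list[np.ndarray]:
    """Draw ``n`` masks without replacement and resize them to ``target_size``.

    Resizing is nearest-neighbor so masks stay strictly binary.  If an
    ``exclude`` mask (at target size) is supplied — e.g. pre-existing SR in
    the underlying frame — overlapping pixels are clipped out of the
    sampled masks.
    """
    if len(library) == 0:
        raise GenerationError("empty mask library")
    if n > len(library):
        raise GenerationError(
            f"cannot sample {n} masks without replacement from a library of {len(library)}"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(library), size=n, replace=False)
    out = []
    for i in idx:
        m = library.masks[int(i)]
        if m.shape != tuple(target_size):
            m = resize(m.astype(np.float64), target_size, order=0,
                       anti_aliasing=False, preserve_range=True) > 0.5
        else:
            m = m.copy()
        if exclude is not None:
            m &= ~exclude.astype(bool)
        out.append(m)
    return out


# ---------------------------------------------------------------------------
# training-set utilities
# ---------------------------------------------------------------------------

def augment_training_pairs(
    image: np.ndarray, mask: np.ndarray, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Quadrant crops with random flips, applied identically to image and mask.

    A 576x768 input yields four 288x384 pairs.  Each crop is independently
    flipped horizontally and/or vertically with probability 1/2.
    """
    if image.shape[:2] != mask.shape[:2]:
        raise ValueError(
            f"image {image.shape[:2]} and mask {mask.shape[:2]} sizes differ"
        )
    h2, w2 = image.shape[0] // 2, image.shape[1] // 2
    rng = np.random.default_rng(seed)
    pairs = []
    for r0 in (0, h2):
        for c0 in (0, w2):
            img = image[r0 : r0 + h2, c0 : c0 + w2].copy()
            msk = mask[r0 : r0 + h2, c0 : c0 + w2].copy()
            if rng.random() < 0.5:
                img, msk = img[:, ::-1], msk[:, ::-1]
            if rng.random() < 0.5:
                img, msk = img[::-1, :], msk[::-1, :]
            pairs.append((np.ascontiguousarray(img), np.ascontiguousarray(msk)))
    return pairs


def train_val_test_split(
    n_items: int, seed: int, fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Shuffled 80/10/10 index split (train, validation, test)."""
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    idx = rng.permutation(n_items)
    n_train = int(round(fractions[0] * n_items))
    n_val = int(round(fractions[1] * n_items))
    return idx[:n_train], idx[n_train : n_train + n_val], idx[n_train + n_val :]
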