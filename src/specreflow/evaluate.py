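"""Benchmark protocol: synthetic-overlay trials and significance testing.

A *trial* takes 100 consecutive clean frames with ground truth available.
The first 50 are warm-up: left untouched, they give temporal engines donor
content.  Onto each of the following 50 assessment frames one mask,
sampled without replacement from a mask library, is overlaid as a
synthetic specular highlight.  The restorer sees the full corrupted
100-frame window; mPSNR/mSSIM (and full-frame PSNR/SSIM for contrast) are
scored on the assessment frames against the clean ground truth.

A *benchmark* runs 13 such trials per restorer on temporally disjoint
windows with independent mask draws, then compares engines pairwise with
two-tailed two-sample t-tests on the per-trial metric means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .fixtures import MaskLibrary, paint_sr, sample_overlay_masks
from .metrics import aggregate_finite_mean, full_frame_metrics, mpsnr, mssim
from .restore import RestorerSpec, restore_sequence

__all__ = [
    "TrialSpec",
    "TrialResult",
    "ComparisonReport",
    "run_trial",
    "run_benchmark",
    "two_sample_ttest",
]


@dataclass(frozen=True)
class TrialSpec:
    """One 100-frame trial: 50 warm-up frames, 50 masked assessment frames."""

    n_frames: int = 100
    n_warmup: int = 50
    n_masks: int = 50
    mask_seed: int = 0
    trial_id: int = 0
    # corruption is confined to the mask: the overlay saturates exactly the
    # masked pixels, so metrics see only restorer-attributable error
    core_intensity: int = 255
    halo_width: int = 0

    @property
    def n_assessment(self) -> int:
        return self.n_frames - self.n_warmup

    def __post_init__(self) -> None:
        if self.n_warmup >= self.n_frames:
            raise ValueError("need at least one assessment frame")
        if self.n_masks != self.n_assessment:
            raise ValueError("one sampled mask per assessment frame")


@dataclass
class TrialResult:
    restorer: str
    trial_id: int
    per_frame: list[dict]  # keys: frame, mpsnr, mssim, psnr, ssim
    aggregates: dict

    @staticmethod
    def from_scores(restorer: str, trial_id: int, per_frame: list[dict]) -> "TrialResult":
        agg = {}
        for key in ("mpsnr", "mssim", "psnr", "ssim"):
            vals = [f[key] for f in per_frame if not math.isnan(f[key])]
            mean, n_inf = aggregate_finite_mean(vals)
            agg[f"mean_{key}"] = mean
            if key in ("mpsnr", "psnr"):
                agg[f"n_inf_{key}"] = n_inf
        return TrialResult(restorer, trial_id, per_frame, agg)


@dataclass
class ComparisonReport:
    restorer_a: str
    restorer_b: str
    metric: str
    t_statistic: float
    p_value: float
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float


def two_sample_ttest(
    a: Sequence[float], b: Sequence[float], equal_var: bool = True
) -> tuple[float, float]:
    """Two-tailed two-sample t-test for means.

    Pooled-variance by default; ``equal_var=False`` gives the Welch
    variant.  Two zero-variance samples with equal means return
    ``(0.0, 1.0)`` rather than NaN.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least two observations")
    if np.var(a) == 0.0 and np.var(b) == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return math.copysign(math.inf, a.mean() - b.mean()), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def overlay_trial_masks(
    clean: np.ndarray,
    library: MaskLibrary,
    spec: TrialSpec,
    exclude: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Corrupt the assessment frames of a clean window with sampled masks.

    Returns ``(corrupted_frames, mask_sequence)``; warm-up frames carry
    zero mask pixels.  Deterministic per ``spec.mask_seed``.
    """
    if len(clean) < spec.n_frames:
        raise ValueError(
            f"need at least {spec.n_frames} frames, got {len(clean)}"
        )
    window = clean[: spec.n_frames]
    h, w = window.shape[1:3]
    sampled = sample_overlay_masks(
        library, spec.n_masks, (h, w), seed=spec.mask_seed, exclude=exclude
    )
    corrupted = window.copy()
    masks = np.zeros((spec.n_frames, h, w), dtype=bool)
    for k, mask in enumerate(sampled):
        t = spec.n_warmup + k
        masks[t] = mask
        if mask.any():
            corrupted[t] = paint_sr(
                window[t], mask, spec.core_intensity, spec.halo_width
            )
    return corrupted, masks


def run_trial(
    clean: np.ndarray,
    library: MaskLibrary,
    restorer: RestorerSpec,
    spec: TrialSpec,
    exclude: Optional[np.ndarray] = None,
) -> TrialResult:
    """Run one restorer on one corrupted 100-frame window and score it."""
    corrupted, masks = overlay_trial_masks(clean, library, spec, exclude)
    restored = restore_sequence(corrupted, masks, restorer)
    per_frame = []
    for t in range(spec.n_warmup, spec.n_frames):
        gt = clean[t]
        rest = restored[t]
        mask = masks[t]
        if mask.any():
            f_mpsnr = mpsnr(gt, rest, mask)
            f_mssim = mssim(gt, rest, mask)
        else:  # a sampled mask can be clipped to nothing by the exclusion zone
            f_mpsnr = math.nan
            f_mssim = math.nan
        psnr, ssim = full_frame_metrics(gt, rest)
        per_frame.append(
            {"frame": t, "mpsnr": f_mpsnr, "mssim": f_mssim, "psnr": psnr, "ssim": ssim}
        )
    return TrialResult.from_scores(restorer.name, spec.trial_id, per_frame)


def _disjoint_windows(dataset: Sequence[np.ndarray], n_frames: int) -> list[np.ndarray]:
    windows = []
    for seq in dataset:
        for start in range(0, len(seq) - n_frames + 1, n_frames):
            windows.append(seq[start : start + n_frames])
    return windows


def run_benchmark(
    dataset: Sequence[np.ndarray],
    restorers: Sequence[RestorerSpec],
    n_trials: int = 13,
    base_seed: int = 0,
    trial_spec: TrialSpec = TrialSpec(),
    library: Optional[MaskLibrary] = None,
    metrics: tuple[str, ...] = ("mpsnr", "mssim"),
) -> tuple[list[TrialResult], list[ComparisonReport]]:
    """13-trial benchmark over temporally disjoint windows.

    Every restorer sees identical corrupted inputs per trial (same window,
    same mask draw).  Pairwise two-tailed t-tests compare the per-trial
    means of each metric between every pair of restorers.
    """
    from .fixtures import generate_mask_library

    names = [r.name for r in restorers]
    if len(set(names)) != len(names):
        raise ValueError("restorer names must be unique within a benchmark")
    windows = _disjoint_windows(dataset, trial_spec.n_frames)
    if len(windows) < n_trials:
        raise ValueError(
            f"need {n_trials} disjoint {trial_spec.n_frames}-frame windows, "
            f"got {len(windows)}"
        )
    if library is None:
        library = generate_mask_library(seed=base_seed + 7_001)
    results: list[TrialResult] = []
    for i in range(n_trials):
        spec_i = TrialSpec(
            n_frames=trial_spec.n_frames,
            n_warmup=trial_spec.n_warmup,
            n_masks=trial_spec.n_masks,
            mask_seed=base_seed * 1_000 + i,
            trial_id=i,
            core_intensity=trial_spec.core_intensity,
            halo_width=trial_spec.halo_width,
        )
        for restorer in restorers:
            results.append(run_trial(windows[i], library, restorer, spec_i))

    comparisons: list[ComparisonReport] = []
    by_name = {
        name: [r for r in results if r.restorer == name] for name in names
    }
    for ia in range(len(names)):
        for ib in range(ia + 1, len(names)):
            na, nb = names[ia], names[ib]
            for metric in metrics:
                va = [r.aggregates[f"mean_{metric}"] for r in by_name[na]]
                vb = [r.aggregates[f"mean_{metric}"] for r in by_name[nb]]
                va = [v for v in va if not math.isnan(v)]
                vb = [v for v in vb if not math.isnan(v)]
                t, p = two_sample_ttest(va, vb)
                comparisons.append(
                    ComparisonReport(
                        na, nb, metric, t, p, len(va), len(vb),
                        float(np.mean(va)), float(np.mean(vb)),
                    )
                )
    return results, comparisons
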