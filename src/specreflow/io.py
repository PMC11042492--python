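"""Frame/mask I/O, manifests, and the end-to-end pipeline driver.

On-disk conventions: frames are 8-bit RGB PNGs named ``frame_%05d.png``;
masks are single-channel 0/255 PNGs named ``mask_%05d.png``; every run
writes a JSON manifest recording the configuration and seeds needed to
reproduce its outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np

from .detect import DetectionConfig, detect_sequence
from .metrics import full_frame_metrics, mpsnr, mssim
from .restore import RestorerSpec, restore_sequence
from .unet import LightUNet, LightUNetConfig

__all__ = [
    "PipelineConfig",
    "read_frame_sequence",
    "write_frame_sequence",
    "read_mask_sequence",
    "write_mask_sequence",
    "save_model",
    "load_model",
    "run_pipeline",
]

_IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg", ".bmp", ".tif", ".tiff"}


@dataclass
class PipelineConfig:
    input_dir: Path
    output_dir: Path
    weights: Optional[Path] = None
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    restorer: RestorerSpec = field(
        default_factory=lambda: RestorerSpec("flow", "flow-propagation")
    )
    score_against: Optional[Path] = None  # clean ground-truth frames, if any
    seed: int = 0


def _image_files(path: Path) -> list[Path]:
    return sorted(p for p in path.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES)


def read_frame_sequence(path: Path | str) -> np.ndarray:
    """Read an ordered RGB uint8 sequence from a directory of images.

    Files are taken in lexicographic order; all frames must agree in size.
    """
    path = Path(path)
    if not path.is_dir():
        raise FileNotFoundError(f"{path} is not a directory of frames")
    files = _image_files(path)
    if not files:
        raise ValueError(f"no image files found in {path}")
    frames = []
    for f in files:
        try:
            img = iio.imread(f)
        except Exception as exc:  # noqa: BLE001 - name the offending file
            raise ValueError(f"could not read frame {f}") from exc
        if img.ndim == 2:
            img = np.stack([img] * 3, axis=-1)
        if img.shape[2] == 4:
            img = img[:, :, :3]
        frames.append(img.astype(np.uint8))
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise ValueError(f"mixed frame dimensions in {path}: {sorted(shapes)}")
    return np.stack(frames)


def write_frame_sequence(path: Path | str, frames: np.ndarray,
                         pattern: str = "frame_%05d.png") -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for t, frame in enumerate(frames):
        iio.imwrite(path / (pattern % t), np.asarray(frame, dtype=np.uint8))


def read_mask_sequence(path: Path | str) -> np.ndarray:
    """Read 0/255 PNG masks as a boolean (T, H, W) array."""
    path = Path(path)
    files = _image_files(path)
    if not files:
        raise ValueError(f"no mask files found in {path}")
    masks = []
    for f in files:
        img = iio.imread(f)
        if img.ndim == 3:
            img = img[:, :, 0]
        masks.append(img > 127)
    shapes = {m.shape for m in masks}
    if len(shapes) != 1:
        raise ValueError(f"mixed mask dimensions in {path}: {sorted(shapes)}")
    return np.stack(masks)


def write_mask_sequence(path: Path | str, masks: np.ndarray,
                        pattern: str = "mask_%05d.png") -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for t, mask in enumerate(masks):
        iio.imwrite(path / (pattern % t),
                    (np.asarray(mask, dtype=bool) * np.uint8(255)))


# ---------------------------------------------------------------------------
# model serialization: .npz weights + JSON sidecar with the architecture
# ---------------------------------------------------------------------------

def save_model(model: LightUNet, path: Path | str) -> None:
    path = Path(path)
    state = model.state_dict()
    np.savez(path, *state)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(asdict(model.config), indent=2))


def load_model(path: Path | str) -> LightUNet:
    path = Path(path)
    sidecar = path.with_suffix(".json")
    cfg = LightUNetConfig(**json.loads(sidecar.read_text()))
    model = LightUNet(cfg)
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as data:
        state = [data[k] for k in data.files]
    model.load_state_dict(state)
    return model


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig) -> dict:
    """enhance -> detect -> restore (-> score), writing artifacts and a manifest.

    Returns the manifest dictionary.  Detection runs threshold-only when no
    weights are supplied.
    """
    frames = read_frame_sequence(config.input_dir)
    model = load_model(config.weights) if config.weights else None
    masks = detect_sequence(model, frames, config.detection)
    restored = restore_sequence(frames, masks, config.restorer)

    out = Path(config.output_dir)
    write_mask_sequence(out / "masks", masks)
    write_frame_sequence(out / "restored", restored)

    manifest: dict = {
        "n_frames": int(len(frames)),
        "frame_shape": list(frames.shape[1:]),
        "seed": config.seed,
        "detection": asdict(config.detection),
        "restorer": {"name": config.restorer.name, "kind": config.restorer.kind,
                     "params": config.restorer.params},
        "weights": str(config.weights) if config.weights else None,
    }
    if config.score_against is not None:
        clean = read_frame_sequence(config.score_against)
        scores = []
        for t in range(len(frames)):
            entry = {"frame": t}
            psnr, ssim = full_frame_metrics(clean[t], restored[t])
            entry["psnr"], entry["ssim"] = psnr, ssim
            if masks[t].any():
                entry["mpsnr"] = mpsnr(clean[t], restored[t], masks[t])
                entry["mssim"] = mssim(clean[t], restored[t], masks[t])
            scores.append(entry)
        manifest["scores"] = scores
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
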