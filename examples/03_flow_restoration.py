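"""Restore a corrupted moving sequence with the flow-propagation engine.

Corrupts one frame of a panning synthetic sequence, restores it by
chaining optical flow to unmasked donor frames, and compares the fill
error against single-frame diffusion inpainting.
"""

import numpy as np

import specreflow as sr
from specreflow.restore import RestorerSpec, restore_sequence

scene = sr.SceneConfig(height=64, width=96, n_frames=7,
                       motion_model="translation", motion_magnitude=2,
                       noise_sigma=0, seed=8)
clean = sr.generate_tissue_sequence(scene)
masks = np.zeros((7, 64, 96), dtype=bool)
masks[3, 24:36, 40:62] = True  # hide a patch (vessels included) in frame 3
corrupted = clean.copy()
corrupted[3][masks[3]] = 255

for kind in ("flow-propagation", "diffusion-inpaint"):
    out = restore_sequence(corrupted, masks, RestorerSpec(kind, kind))
    err = np.abs(out[3].astype(int) - clean[3].astype(int))[masks[3]]
    mp = sr.mpsnr(clean[3], out[3], masks[3])
    ms = sr.mssim(clean[3], out[3], masks[3])
    print(f"{kind:18s} max|err|={err.max():3d}  mPSNR={mp:6.2f} dB  mSSIM={ms:.4f}")
# the flow engine copies the true tissue (vessels survive) from adjacent
# frames, so its error stays within interpolation rounding; diffusion can
# only blur the surroundings inward and loses the structure
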