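"""Enhance a corrupted synthetic frame and detect its specular highlights.

Builds one synthetic tissue frame with saturated highlight blobs, runs the
saturation-based enhancement and the threshold-only detector, and prints
how the highlight/tissue histogram gap and the detection scores change.
"""

import numpy as np

import specreflow as sr

# one clean frame, then overlay three highlight blobs with halos
scene = sr.SceneConfig(height=96, width=128, n_frames=1, motion_model="static", seed=1)
clean = sr.generate_tissue_sequence(scene)[0]
corrupted, masks = sr.synthesize_sr_artifacts(
    clean[None], sr.SRArtifactConfig(n_regions=3, seed=2)
)
frame, gt = corrupted[0], masks[0]

enhanced = sr.enhance_frame(frame)
value_before = frame.max(axis=2).astype(float)
value_after = enhanced.max(axis=2).astype(float)
gap_before = value_before[gt].min() - np.median(value_before[~gt])
gap_after = value_after[gt].min() - np.median(value_after[~gt])
print(f"value gap highlight-vs-tissue: {gap_before:.0f} -> {gap_after:.0f}")
# the gap widens because chromatic tissue is darkened while the
# achromatic highlight cores are fixed points of the 1-S product

for dilate in (False, True):
    pred = sr.detect_frame(None, frame, sr.DetectionConfig(dilate=dilate))
    dice, iou, sens = sr.detection_metrics(pred, gt)
    tag = "dilated " if dilate else "undilated"
    print(f"{tag} detection: dice={dice:.3f} iou={iou:.3f} sensitivity={sens:.3f}")
# dilation trades Dice for sensitivity: the restoration stage wants the
# degraded rim around each highlight covered, not a pixel-perfect outline
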