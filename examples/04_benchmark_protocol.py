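"""A scaled-down overlay benchmark with significance testing.

Runs 5 trials (20-frame windows, 10 warm-up / 10 masked assessment
frames) of the flow-propagation engine against diffusion inpainting and
the unrestored baseline, then prints per-engine means and the two-sample
t-test separating the engines.  The full protocol (100-frame windows,
50 masks, 13 trials) is what scripts/acceptance.py runs.
"""

import specreflow as sr
from specreflow.evaluate import TrialSpec, run_benchmark
from specreflow.fixtures import generate_mask_library
from specreflow.restore import RestorerSpec

scene = sr.SceneConfig(height=64, width=96, n_frames=100,
                       motion_model="translation", motion_magnitude=1, seed=3)
clean = sr.generate_tissue_sequence(scene)
library = generate_mask_library(60, (64, 96), seed=4)
trial = TrialSpec(n_frames=20, n_warmup=10, n_masks=10, mask_seed=0)

restorers = [
    RestorerSpec("flow", "flow-propagation"),
    RestorerSpec("diffusion", "diffusion-inpaint"),
    RestorerSpec("unrestored", "identity"),
]
results, comparisons = run_benchmark([clean], restorers, n_trials=5,
                                     base_seed=5, trial_spec=trial, library=library)

for name in ("flow", "diffusion", "unrestored"):
    rows = [r.aggregates for r in results if r.restorer == name]
    mp = sum(r["mean_mpsnr"] for r in rows) / len(rows)
    ms = sum(r["mean_mssim"] for r in rows) / len(rows)
    print(f"{name:10s} mean mPSNR={mp:6.2f} dB  mean mSSIM={ms:.4f}  (n={len(rows)} trials)")

for c in comparisons:
    if {c.restorer_a, c.restorer_b} == {"flow", "diffusion"}:
        print(f"flow vs diffusion ({c.metric}): t={c.t_statistic:+.2f}  p={c.p_value:.2e}")
# small p-values: per-trial means of the flow engine are separated from
# single-frame inpainting by far more than the between-trial variability
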