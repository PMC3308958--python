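"""Run the complete pipeline from one config: phantom -> depth -> simulate
-> cluster detection -> laminar profiles -> depth ANOVA.

Everything is driven by a single seed; rerunning with the same seed skips
completed stages (digest match) and reproduces byte-identical CSVs.
"""

import pandas as pd

from laminarpy.pipeline import run_pipeline

manifest = run_pipeline(
    {"phantom": {"fov_mm": [16.0, 16.0, 8.0]},
     "analysis": {"n_sessions": 3}},
    out_dir="pipeline_demo", seed=1)

print(f"stages: { {k: round(v, 2) for k, v in manifest['timings_s'].items()} }")
print(f"clusters detected: {manifest['n_rois']}")
for flags in manifest["roi_flags"]:
    print(f"  ROI of {flags['size']} voxels, WM-stable: {flags['wm_stable']}"
          f" (|delta WM| = {flags['wm_delta_pct']:.3f}%)")

anova = pd.read_csv("pipeline_demo/depth_anova.csv")
print(anova.to_string(index=False))
# Each row tests for a main effect of depth on the intact-minus-scrambled
# differential across the simulated sessions of one ROI; the ground truth
# has a mid-depth scrambled excess, so F should be large and p small.
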