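"""Simulate a two-condition laminar BOLD session and recover the profile.

Ground truth: both conditions respond at 1% at all depths, but 'scrambled'
carries an extra 0.5% in the middle of the cortical thickness. The session
adds the voxel-sampling blur (87% of 0.7 mm), AR(1) noise at 0.5% and a
superficial baseline bias, then the analysis averages voxels within five
equally-populated depth bins before fitting the GLM.
"""

import numpy as np

from laminarpy.synthetic_cortex import PhantomConfig, make_ribbon_phantom, \
    voxelize, LABEL_GM
from laminarpy.bold_simulator import BlockDesign, NeuralDepthProfile, \
    simulate_session
from laminarpy import depth_mapping as dm
from laminarpy import laminar_analysis as la

config = PhantomConfig()
pair = make_ribbon_phantom(config)
tissue, truth = voxelize(pair, config)
depthmap = dm.matched_faces_depth(pair, tissue)

design = BlockDesign(condition_labels=("intact", "scrambled"))
ground_truth = NeuralDepthProfile(
    amplitude={"intact": 1.0,
               "scrambled": NeuralDepthProfile.middle_bump(1.0, 0.5)},
    baseline_bias=NeuralDepthProfile.linear(1.0, 1.6))

session = simulate_session(truth, ground_truth, design,
                           noise_std_pct=0.5, ar1=0.3,
                           psf_fwhm_mm=0.87 * 0.7,
                           labels=tissue.labels, seed=11)

vox = np.argwhere(tissue.labels == LABEL_GM)
roi = la.ClusterROI(voxels=vox,
                    wm_voxels=la.adjacent_wm_voxels(vox, tissue.labels))
profile = la.laminar_profile(session.data, depthmap, roi, design, k=5)
diff = la.differential_profile(profile)

print("bin  depth  intact%   scrambled%   diff%")
for b in range(5):
    print(f"{b}   {profile.mean_depth[b]:.2f}   "
          f"{profile.amplitude['intact'][b]:.3f}    "
          f"{profile.amplitude['scrambled'][b]:.3f}      "
          f"{diff.difference[b]:+.3f}")
print(f"WM reference: intact {profile.wm_amplitude['intact']:+.3f}%, "
      f"scrambled {profile.wm_amplitude['scrambled']:+.3f}%")
print(f"differential extremum at bin {diff.extremum_bin} (expected 2)")
# The middle bin shows the largest intact-minus-scrambled difference
# (negative: the excess was injected into 'scrambled'); neighbouring bins
# pick up part of it through the point-spread blur.
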