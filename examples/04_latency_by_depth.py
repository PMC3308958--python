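"""Fourier-phase onset latency as a function of cortical depth.

The hemodynamic response starts in deep layers and reaches superficial
layers ~100 ms or more later, following the penetrating arterioles. Here a
deep-to-superficial onset gradient is injected as ground truth across five
synthetic subjects and read back as the phase of the stimulus-frequency
Fourier component, scaled to seconds over the 32 s block cycle, with each
subject's mean latency subtracted before the depth ANOVA.
"""

import numpy as np

from laminarpy.synthetic_cortex import PhantomConfig, make_ribbon_phantom, \
    voxelize
from laminarpy.bold_simulator import BlockDesign, NeuralDepthProfile, \
    simulate_session
from laminarpy import depth_mapping as dm
from laminarpy import laminar_analysis as la

config = PhantomConfig()
pair = make_ribbon_phantom(config)
tissue, truth = voxelize(pair, config)
depthmap = dm.matched_faces_depth(pair, tissue)

design = BlockDesign()
# onset latency rises linearly from 0 s at the WM boundary to 0.4 s at the
# pial surface: deep layers lead, as reported for penetrating arterioles
ground_truth = NeuralDepthProfile(
    amplitude={"stimulus": 1.0},
    latency={"stimulus": NeuralDepthProfile.linear(0.0, 0.4)})

subjects = [simulate_session(truth, ground_truth, design,
                             noise_std_pct=0.5, ar1=0.3,
                             psf_fwhm_mm=0.0, labels=tissue.labels, seed=s)
            for s in range(5)]

vox = np.argwhere(depthmap.gm_labeled)
roi = la.ClusterROI(voxels=vox, wm_voxels=np.empty((0, 3), int))
lat_profile, anova = la.latency_by_depth(subjects, depthmap, roi, k=5)

print("bin  depth  mean latency (mean-subtracted, s)")
for b in range(5):
    print(f"{b}    {lat_profile.mean_depth[b]:.2f}   "
          f"{lat_profile.group_mean[b]:+.3f}")
print(f"depth ANOVA: F_{anova.df_num},{anova.df_den} = {anova.F:.2f}, "
      f"p = {anova.p_value:.4f}")
# A monotone mean-subtracted latency profile spanning ~0.4 s with a
# significant depth main effect mirrors the deep-leads-superficial onset
# ordering; per-subject mean subtraction removes global hemodynamic delay.
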