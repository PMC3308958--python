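# laminarpy

Laminar (cortical-depth-resolved) fMRI analysis, exercised end-to-end on
synthetic cortical-ribbon phantoms with known ground truth.

High-resolution fMRI can resolve signal changes *within* the thickness of
cortex, but turning 0.7 mm voxels into laminar response profiles requires a
chain of delicate steps: assigning each gray-matter voxel a relative
cortical depth from paired white-matter/pial surface meshes, binning voxels
into equally-populated depth bins, averaging before regression, modelling
the blur that voxel sampling imposes on any laminar profile, and testing
depth effects nonparametrically. `laminarpy` implements that chain for
researchers who want to validate a laminar pipeline against data where the
truth is known — every stage can be driven by a parametric phantom and a
forward BOLD simulator instead of a scanner.

## What it computes

- **Cortical depth from surfaces** (`depth_mapping`). For matched WM/GM
  triangulated meshes, each GM voxel's absolute depth d and local thickness
  T come from the WM→GM segments traversing the voxel; relative depth is
  d/T ∈ [0, 1] (0 at the WM boundary, 1 at the pial surface). Three segment
  families are provided — matched vertices, WM-surface normals, nearest GM
  point — which agree closely on *relative* depth even in curved cortex.
  Segmentation QC excludes voxels with thickness ≥ 4 mm.
- **Laminar profiles** (`laminar_analysis`). ROI voxels are sorted by
  relative depth into k equally-populated bins (default k = 5); bin time
  series are averaged, then a GLM with a double-gamma HRF regressor per
  condition estimates percent signal change β·100/β₀ per bin. Differential
  profiles subtract conditions per depth; a one-way ANOVA over bins with
  ROIs as replicates (df = (k−1, k(r−1))) tests for a depth effect, and
  per-depth paired t-tests are Bonferroni-corrected over 2k comparisons.
- **Cluster/ROI rules**. Activation clusters are face-connected components
  of p < 0.001 voxels (≥ 100 voxels) on data smoothed with σ = 1.4 mm —
  smoothing for delineation only. ROIs are excluded when the WM-reference
  amplitudes of the two conditions differ by more than max(0.16%, 2·SE),
  when any bin holds < 40 voxels, or when the stimulus was present < 25% of
  the time in the ROI's visual-field region.
- **Permutation inference** (`glm_stats`). Significance comes from
  relabeling whole 16 s blocks, rebuilding the regressor and re-estimating
  N = 1000 times; p = (1 + #{|t_null| ≥ |t_obs|})/(N + 1), two-sided,
  identity excluded. A DCT high-pass filter (cutoff 4 cycles/scan) is
  projected out of data and regressors alike.
- **Fourier latency**. Response onset per depth bin is the phase of the
  Fourier component at the block-alternation frequency (10 cycles/scan,
  32 s cycle), scaled to 0–32 s, mean-subtracted per subject.
- **Forward simulation** (`bold_simulator`, `synthetic_cortex`). A folded
  ribbon phantom (sinusoidal WM surface, normal-offset GM surface) supplies
  ground-truth depth; each GM voxel's signal is
  `baseline · bias(depth) · [1 + Σ_c amp_c(depth)/100 · resp_c(t − lat_c(depth))]`
  with Gaussian point-spread blur and AR(1) noise. The voxel-sampling PSF
  model itself is derived in-package: the 1D projection of a cubic voxel,
  averaged over surface orientations uniform on the sphere, is matched by a
  Gaussian with FWHM ≈ 87% of the voxel edge.
- **Stimulus statistics** (`stimulus_gen`). Hexagonal aperture grids,
  rotation scrambling (uniform [60°, 120°] ∪ [−120°, −60°], mean |rotation|
  90°), RMS contrast (σ/μ) and orientation-band power of vignetted patches.

## Worked example

`python examples/02_simulate_and_laminar_profile.py` simulates a session in
which both conditions respond at 1% everywhere but "scrambled" carries an
extra 0.5% at mid-depth, then recovers the laminar profile:

```
bin  depth  intact%   scrambled%   diff%
0   0.10   0.964    0.979      -0.015
1   0.29   0.990    1.225      -0.236
2   0.49   0.994    1.477      -0.483
3   0.69   0.995    1.258      -0.263
4   0.90   0.972    0.990      -0.019
WM reference: intact +0.027%, scrambled +0.035%
differential extremum at bin 2 (expected 2)
```

Each row is one depth bin (0 deepest). The intact profile recovers the
flat 1% truth; the scrambled profile peaks mid-depth, attenuated and spread
into neighbouring bins by the 0.87 × 0.7 mm point-spread blur. The
differential profile localises the injected effect to the middle bin, and
the near-zero WM reference amplitudes show a stable baseline (an unstable
one would disqualify the ROI). The other scripts in `examples/` walk
through depth mapping, stimulus statistics, latency-by-depth and the full
pipeline.

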