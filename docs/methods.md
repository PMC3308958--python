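# Methods

This note records the models implemented in `laminarpy`, the parameters
that matter, and the choices made where more than one reasonable design
existed. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The cortical-ribbon phantom (`synthetic_cortex`)

The phantom's WM surface is the height field
z = z₀ + A·sin(2πx/λ)·sin(2πy/λ) triangulated on a regular grid (edge
0.35 mm by default, half a voxel); the pial (GM) surface displaces each WM
vertex along the local analytic normal by a thickness field (constant
2.5 mm by default). Vertex i of the GM mesh corresponds to vertex i of the
WM mesh, which is exactly the structure the depth-mapping stage assumes.
Offsetting a surface along its normals self-intersects once the offset
reaches the reciprocal of the maximal principal curvature; configurations
with max(thickness)·max|κ| ≥ 1 are rejected with a geometry error rather
than silently producing a folded GM sheet.

Voxelisation classifies voxel *centres* only: the exact foot point on the
WM height field is found by per-voxel Newton iteration, the signed normal
distance s determines the label (WM for s < 0, GM for 0 ≤ s ≤ thickness,
outside beyond), and true relative depth is s/thickness. Partial-volume
effects are deliberately not modelled at this stage — they enter through
the simulator's point-spread blur, which is where the acquisition puts
them. Voxels whose foot point falls outside the meshed x/y extent (the
grid is rounded to whole voxels) stay unlabeled rather than extrapolated.

Retinotopic tags are a deterministic map from (x, y): eccentricity bands
{1–3°, 3–6°, 6–9°} scaled so the farthest corner is 9°, and eight equal
polar wedges. They stand in for a retinotopy session; no traveling-wave
analysis is performed.

Defaults (20 × 20 × 8 mm field, 0.7 mm isotropic voxels) keep a full
pipeline run in the low seconds while leaving ≈ 3000 GM voxels — enough
for five 40-voxel depth bins with a wide margin.

## Depth mapping (`depth_mapping`)

All three metrics reduce to one accumulation rule over WM→GM segments: a
voxel's absolute depth is the mean over traversing segments of the scalar
projection of (centre − WM endpoint) onto the segment direction (clamped to
[0, length]); its thickness is the mean traversing-segment length;
relative depth is their ratio clipped to [0, 1]. "Traverses" means the
segment intersects the voxel cube with positive path length — face- or
corner-touching contacts of measure zero are excluded, a rule chosen so the
implementation and the exhaustive segment × voxel test oracle can state
exactly the same predicate. The segment families are:

- **matched_faces** (default): segments join matched mesh vertices. It is
  the default because it labels the most GM voxels and needs no
  intersection search.
- **wm_normal**: WM vertex normals extended to their first GM-mesh
  intersection (vectorised Möller–Trumbore). Normals that miss the GM mesh
  within 3× the median matched thickness are skipped and counted.
- **nearest_gm**: shortest segment from each WM vertex to the GM surface
  (KD-tree shortlist over face centroids, then exact point-triangle
  projection).

On a flat slab the three families coincide exactly; on curved cortex they
differ in *absolute* depth but agree closely in *relative* depth, which is
why laminar analysis is built on the relative quantity. Voxels whose
traversing segments disagree in length by more than 50% of their mean
(e.g. both banks of a tight sulcus) are flagged; the QC rule excludes
voxels with thickness not strictly below 4 mm.

## BOLD forward model (`bold_simulator`)

Per GM voxel:

    signal(t) = baseline · bias(d) · [1 + Σ_c amp_c(d)/100 · resp_c(t − lat_c(d))]

with d the voxel's true relative depth, baseline 100 arbitrary units,
`bias` a multiplicative baseline factor (default pipeline setting: linear
1.0 → 1.6 toward the surface, emulating the superficial vascular bias),
`amp_c` in percent signal change and `lat_c` an onset latency in seconds
(must stay within one block length). `resp_c` is the condition boxcar
convolved with the canonical double-gamma HRF (delays 6/16 s, dispersions
1/1, undershoot ratio 6, 32 s kernel, unit sum) *sampled at TR*: the
simulator synthesises from exactly the regressor the GLM fits, realising
sub-TR latencies by linear interpolation of that series. This makes
noiseless, blur-free sessions invert to ground truth at numerical
precision and keeps latency differences faithful to ~10 ms; a fine-grid
convolution would instead carry an O(1 s) phase offset against the
TR-sampled regressor and contaminate both checks.

The design is 16 s stimulus / 16 s rest, 10.5 cycles at TR 2 s = 168
volumes; the run starts and ends on a stimulus block (11 stimulus, 10 rest
blocks). Noise is AR(1) (coefficient 0.3) with stationary standard
deviation expressed in percent of baseline (default 0.5%); blur is an
isotropic Gaussian applied volume-wise after signal synthesis (acquisition
interpretation), with FWHM defaulting to 87% of the voxel edge. Anisotropic
through-slab blur is exposed as a parameter choice but not defaulted, since
no quantitative characterisation exists to anchor it.

### The voxel-sampling PSF constant

The projection of a unit cube onto a direction d is the sum of three
independent uniforms of widths |d₁|, |d₂|, |d₃|; its density is evaluated
in closed form and averaged over directions uniform on the sphere.
`psf_fwhm_estimate` models that averaged profile as a Gaussian **matched at
half maximum**: the reported FWHM is the profile's measured half-max width
(≈ 0.87 of the voxel edge). An unconstrained least-squares Gaussian fit is
also available (`fit="lsq"`); it trades the tails against the core and
yields ≈ 0.77. The half-max convention is the default because it is the
one under which the conventional "87%" figure for laminar sampling blur is
recovered; both are deterministic given the seed.

## GLM and inference (`glm_stats`)

**Drift removal.** A DCT-II basis spans frequencies strictly below the
cutoff (default 4 cycles/scan — 0.0119 Hz over 336 s); basis k completes
k/2 cycles per scan, so k runs 1..7. The projection is applied to data and
regressors alike (it is idempotent), retains the temporal mean, and errors
when the cutoff reaches Nyquist.

**Amplitude.** OLS with intercept; percent signal change is 100·β/β₀ with
β₀ the fitted intercept. Scaling by the raw temporal mean would fold the
stimulus-driven signal into the denominator and bias amplitudes low by
mean(regressor)·amplitude (≈ 0.5% of the amplitude at this design); the
intercept is the stimulus-free baseline estimate and makes noiseless
forward-inverse recovery exact.

**Permutation test.** The null relabels whole blocks (preserving
within-block autocorrelation), rebuilds the HRF regressor, and re-estimates
N = 1000 times; the identity relabeling is excluded and p uses the plus-one
estimator, so min p = 1/(N+1) — reaching p < 0.001 therefore requires
N ≥ 1000. The default test statistic is the **studentized** amplitude |t|,
not the raw β: relabelings that make all stimulus blocks contiguous
concentrate their regressor variance below the high-pass cutoff, so after
filtering their β estimates explode under the null and a raw-amplitude test
becomes so conservative that strongly active voxels can fail p < 0.001.
The t statistic is bounded by the regressor-data correlation, immune to
that degeneracy, and the permutation test remains exact under block
exchangeability with either statistic (`statistic="amplitude"` keeps the
raw version). Timepoint-level shuffling exists behind a flag for
comparison; it destroys the autocorrelation structure and is not the
default. The vectorised map variant shares one set of relabelings across
voxels (each voxel's null remains exact) for cluster detection.

**Fourier latency.** The series is truncated to n whole 32 s cycles
(default 10) and the phase φ of the DFT bin at n cycles/scan is scaled to
latency = φ·32/(2π) ∈ [0, 32) s, with the sign convention that a delayed
cosine maps to a positive latency equal to its delay. Zero power at the
stimulus frequency raises rather than returning an arbitrary phase.

## Laminar analysis (`laminar_analysis`)

Binning sorts voxels stably by relative depth and cuts k contiguous groups
whose sizes differ by ≤ 1, deeper bins taking the remainder. Profiles are
average-then-regress: the bin's voxel series are averaged first and the GLM
fit once per bin, so bin SEs reflect the averaged series' residuals. The
WM reference applies the identical estimator to the ROI's one-shell
face-adjacent WM voxels (the adjacency rule is this package's
concretisation of "immediately adjacent white matter"); a missing WM shell
reports NaN and the stability rule then passes rather than excluding.

Cluster detection smooths every volume with σ = 1.4 mm, recomputes
amplitude and block-permutation p per GM voxel on the smoothed series, and
takes face-connected (6-neighbourhood — the conservative standard)
components of p < 0.001 with ≥ 100 voxels. Smoothing serves delineation
only; profile estimation always returns to unsmoothed data. Eligibility:
WM-reference condition difference ≤ max(0.16%, 2·mean SE across ROIs),
≥ 40 voxels per bin, stimulus presence ≥ 25%; condition preference is the
sign of the depth-averaged differential. The depth ANOVA is one-way fixed
effects with bins as the factor and ROIs (or subjects) as replicates —
df (k−1, k(r−1)), i.e. (4, 30)/(4, 15)/(4, 10) for 7/4/3 replicates at
k = 5 — with no subject-level random effect. Per-depth paired t-tests are
two-sided with Bonferroni factor 2k (10 at k = 5). Latency-by-depth
averages scans within subject, takes bin-averaged Fourier latencies,
subtracts each subject's mean, and applies the same ANOVA.

## Pipeline (`pipeline`, CLI)

One TOML config drives phantom, depth, simulation and analysis; a master
seed spawns per-stage and per-session seeds. The manifest records the
config snapshot, seeds, stage timings and SHA-256 digests of every output;
an identical completed run is skipped on re-execution, and deterministic
CSV formatting makes reruns byte-identical. The library is the primary
interface; the `laminarpy` CLI is a thin wrapper for shell use.

## What the phantom does and does not show

The generator reproduces the *structure* of the laminar problem: matched
surfaces with curvature, continuous depth sampling at 0.7 mm, block-design
dynamics through a canonical HRF, depth-dependent amplitude/latency/bias,
sampling blur, and temporally autocorrelated noise. It does not attempt
realistic gyral topology, physiological (cardiac/respiratory) noise, motion,
susceptibility distortion, registration error, or draining-vein geometry
beyond a monotone baseline bias. Passing tests therefore demonstrate that
the analysis chain is correct and calibrated under its stated assumptions —
not that those assumptions exhaust real 7T data. Two further limitations
worth naming: rotation scrambling preserves per-aperture RMS contrast only
up to interpolation error, and apertures whose content merely grazes the
aperture boundary can show relative contrast changes of several percent
(the preserved quantity is the across-aperture mean); and with few distinct
GM depth values (a flat slab at coarse voxels) equally-populated bins split
tied depths arbitrarily, which is why curved phantoms — with continuous
depth distributions — are used wherever a test depends on fine depth
structure.
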