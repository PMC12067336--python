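# Methods

This note documents the models implemented in `n2ibone`, the defaults and
why they were chosen, what the synthetic data does and does not emulate,
and the numerical conventions that matter for reproducing results.

## Bone phantom (`n2ibone.phantom`)

The phantom is a 3D grid of linear attenuation values at 24 keV with
1.6 µm voxels. A rectangular cortical-bone prism spans the axial extent
and a centered fraction (default 0.78) of each transverse axis; a water
bath fills the remainder; one alumina cylinder of known density
(3.95 g cm⁻³) sits in the bath as a mineral-calibration reference.
Attenuation coefficients come from packaged µ/ρ constants (log-log
interpolation of the NIST tables at 24 keV; user-overridable): water
0.573, alumina 1.376, hydroxyapatite 2.317, cortical bone
2.441 cm² g⁻¹. The matrix gray level is (µ/ρ)ₕₐ × 1.226 g cm⁻³, so the
default calibration maps it to 1226 mgHA cm⁻³, the healthy-bovine
reference.

Lacunae are non-overlapping ellipsoids with uniformly random orientation
(random unit quaternion). True volumes are lognormal with analytic mode
393 µm³ (σ_log = 0.55), truncated to 150–1800 µm³; aspect ratios
(shortest/longest semi-axis, middle axis at the log-midpoint) are normal
with mean 0.46, σ = 0.07, truncated to (0.30, 0.62). The low volume
cutoff keeps every lacuna at ≥ ~36 voxels so discretization error stays
within 15%. Voxelization is 3× supersampled per axis (a voxel belongs to
a lacuna when ≥ half its 27 sub-samples fall inside); placement rejects
any candidate whose one-voxel 26-neighborhood touches an existing lacuna,
so 26-connected labeling can never merge two lacunae. The number density
of lacunae is a free parameter (default 150 in the 64×192×192 grid); the
underlying tissue value is not well constrained.

Known limitations: no Haversian canals, canaliculi, microcracks or
partial-volume gradation at interfaces (attenuation is piecewise
constant), and the bone cross-section is rectangular rather than the
machined-sample geometry. Aspect ratios measured from binary voxel masks
carry an irreducible discretization error at 1.6 µm: on the default
phantom the voxel-moment estimate agrees with the analytic value within
0.05 for lacunae ≥ ~500 µm³ and at the 95th percentile overall, but
individual small lacunae can deviate by up to ~0.07.

## Forward model (`n2ibone.forward_model`)

Projection is the discrete Radon transform per axial slice (parallel
beam, angles in [0, π), equally spaced, half-open), with line integrals
in µ·mm so reconstructions come back in mm⁻¹. Noise is Poisson photon
counting: N ~ Poisson(I₀·e^(−p)) per detector bin, converted back with
−ln(max(N,1)/I₀); the clamp at one count avoids infinities on fully
absorbed rays. Dose reduction is **only** angular subsampling at constant
per-projection exposure — a 1/n dose keeps rows 0, n, 2n, …, i.e.
ceil(N/n) projections, which reproduces the projection counts
{3937, 1969, 1313, 985, 657} for fractions {1, 2, 3, 4, 6}.

The default photon budget I₀ = 20 000 expected counts per bin is
synthetic: the per-projection budget of real beamline scans is unknown. It was
chosen once so that the desk-scale reconstructions reproduce the
qualitative regime the pipeline targets — the raw FBP (even at full dose) cannot
be usefully segmented with an automatic threshold, while the denoised
output can. Beam hardening, scatter, detector blur and ring artifacts are
not modeled.

## Reconstruction and splitting (`n2ibone.recon`)

FBP uses a ramp (Ram-Lak) filter by default (Shepp-Logan window by
argument), no reconstruction-circle mask (the bath fills the field of
view), and scikit-image's Radon/inverse-Radon pair behind the module
surface with unit scaling to mm⁻¹. Sinogram splitting takes every Kth
angle; sizes differ by at most one, the extra angle goes to split 0.

Two baselines are provided for comparison: a sliding-window median filter
and single-distance Paganin phase retrieval, implemented as the Fourier
low-pass 1/(1 + (λ·R·δ/(4πβ))·|k|²) on transmission images followed by
−log, with δ = 1.1378×10⁻⁶ and β = 4.8945×10⁻⁹ (hydroxyapatite at
24 keV). The propagation distance has no packaged default; it is a
required user parameter.

## Noise2Inverse (`n2ibone.n2i`, `n2ibone.msdnet`)

For K = 2 both orderings (A→B, B→A) are used as training pairs (a flag
restricts to one); for K > 2 each leave-one-out assignment uses the mean
of the other K−1 sub-reconstructions as input. Inputs are slabs of
adjacent slices (default 5, odd) centered on the target slice, with slice
indices reflected at the volume boundary (slab 5 at slice 0 reads
2,1,0,1,2). Pair count is K × n_slices.

The network is a mixed-scale dense CNN written in NumPy: one channel per
layer, dense connections to all previous channels (input slab included),
3×3 kernels with dilations cycling 1…10, ReLU, and a learned 1×1
combination of every channel as output. Convolutions are zero-padded
shifted sums contracted by BLAS in float32; training is plain Adam on MSE
at learning rate 10⁻³ (Adam is the de-facto choice for this regime).
Batch size is 12. Default depth is 20 layers —
the full-scale reference protocol uses 100, which is not desk-scale; the
architecture is swappable behind the estimator contract
(`predict_volume`). Inputs and targets are normalized by the global
training-set mean/std, stored in the model so inference is
self-contained. The 80–20 train/validation split is by contiguous
trailing slice blocks (random slices would leak information between
adjacent, highly correlated slices). Training runs a fixed epoch count
(default 100; 30 in the desk configurations) and keeps the
best-validation-epoch weights; epoch 0 of the log is the untrained
network. Training is bit-reproducible for a fixed seed and thread count.

`Noise2InverseDenoiser` follows the scikit-learn estimator idiom
(`fit`/`transform`, `get_params`/`set_params`, trailing-underscore fitted
attributes); `train`/`denoise` are functional wrappers.

## Quantification (`n2ibone.quantify`)

Segmentation thresholds (Yen default; Otsu for segmentability checks) are
computed on 256-bin histograms, mirroring the common ImageJ
implementations. Lacunae are labeled with 26-connectivity; particles are
filtered to 50–2000 µm³ inclusive, in physical units (voxel volume
4.096 µm³ at 1.6 µm). Aspect ratio is interpreted as the ratio of
shortest to longest principal axis = √(λ_min/λ_max) of the voxel-
coordinate covariance (+ voxel self-variance s²/12 on the diagonal); this
gives 0.5 for a 2:1:1 ellipsoid and 1.0 for a sphere, matching the
rod-vs-sphere language of the field; the raw eigenvalue ratio is
available by flag.

Distribution modes are the argmax of a Gaussian KDE (Silverman bandwidth
by default) on a 512-point grid over the data range — modes are reported
to µm³ precision, finer than any reasonable histogram bin. Note that
Silverman's bandwidth depends on n, so exact mode invariance under sample
duplication requires an explicit bandwidth.

Mineral calibration: apparent density of each reference region = mean
gray / (µ/ρ) of its material; a least-squares line (exact through two
points) maps apparent to known densities and is applied to all gray
values through (µ/ρ) of hydroxyapatite, in mgHA cm⁻³. In the pipeline
the references are measured on the **plain FBP** reconstruction and the
map is applied to the denoised volume: reference regions are large and
homogeneous, so their FBP means are unbiased, whereas a small MSE-trained
network can suppress a rare high-contrast inclusion it has hardly seen
during training.

The paired comparison runs Shapiro–Wilk on the differences and Levene
across groups (reported, never gating) and a two-sided paired t-test;
zero-variance differences return a flagged degenerate result rather than
an error.

## Dose budgeting (`n2ibone.dosecalc`)

Absorbed dose per scan follows the standard energy-fluence model
D = N_inc·E·(1 − e^(−µt))/m with every factor exposed in
`BeamlineParams`; dose is exactly proportional to the projection count.
The `insitu_bone_geometry` preset (3.28 mm² region of interest, 1 mm bone
thickness, 24 keV, 100 ms, 3937 projections) solves for the effective
flux density that makes a full scan deposit 8.0 kGy; the result,
~2.7×10⁴ photons s⁻¹ µm⁻², falls inside the in-situ chamber effective range
(25 300–137 000). Scans-before-damage is floor(35 kGy / dose) computed
from the *unrounded* dose: 35/(8/3) = 13.125 → 13, whereas the
display-rounded 2.7 kGy would give 12. Doses are rounded to one decimal
for display only. The budget table derives each fractional dose from the
actually retained projection count ceil(N/n) (e.g. 1969/3937 of the full
dose), keeping it consistent with the forward model's subsampling;
against the idealized full/n this differs by < 0.1%.

## Experiments (`n2ibone.pipeline`)

`run_dose_sweep` runs subsample → split (K = 2) → FBP → train → denoise →
quantify → score-against-clean for each dose fraction of one phantom;
`run_paired_experiment` generates several phantoms with distinct seeds,
trains one network per dose level jointly across samples (per-sample by
flag), and compares per-sample modes with the paired t-test. All
randomness derives from a single config seed through named SeedSequence
children recorded in the manifest; a saved manifest regenerates the
report bit-for-bit. Quantification happens inside a bone-interior region
of interest (margin 4 voxels transversally) so bath artifacts cannot
masquerade as lacunae.

Problem sizes: the desk configuration uses a 16×72×72 phantom with 20
lacunae of 150–700 µm³, 360 angles, and a depth-20/slab-5 network trained
30 epochs — large enough for the dose-trend directions (lower recovered
volume and mineralization modes at one-sixth dose, PSNR gains from
denoising at every fraction) to be stable under the recorded seeds, and
small enough for the whole sweep to run in minutes on one CPU. The
full-scale protocol (1024×1024 windows, depth-100 network, 3937
angles) remain expressible through the same configuration objects.

## What passing tests show — and what they do not

The synthetic phantom has piecewise-constant attenuation, perfectly known
geometry, ideal parallel-beam physics and independent Poisson noise.
Passing tests therefore demonstrate the correctness of the pipeline's
arithmetic, the self-supervised training mechanics, and the *direction*
of dose-induced feature distortion. They do not certify magnitudes on
real beamline data, where sample-larger-than-field-of-view truncation,
phase contrast, correlated detector noise and attenuating media produce
additional, structured noise. Desk-scale magnitudes of the dose trend are
exaggerated relative to the full-scale protocol (a depth-20 network on a
72-pixel window distorts small features more than a depth-100 network on
a 1024-pixel window).
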