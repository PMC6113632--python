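# Methods

## Overview

The package analyzes microstructural remodeling of the infarct border zone
(BZ) from two co-registered ex vivo MRI contrasts: a high-resolution late
gadolinium enhancement (LGE) volume (0.33 mm isotropic) that localizes scar
by hyperenhanced signal intensity (SI), and a diffusion-weighted stack
(1×1×3 mm; one b=0 volume plus 30 directions at b = 1,000 s/mm²) from which
per-voxel diffusion tensors are fit. Because no imaging data is deposited
with the source study, a synthetic phantom generates both contrasts with
known ground truth; the phantom is first-class, tested code and defines the
conditions under which the pipeline's recovery properties are demonstrated.

## Tensor model and invariants

Tensors are fit per voxel by ordinary least squares on the log-transformed
Stejskal–Tanner model, `ln(S_i/S_0) = −b·gᵢᵀD gᵢ`, over the six unique
components of symmetric D. Voxels with `S_0` at or below the noise floor or
any non-positive `S_i` cannot be log-transformed; they are masked invalid
rather than clamped, because clamping biases ADC. No positive-definiteness
is enforced after fitting: negative eigenvalues at extreme noise are kept
and flagged, matching a plain least-squares reading of the reconstruction.
Weighted least squares is deliberately not used.

From D the three orthogonal invariants are ADC = tr(D)/3, FA =
√(3/2)·‖Ã‖_F/‖D‖_F and mode = 3√6·det(Ã/‖Ã‖_F), with Ã = D − ADC·I the
deviatoric part. Mode is ill-conditioned as Ã → 0, so tensors whose
deviatoric norm is negligible relative to ‖D‖ (relative threshold 1e−9) are
treated as isotropic: FA = 0, mode = NaN, and NaN mode is excluded from all
downstream statistics.

The phantom needs the inverse map. Writing `ñ = ADC·FA·√(3/(3/2 − FA²))`
for the deviatoric norm and `θ = arccos(mode)/3`, the eigenvalues

    λ_i = ADC + ñ·√(2/3)·cos(θ − 2π(i−1)/3),   i = 1, 2, 3

are exactly the inverse of the forward invariant computation: the three
cosines sum to 0 (trace), their squares sum to 3/2 (deviatoric norm), and
`4·cos t·cos(t−2π/3)·cos(t+2π/3) = cos 3t` returns the mode. The round trip
is verified to 1e−10 over a grid of the invariant space.

## Synthetic phantom

**Geometry.** An LV annulus (default inner/outer radius 18/30 mm) on a
96×96×16 grid at 1×1×3 mm, empty below an apex slice so through-plane
registration has a landmark. The infarct is an angular wedge (default 80°
at the inferior wall, transmural, slices 4–12), matching the predominantly
inferior/inferoseptal infarct location the occlusion model produces. The BZ
is the shell of myocardium within 3 mm (Euclidean, in mm) of the infarct.

**Invariant fields.** Per region, each invariant is drawn through a latent
Gaussian field: white noise is smoothed with a separable Gaussian of
σ = L/2 voxels per axis — a Gaussian kernel of width σ has autocorrelation
`exp(−k²/4σ²)`, which crosses 1/e at k = 2σ, so the 1/e autocorrelation
length equals the target L — then renormalized to unit variance and mapped
through a distribution chosen to respect each invariant's support:
log-normal for ADC, logit-normal for FA, clamped normal for mode, each with
median equal to the region median. Monotone transforms preserve the median
exactly (so the generated per-region medians equal the targets regardless
of dispersion) and approximately preserve the 1/e length. Default region
medians are the pooled literature-calibrated values
(ADC ×10⁻³ mm²/s / FA / mode): normal 0.563/0.470/0.743, remote
0.573/0.464/0.666, BZ 0.647/0.417/0.621, infarct 0.797/0.330/0.515.
Default 1/e lengths (x, y, z voxels): remote and normal 3.0/3.0/1.8, BZ
1.2/1.2/1.1, infarct 1.7/1.7/1.2.

**Dispersions.** The source tables report medians and CIs of medians, not
voxelwise spreads, so the dispersions are free parameters of this package:
ADC log-SD 0.10, FA logit-SD 0.15, mode SD 0.08. They were chosen once as
plausible tissue heterogeneity at these resolutions and are not presented
as measured values.

**Eigenvectors.** The primary eigenvector follows a transmural helix angle
interpolating linearly from +60° (endo) to −60° (epi), the standard
ventricular convention; the secondary eigenvector is the in-plane radial
direction. Eigenvector statistics are outside the analysis scope, so any
smooth, anatomically plausible field suffices.

**Images.** DWI signals follow `S_i = s0·exp(−b gᵢᵀD gᵢ)` with Rician
noise `√((S+n₁)² + n₂²)`, n ~ N(0, σ). SNR is defined throughout the way
it is measured: mean tissue signal divided by the SD of an equal-area
background ROI. A pure-noise Rician background is Rayleigh with SD
0.655σ, so σ = (s0/SNR)/√(2−π/2), which makes the measured SNR equal the
nominal one (default 59 for DWI, 10 for LGE). LGE tissue SI is
Normal(region mean, SD) with plateaus remote 100±10, BZ 180±15, infarct
300±30 a.u. — values chosen (the source reports only low/intermediate/high)
so the background SD implied by SNR 10 equals the remote SD and the
threshold rules separate the plateaus cleanly. The whole LGE frame is
rigidly translated by a configurable offset for the registration stage to
recover.

## LGE segmentation

Per-heart seed ROIs (in the phantom: ground-truth remote and infarct
regions eroded by one voxel, standing in for hand-drawn ROIs) give the SI
mean/SD of remote and infarct. The infarct threshold is halfway between
the two means; the BZ floor is the remote mean plus two remote SDs.
Boundary conventions are fixed: SI ≥ t_half → infarct, t_bz < SI < t_half
→ BZ, SI ≤ t_bz → remote. Labels are down-sampled to the DT-MRI grid by
converting each label to a binary indicator, block-averaging through-plane
to the DT-MRI slice thickness, bicubic-resampling in-plane, and assigning
each voxel the label with the largest resampled fraction; exact ties break
toward the more severe label (infarct > BZ > remote > background).
Refinement then (1) dissolves 6-connected infarct components of ≤3 voxels
into BZ — the destination is BZ, not background, preserving the
intermediate-SI interpretation — and (2) relabels BZ voxels more than 3 mm
(Euclidean in mm, reconciling "three voxels (3 mm)" for 1 mm in-plane /
3 mm through-plane voxels) from surviving infarct to remote. Refinement is
idempotent.

## Registration

The LGE-derived myocardium mask is registered to the b=0-derived DT-MRI
myocardium mask by integer-voxel rigid translation only: through-plane by
aligning the most apical nonempty slice, then in-plane by the single
global (dx, dy) maximizing the sum over slices of the 2D cross-correlation
of the binary masks (FFT-computed, search window ±¼ grid, ties broken
toward the smallest shift norm then lexicographically). Sub-voxel true
offsets register to the nearest integer; interpolating labels would create
mixed classes. The DT-MRI myocardium mask itself is an intensity threshold
on the b=0 volume (fraction of the 99th percentile, largest connected
component) — a deliberate stand-in for tensor-based myocardial
segmentation, adequate because the susceptibility-matched bath is nearly
signal-free.

## Decorrelation

Per region and axis, the ACF at lag k is the region-mean-subtracted,
region-variance-normalized mean product over in-mask voxel pairs k apart;
lags with <30 pairs are truncated. The correlation length is the first 1/e
crossing, linearly interpolated and rounded to the nearest integer ≥1
(x and y share one rounded length). Each invariant map is then decimated
on a lattice anchored at the region bounding-box minimum. Strides are
estimated per invariant by default (a config switch shares the ADC strides).

A structural caveat: decimating a Gaussian-ACF field at exactly its 1/e
length leaves, by definition, ≈1/e ≈ 0.37 correlation between adjacent
retained samples (measurement-noise dilution brings the observed value to
≈0.28 for remote ADC). Decimation by the autocorrelation length therefore
reduces, but does not eliminate, residual correlation; the retained
samples are "approximately independent" only in that sense. Strides of
about twice the 1/e length would be needed to push residual lag-1
correlation below 0.2, at the cost of most of the sample size. The
pipeline implements the stated rule.

## Bootstrap statistics

All resampling is seeded and reproducible. Histograms use 32 equal-width
bins spanning the pooled min/max of the two compared groups, 1,000
resamples, and per-bin 95% percentile CIs; disjoint CIs within a bin flag
a significant difference in that invariant range. Median CIs are
percentile bootstrap (1,000 resamples). The two-group median comparison
resamples each group independently (10,000 resamples); the two-sided p is
twice the smaller tail of the bootstrap differences about zero, floored at
1/(1+B). Percentile (not BCa) intervals are used as the simplest
defensible choice.

The repeated-measures ANOVA analog is this package's documented
construction (the source cites a method without formulas): each
(heart, region) cell is summarized by its median; the observed statistic
is the classical within-subject F on the hearts × regions median table,
`F = MS(region)/MS(heart×region residual)`; the null distribution removes
the region effect within each heart (subtract the cell median, add the
heart's overall median — preserving between-heart effects), resamples each
cell with replacement, and recomputes cell medians and F 10,000 times;
`p = (1 + #{F* ≥ F_obs})/(1 + B)`. The construction is validated by its
type-I error rate (0.04–0.05 at α = 0.05 in simulation) and the observed F
is cross-checked against an independent repeated-measures ANOVA
implementation.

## Problem sizes and reproducibility

All randomness flows from one root seed through named substreams (phantom
geometry noise, DWI noise, LGE noise, rigid offsets, each bootstrap
routine), so identical configs give byte-identical reports and any stage
can be rerun in isolation. The shipped analyses use desk-scale problem
sizes — single hearts at 96×96×16 (the default grid, which yields ≳1,500
decorrelated remote ADC samples per heart), studies of 3–7 hearts per arm —
chosen so the whole suite runs comfortably on one CPU.

## What the phantom does and does not show

Passing recovery tests on the phantom demonstrates that the pipeline's
estimators are unbiased and its rules correct *under the generator's
assumptions*: Gaussian-smoothed stationary invariant fields, exact SI
plateaus, a rigid inter-frame offset, Rician noise, and a clean bath. Real
ex vivo data adds features the phantom deliberately omits: eddy-current
and EPI distortion, coil inhomogeneity, partial-volume mixtures at region
boundaries with graded (not plateau) SI, non-stationary correlation, and
anatomically irregular infarct shapes. Recovery on the phantom is
therefore necessary, not sufficient, evidence for performance on real
acquisitions.

## Known limitations

- Myocardial segmentation from the b=0 intensity threshold assumes a
  signal-free background; it is not a substitute for anatomical
  segmentation on in vivo data.
- Registration is translation-only; rotations or deformations are out of
  scope.
- Residual post-decimation correlation (above) makes per-bin histogram CIs
  and median CIs slightly anti-conservative.
- The ANOVA analog's null construction is exchangeable over hearts but
  assumes cell medians are the right summary; very small cells (<5
  samples) are rejected rather than modeled.
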