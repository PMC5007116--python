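# Methods

This note documents the models, defaults and design choices behind `pkpet`,
and what its synthetic validation does and does not establish about real
TSPO PET data.

## Forward kinetics

Tissue curves are generated from the two-tissue compartment model with rate
constants K₁ [mL/cm³/min], k₂ (free-compartment efflux), k₃/k₄ (exchange with
the specifically bound compartment, so BP_ND = k₃/k₄) and fractional blood
volume V_b. The solution uses the analytic bi-exponential impulse response
obtained from the eigenvalues of the 2×2 rate matrix rather than ODE
stepping; a fine-step Runge–Kutta integration exists in the test suite as an
independent oracle. Convolutions are evaluated with a piecewise-linear
recursive scheme (exact for linear segments, with a series expansion of the
coefficients when rate·Δt < 10⁻⁴ to avoid cancellation), on a uniform
internal grid of 0.5 s. Computing continuous kinetics on this fine grid and
frame-averaging afterwards keeps convolution accuracy independent of the
frame schedule.

The plasma input is a tri-exponential bolus (Feng form) with defaults
A₁ = 851.1 kBq/mL/min, A₂ = 21.9, A₃ = 20.8 kBq/mL, λ₁ = 4.134, λ₂ = 0.1191,
λ₃ = 0.0104 min⁻¹ and a 0.5-min arrival delay — standard textbook bolus
pharmacokinetics, fully configurable since no published input function is
being reproduced. Whole blood defaults to the plasma curve (no metabolite or
plasma-to-blood modelling; metabolite correction is explicitly out of scope).

The acquisition covers 60.5 min in 22 frames
(1×30, 6×5, 3×10, 4×60, 2×150, 2×300, 4×600 s — a conventional
back-loaded dynamic schedule, configurable). Frame values are means of the
continuous curve over the frame (trapezoid on the internal grid; adaptive
quadrature for callable curves, which is exact for linear integrands).

Simulated TACs are decay-corrected, as reconstructed clinical images are;
radioactive decay enters only the noise model. Frame noise is zero-mean
Gaussian with SD = α·√(C/(Δt_min·2^(−t/20.4 min))) — the standard surrogate
for reconstructed-image noise, growing for short and late frames. α = 0.3 is
used as the "noisy" operating point throughout; it produces roughly 5–15%
relative noise on late-frame gray-matter values at the default activity
scale, and keeps the voxelwise fits well-posed (Poisson counting on the
sinogram level is deliberately not modelled).

## Kinetic classes and phantoms

The four supervised-cluster classes use these default parameters
(per minute; V_b unitless):

| class                  | K₁   | k₂   | k₃   | k₄   | V_b  | BP_ND |
|------------------------|------|------|------|------|------|-------|
| gray, specific binding | 0.10 | 0.20 | 0.04 | 0.08 | 0.03 | 0.5   |
| gray, no binding       | 0.10 | 0.20 | 0    | 0    | 0.03 | 0     |
| white matter           | 0.05 | 0.12 | 0    | 0    | 0.02 | 0     |
| blood                  | 0    | 0    | 0    | 0    | 1.00 | —     |

These are chosen once as PK11195-scale values: slow specific-binding exchange
(k₃ well below k₂), delivery and washout roughly halved in white matter, and
small cortical blood volume. With them, the SRTM approximation error of the
full voxelwise fit on noiseless phantoms is small (median |ΔBP_ND| ≈ 0.013 in
the specific-binding class); the residual bias is the well-known consequence
of fitting two-tissue data, whose reference curve carries a blood-volume
share, with a reference-tissue model. Note that for white matter the SRTM
outcome is DVR − 1 = (K₁/k₂)/(K₁'/k₂') − 1 ≈ −0.17 rather than k₃/k₄ = 0:
when non-displaceable distribution volumes differ between target and
reference, that offset is a property of the model, not a defect of the fit.

The default phantom is a 32×32×16 grid of 2×2×2 mm voxels with an
ellipsoidal brain mask: a central blood pool (normalized radius < 0.20), a
white-matter shell (< 0.55) and a cortical ribbon split between the two gray
classes on a voxel-parity checkerboard, so that both gray classes are
spatially interleaved as they are in cortex at PET resolution. Class
templates for the decomposition are generated from the declared class
kinetics (a template TSV can be substituted for real data; deriving
population templates from scans is out of scope).

## SVCA4 reference extraction

Voxel TACs inside the anatomical mask are normalized to unit trapezoid area
(shape, not scale, carries the kinetic information; voxels with non-positive
area are excluded) and decomposed onto the four templates by non-negative
least squares — weights are mixture proportions, so the non-negativity
constraint is the physiologically meaningful choice; unconstrained least
squares is available behind a flag. The reference input is the
class-weight-weighted mean of the **raw** TACs of the selected voxels, so it
keeps absolute units.

Selection policy: the published SVCA literature does not fix a threshold, so
both a top-fraction rule (default: top 10% of in-mask voxels by
no-binding-gray weight, at least 50 voxels) and an absolute weight-share
threshold are exposed. Weight-weighted averaging over a top fraction
degrades gracefully with noise; at α = 0.3 on the default phantom the
selected set is ≥ 90% pure reference-class voxels.

## RPM-V_b fitting

The basis holds C_r ⊗ e^(−θ₃t) for 64 logarithmically spaced θ₃ in
[0.006, 0.6] min⁻¹, which brackets k₂/(1+BP_ND) for plausible PK11195
kinetics; basis curves are computed by fine-grid convolution of the
(zero-anchored, linearly interpolated) reference and then frame-averaged.
For each θ₃ the model

    C_t ≈ θ₁·C_r + θ₂·B(θ₃) + θ_v·C_b

is solved by weighted linear least squares (frame weights default to
duration × decay, ∝ Δt·2^(−t/20.4 min); uniform weights selectable), and the
θ₃ with minimal weighted RSS wins, ties resolving deterministically to the
smallest grid index. Tissue parameters are reported after removing the
blood-volume share of the signal:

    V_b = θ_v (clamped to [0, 1)),  R₁ = θ₁/(1 − V_b),
    k₂ = θ₂/(1 − V_b) + R₁θ₃,       BP_ND = k₂/θ₃ − 1.

The (1 − V_b) rescaling is the package's default because it makes the fit an
exact inverse of the vascular-corrected forward model: on noiseless data the
generator's (BP_ND, V_b) are recovered to within one θ₃ grid step and 0.005
respectively. The raw-coefficient convention (tissue parameters taken from
θ₁, θ₂ directly) is available with `rescale=False`. Negative BP_ND estimates
are retained — clipping would bias group means that sit near zero, exactly
the regime of TSPO case-control data. All-zero voxels are flagged degenerate
(NaN in maps); a grid-endpoint optimum is flagged `boundary`.

For real data the blood curve would come from the SVCA blood class
(`blood_source="svca"`); synthetic runs may use the true whole-blood curve.
ROI values default to means of the voxelwise BP_ND map over the composite
region (matching a parametric-mapping workflow); fitting ROI-averaged TACs
is equally supported and is the fast path for replicated experiments.

A note on grid refinement: log-spaced grids with n and 2n points do not
nest, so "more basis functions never worsen the fit" holds in the nested
sense — refining n points to 2n−1 (which contains the original grid) can
only decrease the minimal RSS; that is the property the tests check.

## ROI aggregation and statistics

Composite ROIs are volume-weighted averages of anatomical subregions
(7 frontal, 8 temporal, 4 parietal, caudate + putamen, thalamus; total gray
is the union of all 21), with NaN voxels excluded together with their volume
share. In phantoms, subregion labels partition the specific-binding gray
voxels.

The statistical battery: one-way fixed-effects ANOVA (also reconstructible
from printed group means/SDs/sizes, which is exactly equivalent on
moment-matched data); ANCOVA as the extra-sum-of-squares F for the group
term in value ~ group + age (single-df type-III term, df (1, n−3)); MANOVA as
Wilks' Λ = det(E)/det(E+H) for the group contrast across the five regional
ROIs with age covariate, converted exactly to F on (p, v_e−p+1) df for the
single hypothesis df (implemented directly from the SSCP matrices;
statsmodels' MANOVA serves as an independent oracle in the tests); classical
mean-centered Levene (Brown–Forsythe median-centering behind a flag); Pearson
correlation with the t-based two-sided p; Pearson χ² **without** continuity
correction on the 2×2 gender table (with Yates' correction the statistic for
a 14/3 vs 16/3 split would collapse to ≈ 0.00 rather than 0.02); Bonferroni
adjustment min(1, p·m); and the two-group sample size

    n = ⌈(z₁₋α/₂ + z_power)²(σ₁² + σ₂²)/(μ₁ − μ₂)²⌉

under the normal approximation. The normal approximation, not the
noncentral-t, is the deliberate choice: for the reference design
(μ = 0.07 vs 0.18, σ = 0.10/0.08, α = 0.01, 80% power) it gives n = 16,
whereas the noncentral-t inflates this to ≈ 18. All group tests are
two-sided.

## Cohort emulation

The default cohort reproduces a 17-control / 19-patient case-control design:
per-ROI BP_ND drawn from group-specific normal distributions
(e.g. total gray 0.14 ± 0.09 vs 0.17 ± 0.09), ages N(26, 4²) clipped to
[20, 34], gender (14/3, 16/3), nicotine and cannabis flags as fixed margins
rather than Bernoulli draws (so the demographic table is reproduced
exactly), injected dose / specific activity / injected mass as group
normals, and PANSS totals for patients only. Per-subject ROI values share a
common subject factor giving inter-ROI correlation 0.8 by default — TSPO
binding varies far more between subjects than between regions within a
subject, so regional values are strongly coupled; the split of the printed
group SDs into biological versus measurement variance is not identifiable
from summary data and is a free simulator parameter. Negative BP_ND draws
are permitted (truncation off by default), consistent with reference-tissue
estimates near zero.

## Null calibration and problem sizes

`null_calibration` replays the full chain — draw equal-mean cohorts,
forward-simulate region-level TACs, add frame noise, fit RPM-V_b, run the
group ANOVA — 1000 times and reports the rejection rate at α = 0.05; the
suite requires it to fall in [3%, 7%]. Region-level TAC fitting stands in
for full volumes here because the voxel dimension multiplies cost without
adding information to a test of statistical calibration. With the default
sizes (22 frames, 0.5-s internal grid, 64 basis functions, 36 subjects per
replicate) the 1000 replicates take ~12 s on one CPU; the volumetric
pipeline fits a 32×32×16 phantom per subject in about half a second.

## What the synthetic validation does not show

The simulator draws voxels from four discrete kinetic classes with spatially
homogeneous parameters; real gray matter has continuous kinetic gradients,
partial-volume mixing at boundaries (no partial-volume correction is
applied anywhere in the chain), subject motion, attenuation/scatter residuals
and reconstruction-correlated noise, none of which are modelled. Passing
recovery tests therefore demonstrates the correctness and calibration of the
estimation chain under its own model assumptions — not the accuracy of SVCA4
or RPM-V_b on clinical scans, where reference-region contamination by
specific and endothelial binding is the dominant, and here only partially
represented, error source. Age–BP_ND correlation within groups is not
simulated by default, so covariate adjustment is exercised for calibration,
not for confound removal.
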