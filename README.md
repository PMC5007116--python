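# pkpet

Reference-tissue quantification of (R)-[¹¹C]PK11195 dynamic PET, packaged as a
tested, reproducible pipeline.

PK11195 binds the 18 kDa translocator protein (TSPO), whose expression rises
with microglial activation; TSPO PET is the standard in-vivo window on
neuroinflammation. Because no brain region is devoid of TSPO, there is no
anatomical reference region, and quantification instead relies on a
*supervised cluster analysis* (SVCA4) that extracts a reference input from
gray-matter voxels without specific binding, followed by a basis-function
implementation of the *simplified reference tissue model* (SRTM) with a
vascular correction (RPM-V_b) that produces voxelwise maps of the
non-displaceable binding potential BP_ND. `pkpet` implements that whole
chain — plus the dynamic-PET simulator needed to exercise it without access
to clinical scans — for methods researchers who want to study the behaviour
of TSPO reference-region quantification and the statistical power of
case-control designs built on it.

## The models

**Simulator.** Voxel time-activity curves (TACs) follow the two-tissue
compartment model against a tri-exponential bolus plasma input C_p(t):

    dC₁/dt = K₁ C_p − (k₂ + k₃) C₁ + k₄ C₂,   dC₂/dt = k₃ C₁ − k₄ C₂,
    C_t = (1 − V_b)(C₁ + C₂) + V_b C_b,        BP_ND = k₃/k₄

solved analytically via the bi-exponential impulse response, frame-averaged
over a 22-frame, 60.5-min acquisition, with Gaussian frame noise whose
variance follows count statistics (∝ 1/(Δt·2^(−t/20.4 min)) for carbon-11).
Four kinetic classes are simulated: gray matter with specific binding, gray
matter without specific binding, white matter, and blood.

**SVCA4.** Each within-mask voxel TAC is normalized to unit area and
decomposed by non-negative least squares onto the four class templates; the
reference input is the weight-weighted mean of the raw TACs of the voxels
scoring highest on the no-binding gray class.

**RPM-V_b.** For each candidate θ₃ on a log grid, the SRTM

    C_t(t) = R₁ C_r(t) + (k₂ − R₁θ₃)(C_r ⊗ e^(−θ₃t))(t),   BP_ND = k₂/θ₃ − 1

is linear; the vascular correction adds the whole-blood curve as a third
column, and the best θ₃ is chosen by weighted residual sum of squares,
yielding BP_ND, R₁, k₂ and V_b maps.

**Statistics.** Composite volume-weighted ROIs (total gray, frontal,
temporal, parietal, striatum, thalamus), one-way ANOVA / age-adjusted ANCOVA
per ROI, MANOVA (Wilks' Λ) across the five regional ROIs, Levene's variance
test, Pearson correlations, gender χ², Bonferroni correction, and the
two-group sample-size calculation n = (z₁₋α/₂+z_power)²(σ₁²+σ₂²)/(μ₁−μ₂)².

## Worked example

```python
from pkpet import (PowerSpec, sample_size_two_groups, chi2_2x2,
                   PipelineConfig, run_pipeline)

n, power = sample_size_two_groups(PowerSpec(mu1=0.07, mu2=0.18,
                                            sigma1=0.10, sigma2=0.08, alpha=0.01))
print(f"required sample size per group: {n} (achieved power {power:.3f})")

chi = chi2_2x2([[14, 3], [16, 3]])
print(f"gender chi-square: {chi.statistic:.2f} (p = {chi.p_value:.2f})")

run_pipeline(PipelineConfig(seed=42, outdir="demo_out"))
```

prints

```
required sample size per group: 16 (achieved power 0.805)
gender chi-square: 0.02 (p = 0.88)
```

and writes a full run (synthetic 17-control / 19-patient cohort, region-level
TAC fitting, group statistics) under `demo_out/`. The per-ROI one-way ANOVA
rows of `demo_out/stats_report.tsv` for this seed:

```
total_gray   F =  0.80  p = 0.38
frontal      F =  0.01  p = 0.93
temporal     F =  0.95  p = 0.34
parietal     F =  0.91  p = 0.35
striatum     F =  0.61  p = 0.44
thalamus     F =  0.45  p = 0.51
```

i.e. at the configured group means and between-subject spread, no region
shows a significant case-control difference — the expected behaviour for a
two-group design of this size given the large intersubject variability of
TSPO binding. Sixteen subjects per group is exactly what the power
calculation above demands to detect a BP_ND difference of 0.07 vs 0.18 with
80% power at α = 0.01.

The same chain is available from the shell:

```sh
pkpet run-all --seed 42 --outdir demo_out
pkpet report --outdir demo_out
```

with `simulate`, `extract-ref`, `fit`, `roi` and `stats` subcommands for the
individual stages (NIfTI volumes + JSON frame timing in, TSV/JSON out).

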