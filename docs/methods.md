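# Methods

## Overview

`rnflcomp` normalizes circumpapillary RNFL thickness profiles for
age, gender, axial length (AL), disc–fovea distance (DFD) and
disc–fovea angle (DFA), so that disease-related thinning stands out
against a tighter normative band. The compensation is trained only on
healthy eyes (normative design) and applied unchanged to new eyes.
A profile is a circular vector of P samples (default P = 768, i.e.
0.469°/sample); index 0 is taken at the temporal horizontal position
with indices increasing superiorly (TSNIT unrolling). This convention
fixes plot orientation only; no computation depends on it.

## Phase 1 — age

Thickness loss with age is treated as relative (a constant fraction per
year), so the model lives in log-thickness (floored at 1 µm, since 0 µm
is legal input in severe atrophy):

    log y_{n,i} ≈ μ_i − ρ_i (a_n − a_ref).

ρ is estimated jointly over all points with a circular
second-difference penalty λ·Σ_i (ρ_{i−1} − 2ρ_i + ρ_{i+1})², encoding
that neighbouring points on the scan circle age alike. With μ profiled
out, the stationarity conditions form a circulant linear system solved
exactly by FFT — no iteration, no tuning. Defaults: a_ref = training
mean age; λ = 10·n (the penalty then scales with the data term).
Degenerate input (all ages equal) raises an error rather than
returning an arbitrary slope.

Whether to compensate raw or log thickness is an implementation choice;
log was chosen because the cited ageing effect is relative (0.3 %/yr)
and because it makes compensation exactly invertible.

## Phase 2 — FCN scale/shift

A fully connected network (4 → 16 → 16 → 2, tanh hidden units) maps the
standardized covariates (AL, DFD, DFA z-scored on the training set;
gender coded 0/1) to a global log vertical scale s and a global
horizontal circular shift δ in index units. Compensation removes the
predicted deformation: `exp(−s) · y(i + δ)` with circular linear
interpolation (higher-order interpolation was rejected to keep the
piecewise-linear oracle checks exact). Output activations are bounded
(s = tanh, |s| ≤ 1; |δ| ≤ P/8), which excludes the degenerate
scale-to-zero solution.

Training minimizes

    L = Σ_i Var_n(c_{n,i}) + γ[(mean_n s_n)² + (mean_n δ_n)²] + ½·w·L₀·ΣW²

by deterministic full-batch Adam (learning rate 10⁻², 2000 iterations,
seeded Glorot initialization for hidden layers, gradients derived
analytically through the interpolation; early stop when the relative
loss change drops below 10⁻⁸; the returned parameters are the
best-loss iterate). Three safeguards matter:

* **Mean-zero projection.** Uniformly down-scaling every profile
  reduces across-subject variance, so the variance loss alone drives
  mean(s) toward the clamp. The applied deformations are therefore the
  network outputs minus their training means (offsets stored with the
  model); the soft penalty γ = 10 keeps the raw means themselves small.
* **Weight decay** (w = 0.01, made dimensionless by multiplying with
  the identity-transform variance L₀). Without it the network, given
  continuous covariates, partially memorizes subject-specific
  variability; with it the fitted s and δ track the true generative
  deformations closely in recovery experiments.
* **Covariate clamping.** At prediction time each z-scored covariate is
  clamped to the range seen in training: the compensation is a
  normative model and is undefined outside the healthy covariate
  support, where a network would extrapolate arbitrarily (glaucomatous
  eyes routinely carry DFD values far beyond the normative range).
* **Zero-initialized output layer.** Iteration 0 is exactly the
  identity transform, so the best iterate can never increase the
  training variance — this makes the stage-wise variance monotonicity
  a structural property rather than an empirical hope.

## Phase 2 — RBFN residual

What a rigid scale/shift cannot remove (peak convergence with axial
elongation, other smooth covariate-linked shape changes) is absorbed by
a radial basis function network with built-in spatial smoothness:

    r̂(x, i) = Σ_k Σ_m v_{k,m} φ_k(x) ψ_m(i),

φ Gaussian kernels at K = 12 k-means centers in standardized covariate
space (shared bandwidth = median inter-center distance), ψ circular
Gaussians at M = 24 equally spaced angular centers (width 1.5 ×
spacing). v solves `min ‖R − Φ V Ψᵀ‖² + α‖V‖²` in closed form via the
eigendecompositions of ΦᵀΦ and ΨᵀΨ (α = 10⁻³·n; α = 0 with a singular
system raises an instructive error). Subtracting r̂ (and clipping at
0 µm) yields the final compensated profile. K = 12 is deliberately
coarse — enough for variance removal while limiting the network's
ability to chase idiosyncratic structure; recovery experiments that
need to reproduce a planted field use a larger K explicitly.

The RBFN conditions on the covariates and is fit to the residuals of
the FCN-compensated profiles about their per-point mean; conditioning
it on the FCN outputs instead was considered and rejected as less
identifiable (the FCN outputs are two numbers; the covariates carry
strictly more information).

## Detection and evaluation

The normative limit is per-point: the empirical 5th percentile
(linearly interpolated order statistic) of the reference profiles, or
mean − 1.645·SD under the Gaussian option. Points exactly at the bound
count as *not* below. The detection score is the longest circular run
of consecutive points strictly below the limit (wrap-around runs
count; all-below scores P). ROC sweeps the integer run length; AUROC
is the trapezoidal area, identical to the Mann–Whitney statistic with
ties ½. Limits are fit on the training normals and reused for the
validation cohort — the alternative (limits from validation controls)
leaks the evaluation data into the detector.

Axial-length subgroups take the ⌈fraction·n⌉ longest eyes (ties broken
by eye id for determinism), keeping both labels, mirroring a
percentile-subgroup analysis. Performance at a fixed run-length
threshold reports accuracy, sensitivity, specificity, PPV and NPV from
the confusion counts; undefined ratios are NaN with the zero
denominator visible in the counts.

## Synthetic cohorts

The generator produces the double-hump TSNIT profile as a baseline
(75 µm) plus two circular-Gaussian arcuate peaks (55 µm at ±70°,
width 25°) and a broad nasal bump (15 µm at 180°, width 75°),
calibrated once so the reference profile averages ≈ 102 µm. Covariate
marginals are truncated Gaussians matching a population-based sample
(normals: age 62.3 (8.9) y, AL 23.18 (0.96) mm, DFD 4.88 (0.27) mm,
DFA 7.59 (3.4)°, 43.4 % male; glaucoma: 69.4 (9.3), 23.77 (1.27),
5.41 (0.82), 8.16 (4.36), 54.3 %), truncated at the observed ranges.

Covariate effects on the profile:

* age: multiplicative (1 − 0.003)^Δage;
* AL: thinning 1.5 %/mm and peak convergence 2.5°/mm, plus a
  hinge-linear acceleration beyond 24 mm (1 %/mm and 5°/mm extra) —
  the myopic regime where peripapillary anatomy changes
  disproportionately and a linear correction is known to fall short;
* DFA: whole-profile rotation, 2.5°/deg (no quantitative literature
  value exists; this placeholder makes the rotation channel a
  substantial, label-neutral, fully compensable distortion);
* DFD: vertical scale −3 %/mm; gender: ±2 %.

Unexplained biological variability — without which normative detection
would be unrealistically easy — enters as a per-eye log-normal overall
thickness factor (SD 0.07), per-peak position jitter (SD 2°) and
amplitude jitter (SD 4 %), plus i.i.d. 6 µm measurement noise.
Glaucomatous eyes additionally receive one cosine-tapered wedge defect
near the arcuate bundles (center |50–90|°, width 10–45°, depth
15–75 %) and diffuse thinning (0–25 %), a severity mix spanning all
disease stages and placing the glaucoma-group mean RNFLT near 85 µm
versus the normative 102 µm.

What the generator does **not** model: parapapillary gamma/delta-zone
optics, retinal vessel positions, OCT speckle and segmentation-failure
artifacts, spatially correlated measurement noise, and any
covariate–covariate interaction beyond the hinge. Passing tests
therefore demonstrate that the pipeline removes the deformations it
models and improves run-length detection under those conditions — not
clinical performance on real OCT data.

## Problem sizes and numerics

The default experiment uses the full study geometry: 2223 training
normals, 254+254 validation eyes, P = 768. Unit and property tests run
at P = 8–128 with a few dozen to a few hundred eyes — the estimators
read P from the data, so nothing is hard-coded to 768. The
variance-monotonicity suite runs five seeds at n = 300, P = 128 with a
400-iteration FCN budget, the property being size-independent.
Tolerances: oracle equivalences at 10⁻⁸ (exact linear algebra),
identities at 10⁻⁹–10⁻¹² (floating point), recovery checks at the
generative truth within 10⁻⁶ (age), r ≥ 0.95 (rotation) and 5 %
relative RMSE (planted residual). Equivariance under rotation of the
training data holds exactly in exact arithmetic and to sub-µm level in
floating point (summation-order differences amplified by the
optimizer).

## Known limitations

* The FCN's horizontal transform is a single global shift; genuinely
  per-point warps are delegated to the additive RBFN stage, which can
  approximate but not exactly represent a warp.
* Run-length detection uses one fixed normative percentile; no
  per-point multiplicity control is attempted.
* AUROC is reported without confidence intervals.
* With strongly non-Gaussian thickness distributions the
  `gaussian_1645` limit option is biased; the empirical percentile is
  the default for that reason.
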