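# rnflcomp

Covariate compensation of circumpapillary retinal-nerve-fiber-layer
thickness (RNFLT) profiles, and run-length normative-limit detection of
glaucoma — with a synthetic-cohort generator for controlled,
fully reproducible experiments.

## The problem

Glaucoma is diagnosed morphometrically from thinning of the
peripapillary RNFL, measured by OCT as a 768-point thickness profile on
a 3.4-mm circle around the optic disc (the double-humped "TSNIT"
curve). The profile, however, also depends on covariates that have
nothing to do with disease: it thins with age (~0.3 %/yr), and in
myopic (axially elongated) eyes the arcuate-bundle peaks converge
toward the temporal raphe, the whole profile rotates with the
disc–fovea angle, and overall thickness drifts with axial length and
disc–fovea distance. Against a population normative band, a healthy
long eye therefore looks abnormal — which is precisely why OCT-based
glaucoma detection deteriorates in high myopia.

`rnflcomp` removes the covariate-attributable deformation in two
phases, then detects glaucoma as a sustained dip below the normative
band:

1. **Age compensation** — per-point relative ageing rates ρ_i are fit
   in log-thickness by penalized least squares with a circular
   second-difference smoothness penalty,
   `min_ρ Σ_{n,i} (log y_{n,i} + ρ_i(a_n − ā) − μ_i)² + λ Σ_i (Δ²ρ)_i²`,
   solved exactly in the Fourier domain (the system is circulant).
   Profiles are rescaled by `exp(ρ_i (age − ā))`.
2. **Scale/shift network (FCN)** — a small fully connected network maps
   (axial length, disc–fovea distance, disc–fovea angle, gender) to a
   global log vertical scale s and a circular horizontal shift δ;
   compensation applies `exp(−s)·y(i+δ)`. Trained full-batch to
   minimize the across-subject per-point variance of the compensated
   profiles.
3. **Residual RBFN** — a radial-basis-function network, Gaussian in
   covariate space and circular-Gaussian in angle, absorbs the smooth
   covariate-correlated structure a rigid scale/shift cannot (e.g.
   peak convergence); its coefficients solve a ridge least-squares
   problem in closed form.

Detection: an eye scores the length of its longest circular run of
consecutive points strictly below the one-sided 95 % lower normative
limit (per-point empirical 5th percentile of healthy reference
profiles). Sweeping the run length gives the ROC curve; AUROC equals
the Mann–Whitney probability with ties counted ½.

All estimators are scikit-learn style (`fit`/`transform`,
`get_params`, fitted attributes with trailing underscores) and operate
on a DataFrame holding the profile columns `p0..p{P−1}` plus the
covariate columns, so they compose with sklearn pipelines.

## Worked example

```python
from rnflcomp import RunConfig, run_experiment

report = run_experiment(RunConfig())   # seed 0; ~5 min on one core
for frac, block in report["subgroups"].items():
    print(f"top {frac}: AUROC {block['original']['auroc']:.3f} -> "
          f"{block['compensated']['auroc']:.3f} "
          f"(gain {block['relative_auroc_gain_pct']:+.1f}%), "
          f"|comp| {block['mean_absolute_compensation']:.2f} um")
```

prints

```
top 0.1: AUROC 0.950 -> 0.994 (gain +4.6%), |comp| 10.55 um
top 0.2: AUROC 0.954 -> 0.994 (gain +4.2%), |comp| 10.13 um
top 0.3: AUROC 0.962 -> 0.981 (gain +1.9%), |comp| 9.93 um
top 1: AUROC 0.970 -> 0.985 (gain +1.6%), |comp| 8.91 um
```

Reading: on the default synthetic validation cohort (254 glaucomatous
and 254 healthy eyes, 768-point profiles), compensation improves
glaucoma discrimination everywhere, most strongly in the 10 % of eyes
with the longest axial length (where covariate distortion is largest),
and the mean absolute profile change introduced by compensation grows
with axial length — the qualitative signature the method is built for.

The same pipeline is available from the shell:

```bash
rnflcomp simulate --seed 0 --out-dir data/
rnflcomp train --profiles data/train_profiles.csv \
    --covariates data/train_covariates.csv --out model.json
rnflcomp compensate --model model.json --profiles data/val_profiles.csv \
    --covariates data/val_covariates.csv --out compensated.csv
rnflcomp evaluate --model model.json \
    --train-profiles data/train_profiles.csv \
    --train-covariates data/train_covariates.csv \
    --profiles data/val_profiles.csv \
    --covariates data/val_covariates.csv \
    --out report.json --plots plots/
```

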