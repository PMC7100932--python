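# piresponse

Image-based invasiveness metrics and volumetric temozolomide (TMZ) response
analysis for glioblastoma (GBM) cohorts.

GBM patients treated with the standard of care (resection, chemoradiation,
then adjuvant TMZ cycles) vary enormously in how their tumors respond. This
package implements, as a tested pipeline, an analysis that asks which
pre-treatment imaging characteristics predict volumetric response: it couples
a reaction–diffusion model of glioma growth to routine MRI measurements,
classifies patients as volumetric responders or non-responders, and runs the
stratified statistical battery (Welch *t*, regression slope *F*, Kaplan–Meier /
log-rank) relating invasiveness, TMZ cycle count and survival. A synthetic
cohort generator with planted effects makes every stage runnable and testable
with no data download.

It is aimed at quantitative neuro-oncology researchers: the library
(`src/piresponse/`) holds all computation, the numbered scripts under
`analysis/` are thin narrative drivers, and a `piresponse` CLI wraps the same
functions for shell use.

## The model and the D/ρ metric

The proliferation–invasion (PI) model describes normalized glioma cell
density c(r, t) with net diffusion D (mm²/yr) and net logistic proliferation
ρ (1/yr) in spherical symmetry (Fisher–KPP):

    ∂c/∂t = D ∇²c + ρ c (1 − c)

MRI modalities are treated as iso-density contours: the T1Gd (gadolinium-
enhanced) abnormality edge at a high fraction of carrying capacity (default
0.80), the T2-FLAIR edge at a low fraction (default 0.16). Segmented lesion
volumes V are converted to spherically equivalent radii r = (3V/4π)^⅓.
Because the travelling-wave tail decays as exp(−x·√(ρ/D)), the paired radii
give the closed-form invasiveness estimate

    D/ρ = ((r_T2 − r_T1Gd) / ln(0.80/0.16))²   [mm²]

Large D/ρ = invasion-dominated ("diffuse") tumor; small D/ρ =
proliferation-dominated ("nodular"). Volumetric response is the fractional
change of the T1Gd radius over adjuvant TMZ, %ΔT1Gd = (r_post − r_pre)/r_pre;
a strict decrease defines a *responder*. Cohorts are split into evenly sized
nodular / moderate / diffuse tertiles by pre-adjuvant D/ρ.

The package also implements the full PDE as a numerical oracle
(`estimate_d_over_rho_pde`): simulate the model, image it virtually at the
same thresholds, and invert the measured gap→D/ρ relation. A finding worth
knowing before using absolute D/ρ values: the established front's 0.80→0.16
contour distance is ≈6·√(D/ρ), not ln 5·√(D/ρ), because those thresholds sit
in the nonlinear region of the wave. The closed form therefore overestimates
D/ρ by a stable factor ≈14 relative to the PDE ground truth while preserving
ranks — harmless for tertile-based analyses, visible in absolute scales. See
`docs/methods.md` and `analysis/04_invasiveness_recovery.py`.

## Worked example

```bash
python analysis/01_simulate_cohort.py
python analysis/02_patient_metrics.py
python analysis/03_group_comparisons.py
```

prints (abridged):

```
cohort of 90 synthetic subjects (seed 20)
  cycles of TMZ:     mean   5.87  median    5.0  range 1-20
  D/rho (mm^2):      mean  1.850  median  1.582  range 0.1495-8.318
  responders:        51 / 90
...
  invasiveness tertiles (pre-adjuvant D/rho, mm^2):
    nodular   n=30  [0.1495, 1.0591]
    moderate  n=30  [1.1172, 2.2028]
    diffuse   n=30  [2.2190, 8.3178]
...
significant at alpha=0.05 (6):
  p=0.0022  [log_rank]  overall survival: responders vs non-responders (n=51/39)
  p=0.0282  [slope_F]  nodular: cycles vs pct-change T1Gd (slope) (n=30)
  ...
```

The generator plants a negative cycles→response slope only in nodular tumors
and a survival advantage for responders; the analysis recovers exactly that
structure (the diffuse-tertile slope is not significant), which is the
pipeline behaving as designed. The same steps run from the shell:

```bash
piresponse simulate --n 90 --seed 20 --out cohort.csv
piresponse metrics  --input cohort.csv --out metrics.csv
piresponse analyze  --input cohort.csv --out-dir report/ --stratify sex
piresponse validate --input s1_dataset.xlsx --out summary.json   # real data, if you have it
```

`analyze` accepts `--subcohort pseudoprogression` (only subjects with >12
weeks between radiotherapy end and post-adjuvant imaging) and
`--nadir-variant` (response measured to the smallest interim T1Gd volume
rather than the post-adjuvant one).

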