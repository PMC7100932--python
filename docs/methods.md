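# Methods

## The proliferation–invasion model

Normalized glioma cell density c(r, t) (fraction of carrying capacity) obeys
the Fisher–KPP reaction–diffusion equation in spherical symmetry,

∂c/∂t = D (1/r²) ∂/∂r (r² ∂c/∂r) + ρ c (1 − c),

with net diffusion D (mm²/yr) and net proliferation ρ (1/yr). Compact initial
data develop an outgoing travelling front with asymptotic speed 2√(Dρ) whose
tail decays as exp(−x √(ρ/D)); the width scale of the front is w = √(D/ρ).
The model deliberately ignores anatomy: no grey/white-matter differential
motility, no anisotropy, no resection cavity, no mass effect. It is the
minimal mechanistic summary behind the invasiveness metric, not a patient
simulator.

Imaging enters as iso-density thresholds: the T1Gd abnormality edge is the
outermost radius where c crosses `threshold_t1gd` (default 0.80 of carrying
capacity) and the T2-FLAIR edge where it crosses `threshold_t2` (default
0.16). The defaults are the conventional pair in the PI-model literature; the
source analyses this package operationalizes never state them, so both are
configuration, not constants, and every formula carries the general
ln(threshold ratio).

## Two D/ρ estimators, and why they disagree by a known factor

**Closed form (primary).** Treating the whole front profile as its
exponential tail gives gap = r_T2 − r_T1Gd = w·ln(θ₁/θ₂), i.e.

D/ρ = (gap / ln 5)²  at the default thresholds.

This is the field's standard formula and this package's analysis currency:
deterministic, parameter-free beyond the thresholds, exact scale property
(doubling the gap quadruples D/ρ), exact threshold-consistency rescaling.

**PDE lookup (oracle).** Simulate the model at a grid of D/ρ values (fixed
ρ; the dimensionless problem depends on D and ρ only through w and the time
scale 1/ρ), measure the established-wave gap, and invert the strictly
monotone gap→D/ρ table by PCHIP interpolation.

**The measured discrepancy.** Direct simulation shows the established front's
0.80→0.16 contour distance is ≈6.0–6.1·w across the whole clinical range
(D/ρ from 0.005 to 9.5 mm²), not ln 5·w ≈ 1.61·w. The reason is structural:
0.80 and 0.16 sample the *nonlinear* region of the wave, which is much
shallower than the asymptotic tail (the exactly solvable travelling wave at
speed 5/√6 has a 0.80→0.16 width of 6.23·w, a useful cross-check). Squaring
turns this into a stable factor ≈(6.05/1.61)² ≈ 14 by which the closed form
overestimates D/ρ relative to PDE ground truth; measured 13.8–14.4 over the
range, while the lookup recovers truth to <1%. Two practical consequences:

1. Rank-based uses of D/ρ (tertiles, correlations, group comparisons) are
   unaffected — the factor is nearly constant, so ordering is preserved.
   Everything in the response analysis is rank-based.
2. Absolute D/ρ values from the closed form are on the conventional scale
   used for reported per-patient invasiveness values, which is why the closed
   form stays primary; the lookup quantifies the approximation rather than
   replacing the convention. How any particular historical dataset's D/ρ
   column was computed (pure closed form, numerical calibration, serial
   imaging) can be checked empirically with `piresponse validate` /
   `estimate-dr --method pde_lookup` when such a file is available.

## PDE numerics

Method of lines on a uniform radial grid: second-order central differences,
symmetry condition at r=0 (spherical Laplacian 6(c₁−c₀)/Δr²), zero-flux outer
boundary via ghost nodes. Stiff integration with LSODA, tridiagonal Jacobian
band, rtol 1e-6 (1e-8 in oracle tests), atol 1e-9. Defaults Δr = 0.25 mm,
domain 100 mm. The solver errors out rather than returning a contaminated
answer when the front density at the outer boundary exceeds 1e-3.

Established-wave protocols (`simulation_plan`) scale the numerics with the
front width: Δr = min(0.25, max(w/15, 0.005)) mm, run until the front radius
reaches max(35 w, 15 mm), domain sized with a 15 w + 8 mm margin. The initial
bump (Gaussian, amplitude 0.8) is narrowed to at most 5 w for small-w runs;
a bump much wider than w seeds a shallow tail whose growth-dominated
transient outruns the selected wave for a long time. Front speed is measured
as the slope of the T1Gd radius over the final 40% of output times; residual
deviation from 2√(Dρ) (transient ~3/(4ρt), curvature ~w/r) stays under 5%
for the parameter sets used. Grid-halving changes virtual radii by <1%.
Virtual imaging interpolates threshold crossings linearly between grid nodes
and takes the outermost crossing; profiles that never reach a threshold
yield radius 0 with a warning rather than an error.

## Response metrics

%ΔT1Gd = (r_post − r_pre)/r_pre on spherically equivalent radii, stored as a
fraction (floor −1, since radii are non-negative) and formatted as percent
only at reporting boundaries. The sign — all that responder classification
uses — is identical on radii and volumes because the map is monotone. A
strict decrease defines a responder; an exact zero is classified
non-responder with a warning (a tie is not a decrease, and measured volumes
essentially never tie). A zero pre-adjuvant radius makes the metric
undefined: the subject is excluded by error, never imputed.

Nadir: the minimum T1Gd radius among intermediate observations strictly
inside the adjuvant window plus the post-adjuvant observation; ties break to
the earliest time (conservative for time-to-nadir claims). With no
intermediates the nadir is the post-adjuvant image and the
proportion-of-adjuvant-to-nadir is 1 by definition. The proportion is
(t_nadir − t₀)/(t_end − t₀), invariant to common time shifts. Times are day
offsets from the pre-adjuvant image (a `post_t1gd_offset_days` field carries
the denominator); raw calendar dates are out of scope.

Tertiles are rank-based with equal counts (remainder to the lower groups
first, stable ties), not interpolated quantiles, so n=90 gives exactly
30/30/30 and n=72 gives 24/24/24; each group reports its observed (min, max)
as bounds.

## Statistical battery

Welch two-sided t (Satterthwaite df) for two-group mean differences; OLS
slope with the F-test (F = t²) for monotone association; the standard
two-group log-rank (hypergeometric tie variance, χ² with 1 df) and
Kaplan–Meier curves for survival. Implementations are scipy/lifelines behind
the module surface; the test suite checks each statistic against independent
formula-level re-implementations (hand Welch/OLS algebra, a hand life table)
and calibrates type-I error by simulation. α = 0.05 is a reporting threshold
only; no multiplicity correction is applied, deliberately mirroring the
analysis design this package reproduces.

The primary battery: (i) responder vs non-responder Welch comparisons of
age, cycles, proportion-to-nadir, D/ρ, and pre-adjuvant radii; (ii) log-rank
on overall survival, and on time-to-progression restricted to subjects with a
recorded progression date (others are excluded, not censored — progression
ascertainment, not follow-up, is what is missing); (iii) within each D/ρ
tertile, the cycles→%ΔT1Gd slope test and the responder survival split;
(iv) MGMT subanalyses (survival, D/ρ, cycles, response by methylation
status) when status is available; optional sex-stratified reruns (re-tertiled
within stratum by default, so a three-way split of each sex; full-cohort
bounds available as an option) and a nadir-variant rerun. Alive or
lost-to-follow-up subjects are right-censored at their last known time. Any
comparison with an arm too small to test is emitted as a "not estimable" row,
never silently dropped or fabricated.

## Synthetic cohort generator

The generator emulates the *statistical structure* the analysis assumes, at
the emulated study's scale (n=90 by default):

| quantity | default | rationale |
|---|---|---|
| D/ρ | lognormal, log-median ln 1.4, log-sd 0.885, truncated to (0.0034, 9.525) mm² | right-skewed with median ≈1.4 mm² and mean/median ratio ≈1.5, spanning the observed clinical range |
| T2 radius | r_T1Gd + ln 5·√(D/ρ) | exactly the closed form, so D/ρ recovery is an exact round trip |
| pre-T1Gd radius | Normal(12, 6) mm, truncated ≥2 | clinical post-chemoradiation lesion scale |
| cycles | 1 + NegBin(r=2.2, mean 5.1), capped at 21 | integer, median 5, long right tail to 21 |
| age | Normal(55, 12) yr on [18, 76] | adult GBM demographics |
| sex | 2/3 male | typical GBM cohort composition |
| response | Normal(0, 0.35) + tertile slope·(cycles − 6), floored at −1 | median near zero, occasional large excursions |
| planted slope | −0.06/cycle in nodular, 0 in diffuse, midpoint in moderate | effect sizes are design placeholders (the emulated study reports only p-values), strong enough for power checks |
| survival | exponential, non-responder median 450 d, responder hazard ratio 0.5 | shape-1 Weibull keeps the KM-median hazard-ratio check analytic (median ratio = 1/HR) |
| censoring | 21% of subjects, at U(0.25, 1)×their event time | right-censoring independent of group structure |
| progression | recorded for 48% of subjects, same hazard ratio | mirrors partial progression ascertainment |
| MGMT | 35% methylated, observed for 26%; +0.5 shift on log D/ρ, median-preservingly centred | methylated tumors more diffuse; shift magnitude is a free knob, not an empirical value |
| nadir path | 50% reach nadir strictly before the post image, at U(0.6, 1)×min(pre, post) | exercises the nadir machinery with monotone decline-then-recovery paths |

What it does *not* emulate — hence what green tests do not establish about
real data: segmentation and inter-rater noise (the radius jitter flag exists
but defaults off, keeping the D/ρ round trip exact), pseudoprogression
dynamics (the >84-day gap field is drawn independently of everything else),
correlated covariates (age, sex and invasiveness are independent by
construction), per-cycle pharmacokinetics, dropout, or any calendar
structure. Passing recovery tests show the *pipeline* is unbiased and
calibrated, not that the clinical effects are real.

## Calibration checks and their design

With all planted effects zeroed, every p-value in the battery should be
uniform. Two checks: the full analysis of one null cohort passes a KS test at
0.01, and — stronger — each comparison family is KS-uniform across 40
independently seeded null cohorts (Bonferroni at 0.01). The family-wise
design matters: p-values *within* one analysis share the same data, so
pooling them all into a single large-n KS test violates its independence
assumption and eventually flags nothing but the pooling itself (plus the tiny
small-sample anti-conservatism any t/log-rank approximation carries). The
power check plants the default nodular-only slope at n=900 and requires the
nodular slope test to reject while the diffuse one does not, jointly in ≥80%
of 50 replicates (observed ≈90–96%).

## Cohort I/O conventions

Input is CSV or XLSX (sheets `cohort` and `mgmt_expanded` by default) with a
user-editable column map; coded fields follow the de-identified-dataset key
(resection 3/2/1 = GTR/STR/biopsy; MGMT NA/0/1/2 = not available /
undetermined / unmethylated / methylated). Radii may arrive in mm or as
volumes in mm³; radii win when both are present, with a warning if they
disagree by ≥0.1 mm. Inclusion staging (primary GBM; resection + concurrent
chemoradiation + ≥1 adjuvant cycle; demographics and survival available; no
other therapies before the first adjuvant cycle; pre- and post-adjuvant
imaging) is toggleable with a per-stage audit trail of counts and excluded
ids; counts are non-increasing by construction. The pseudoprogression
subcohort keeps subjects with strictly more than 84 days ("more than 12
weeks") between radiotherapy end and post-adjuvant imaging. Missing optional
fields degrade to exclusion from the specific analysis, never imputation.

## Known limitations

- Absolute closed-form D/ρ carries the factor-≈14 scale convention discussed
  above; compare absolute values across datasets only with matching
  conventions.
- The log-rank and Welch tests are asymptotic; at the MGMT subanalysis sizes
  (≈9 vs 14) p-values are indicative, as in the analysis design being
  reproduced.
- The PDE oracle assumes spherical symmetry and homogeneous tissue; it
  validates the estimator's mathematics, not its anatomical realism.
- Problem sizes in tests and the acceptance script (20 simulated recovery
  points, 2000-replicate type-I runs, 40–50 replicate calibration batches,
  n=900 power cohorts) were chosen to make the checks sharp yet quick on a
  single CPU; all scale up by changing one constant.
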