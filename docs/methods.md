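# Methods

## Scope and model

The package computes, per patient, the pressure–diameter indices of aortic
mechanics (strain, distensibility, stiffness index), body-size
normalisations (BMI, BSA, BSA-indexed EAT thickness and volume), and, per
cohort, the median-split comparison, correlation and ROC analyses built on
them. All cohort statistics operate on a plain pandas DataFrame in the
cohort CSV schema; nothing in the statistical layer knows whether the rows
came from a file or the simulator.

### Index formulas and their ambiguities

Strain is the percent systolic excursion of the ascending aortic diameter;
distensibility is `2·strain/pulse pressure` carried in the nominal
`cm²/dyn` labelling convention of the echo/CT literature — the arithmetic
is percent-strain over mmHg and **no unit conversion is applied**, because
the downstream statistics (medians, correlations, ROC) are invariant to any
fixed rescaling and the nominal numbers are the ones practitioners quote
(0.10–0.15 in this population).

The stiffness-index formula is typeset ambiguously in parts of the
literature. We default to the *log of the full quotient*,
`ln[(SBP/DBP)/(ε/100)]`, because it is the only reading consistent with the
summary statistics of the calibration cohort: median strain 2.67% with mean
pressures 143.2/88.4 mmHg gives 4.105 against a reported median of 4.09
(0.4% apart, attributable to rounding of the inputs), whereas the classic
`β = ln(SBP/DBP)/(ε/100)` gives 18.07. The classic form remains selectable
(`classic_beta`) for comparison against studies that use it. Internal
consistency was preferred over the literature-standard formula.

BSA is not specified by the calibration source; Du Bois–Du Bois is the
default (1.831 m² at the cohort mean height/mass against a reported mean of
1.82 m²) with Mosteller selectable. The two differ by ~1.3% at the cohort
mean but up to ~5% at tail-obesity records (BMI ≈ 39), where Mosteller is
known to read higher — a per-patient discrepancy users should be aware of
when comparing indexed EAT values across BSA conventions.

Zero strain leaves the stiffness index undefined. The default is a hard
domain error; an opt-in clamp (`clamp_strain=True`, floor 0.1%) substitutes
the floor with a warning, intended for robustness runs on noisy data only.

## Synthetic cohorts

### What is emulated

The generator targets the marginal means/SDs of the calibration cohort
(n = 97: age 63.48 ± 8.50 y, height 1.67 ± 0.07 m, mass 74.16 ± 11.03 kg,
SBP 143.20 ± 7.78, DBP 88.40 ± 5.66 mmHg, diastolic aortic diameter
33.42 ± 4.36 mm, strain 3.29 ± 2.37 %, EAT thickness 9.51 ± 3.33 mm, EAT
volume 60.03 ± 21.07 mL, 49.5% male) and the published EAT–aorta
association structure. Sampling is a Gaussian copula over nine latent
variables; two constructions guarantee validity of every record:

* pressures are sampled as (DBP, pulse pressure) with positive lower
  bounds, so SBP = DBP + PP > DBP always; the PP marginal (54.8 ± 5.34)
  is derived from the SBP/DBP moments under DBP ⟂ PP, making the
  reconstructed SBP match its published moments;
* the systolic diameter is derived as `diastolic · (1 + strain/100)` from a
  strain latent truncated below at 0.2%, so systolic ≥ diastolic and the
  stiffness index stays finite on every record.

### Truncation and moment matching

Every physical marginal is a truncated normal with a plausibility lower
bound (e.g. EAT volume > 5 mL, strain > 0.2%). Truncation shifts moments —
naively truncating a N(3.29, 2.37²) strain at 0.2 raises its mean to ~3.74
— so the parent (μ, σ) are solved (Brent on the standardised bound, using
the Mills-ratio expressions for truncated moments) such that the truncated
distribution itself has the target mean and SD. A quadrature test verifies
this for every shipped marginal. `summarize` still reports achieved-vs-
target bias per draw so users can see ordinary sampling noise.

The strain marginal deserves a caveat: an SD of 2.37 at mean 3.29 implies a
strongly skewed real-world distribution; the moment-matched truncated
normal reproduces mean, SD and positivity but not the true shape, which is
unknown. A lognormal marginal is available for sensitivity analyses.

### Correlation calibration

The published associations are between EAT measures and *derived* aortic
indices — nonlinear, monotone transforms of the latents — so latent and
induced correlations differ. Two latent entries are treated as calibration
knobs: EAT thickness–strain (targeting an induced thickness–strain
correlation of −0.32) and EAT volume–strain (targeting an induced EAT
volume index–stiffness index correlation of +0.55, the headline
association). `calibrate_latent_targets` runs a fixed-point iteration
(measure induced r over replicate cohorts, rescale the latent entry by
target/induced, ≤ 5 rounds); the shipped values (−0.3389, −0.5402) are its
converged output and a test re-runs a short calibration against them. The
remaining latent entries are mild, fixed, physiologically plausible choices
(height–mass 0.40, mass–EAT 0.30/0.35, age–strain −0.25, EAT
thickness–volume 0.55, …) that are not fitted to any published number; the
induced correlations for the *non-calibrated* cells of the EAT × aorta grid
therefore land close to, but not exactly on, their published counterparts
(e.g. thickness–stiffness ~0.33 vs a published 0.21).

Requested correlation matrices are repaired to the nearest positive
semi-definite correlation matrix by eigenvalue clipping; the Frobenius
repair distance is carried on the generated cohort and a distance > 0.2
raises a calibration error rather than silently sampling from a very
different dependence structure.

Seeding: a counter-based Philox stream keyed on the spec seed; replicate k
of a batch uses seed + k, so batches are extensible without overlap.

### What passing tests do and do not show

The simulator reproduces marginal moments, record validity and the
calibrated association structure — enough to exercise every pipeline stage
and to verify the statistical machinery's operating characteristics. It
does **not** model measurement error, skewness beyond truncation,
comorbidity structure, sex-specific effects, or the coronary-disease
covariates of real CCTA cohorts; agreement of pipeline output with the
simulator's calibration says nothing about any real population beyond the
moments and two associations put in.

## Statistical machinery

* **Median split**: sample median (mean of central order statistics for
  even n); ties at the median join the "≥" group, so 97 distinct values
  split 49/48. All-tied input is a degenerate-split error.
* **Gated comparison**: Shapiro–Wilk per subgroup at a fixed gate of
  α = 0.05 (deliberately independent of the reporting α, so changing the
  significance level never changes which test ran); both pass → pooled
  Student t (Welch optional), else asymptotic tie-corrected Mann–Whitney U.
  Simulation tests pin the procedure's size to [0.03, 0.07] under normal
  and lognormal nulls at n = 49/48, and its power at the calibration
  effect size against the closed-form noncentral-t value (~0.98).
* **Correlations**: Pearson by default — the associations of interest are
  linear; Spearman selectable. Zero-variance columns raise rather than
  emitting NaN.
* **ROC**: thresholds are the descending unique scores with an infinite
  sentinel ("call nothing positive" competes as a rule); a positive call is
  score ≥ threshold. AUC is trapezoidal and is tested to coincide with the
  tie-corrected pairwise U-statistic to 1e−12. The operating point
  maximises accuracy by default (Youden's J optional); ties break toward
  the smallest (most sensitive) threshold. Rates are reported at 3 decimals
  with the exact integer confusion counts retained, since re-deriving
  counts from rounded rates is lossy. The same cutoff may serve several
  outcomes; no uniqueness is enforced.

## Numerical and reporting choices

* Derived CSVs carry full precision (`%.12g`); rounding (2 decimals for
  moments, 3 for rates) happens only at render time in `tables.md`.
* `summary.json` is the single source for every rendered number and is
  byte-stable across reruns of the same seed + config (the output directory
  is excluded from the echoed config for exactly this reason).
* Significance renders as `<α` / `ns`; p-values are kept unrounded in the
  JSON.
* Validation is fail-fast with 1-based row numbers; `--skip-invalid` drops
  bad rows instead for exploratory runs.

## Problem sizes used in the shipped checks

Test and acceptance simulations use 97-patient cohorts in batches of
20–400 replicates (200 for the headline-correlation recovery, 1000
replicates for test-size calibration), sizes at which Monte-Carlo error on
a correlation mean is ~0.005 and on a rejection rate ~0.007 — small against
the tolerances being checked.

## Known limitations

* The calibration reproduces two association targets exactly and the rest
  approximately; it is a demonstration harness, not a re-creation of any
  real cohort.
* Only Gaussian dependence is modelled; no heavy tails, no tail dependence.
* The nominal distensibility unit is carried verbatim; comparisons against
  studies reporting true `10⁻⁶ cm²·dyn⁻¹` distensibility need a conversion
  outside this package.
* CT acquisition, EAT segmentation, calcium scoring and any clinical
  interpretation are out of scope.
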