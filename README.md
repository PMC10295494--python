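# aortastat

Cohort analytics for studies relating **epicardial adipose tissue (EAT)** to
the **mechanical state of the ascending aorta**, as measured by coronary CT
angiography. Written for biostatisticians and imaging researchers who have a
per-patient table of anthropometrics, brachial pressures, ECG-gated aortic
diameters and EAT measurements, and want the standard clinical-paper
analysis — derived indices, median-split subgroup tests, correlations and
ROC prediction — as tested, reproducible code rather than a point-and-click
session. A calibrated synthetic-cohort generator makes every stage testable
when no patient-level data can be shared.

## The indices

With systolic/diastolic aortic diameters `Ds`, `Dd` (mm) and pressures
`SBP`, `DBP` (mmHg):

```
strain          ε  = 100 · (Ds − Dd) / Dd                      [%]
distensibility  D  = 2 · ε / (SBP − DBP)                       [nominal cm²/dyn]
stiffness index β* = ln[ (SBP/DBP) / (ε/100) ]                 [–]
BSA (Du Bois)      = 0.007184 · m^0.425 · (100·h)^0.725        [m²]
EAT indices        = EAT thickness (or volume) / BSA           [mm/m², mL/m²]
```

Two readings of the stiffness-index formula circulate: the log of the full
pressure-to-strain quotient (above, the default) and the classic
β = ln(SBP/DBP)/(ε/100). At a typical strain of 2.67% with pressures
143.2/88.4 mmHg they give 4.11 versus 18.07 — only the first is consistent
with the reference cohort this package is calibrated against, so it is the
default and the classic form stays available as an option
(`stiffness_interpretation="classic_beta"`). Distensibility is carried in
the study's nominal units (2·ε[%]/PP[mmHg]); no dyne conversion is applied.

## The statistical pipeline

1. **Derivation** — validate each record (SBP > DBP, Ds ≥ Dd > 0, …) and
   append the eight derived columns.
2. **Median splits** — dichotomize each variable at its sample median, ties
   joining the "≥ median" group (97 continuous values split 49/48).
3. **Gated comparison** — Shapiro–Wilk on both subgroups at α = 0.05;
   Student's t (pooled; Welch optional) if both pass, Mann–Whitney U
   otherwise. No multiple-testing correction; the report counts the tests.
4. **Correlations** — Pearson (Spearman optional) for each EAT variable
   against stiffness index, strain and distensibility.
5. **ROC** — each EAT measure as a predictor of adverse aortic status
   (stiffness ≥ its median; strain or distensibility < its median), with
   the accuracy-maximal cutoff (Youden optional) and
   sensitivity/specificity/accuracy from the exact confusion counts.

The simulator draws a Gaussian copula over nine latent variables with
moment-matched truncated-normal marginals, and its latent EAT–strain
correlations are calibrated by fixed-point iteration so that the *induced*
correlations on the derived indices hit the published associations
(EAT volume index vs stiffness index = 0.55). See `docs/methods.md`.

## Worked example

```python
from aortastat import PatientRecord, derive_all

d = derive_all(PatientRecord(
    id="example", age=63.5, sex="female", height=1.67, body_mass=74.16,
    sbp=143.2, dbp=88.4, ao_diastolic_diameter=33.42,
    ao_systolic_diameter=34.50, eat_thickness=9.51, eat_volume=60.03,
))
```

prints (via `python examples/01_derive_indices.py`):

```
BSA (Du Bois)           1.831  m^2
BMI                     26.59  kg/m^2
pulse pressure           54.8  mmHg
aortic strain           3.232  %
aortic distensibility  0.1179  (nominal cm^2/dyn)
aortic stiffness idx    3.915
EAT thickness index     5.194  mm/m^2
EAT volume index       32.788  mL/m^2
```

— a 1.08 mm systolic excursion on a 33.42 mm aorta is 3.23% strain; divided
twice-over by the 54.8 mmHg pulse pressure it gives the distensibility, and
the log of the pressure ratio over fractional strain gives a stiffness
index just below 4, i.e. an unremarkable aorta for this age group.

The other `examples/` scripts cover cohort simulation, the median-split
tables, the ROC report, and the one-call pipeline
(`run_pipeline(RunConfig(seed=1, output_dir=...))`), which writes every
table as CSV + markdown, ROC coordinate files, and a `summary.json` that is
byte-identical across reruns of the same seed and config. The same stages
are scriptable from a shell:

```
aortastat simulate --seed 1 --out cohort.csv
aortastat derive --cohort cohort.csv --out derived.csv
aortastat all --simulate --seed 1 --out run/
```

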