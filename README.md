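# strainhet

Myocardial **strain heterogeneity biomarkers** from cardiovascular
magnetic resonance (CMR) feature tracking, with the full prognostic
modeling stack used to evaluate them at population scale.

Global strain (GLS, GCS, GRS — the mean absolute peak systolic strain
across the myocardium) summarizes contractile function but can miss
*regional* disease: a small infarcted territory barely moves the
global mean. The strain **coefficient of variation** quantifies that
regionality directly. For 16 AHA segments with peak segmental strain
Y₁…Y₁₆ (per direction: longitudinal, circumferential, radial),

    CoV = SD(|Y₁|, …, |Y₁₆|) / mean(|Y₁|, …, |Y₁₆|)

so CoV_LS, CoV_CS and CoV_RS are dimensionless heterogeneity indices:
a uniform loss of contraction leaves them unchanged (and lowers global
strain), while a regional lesion raises them — the discriminating
property this package exists to compute and evaluate.

The package provides, as a Python library:

- **`synthetic_cohort`** — a cohort generator emulating a population CMR
  study: covariates and volumetrics, raw signed segmental strain with a
  contiguous-lesion model, injected QC artifacts with a full ledger, and
  Weibull proportional-hazards outcomes with realistic censoring.
- **`strain_biomarkers`** — the QC cascade (no-strain exclusion,
  sign-validity, cohort-level 3×IQR fences, ≥7-valid-segments rule for
  CoV), global strain, strain CoV, and the missing-segment impact
  assessment behind the segment-count rule.
- **`cohort_descriptives`** — healthy-reference selection, mean ± 2 SD
  reference ranges (global and per segment), regional-abnormality
  flags, Mann-Whitney group comparisons, Spearman correlations, tertile
  assignment.
- **`survival_models`** — nested Cox models (Model 1: biomarker; Model
  2: + clinical risk factors; Model 3: + LVMi, LVEDVi, LVEF and the
  reciprocal strain marker), Schoenfeld/VIF diagnostics, Uno's IPCW
  C-index with bootstrap ΔC, continuous NRI(>0), 5-year IPCW Brier
  score, LRT/AIC, Bonferroni correction (m = 15), subgroup analyses
  including the HFpEF-risk rule.
- **`nonlinearity_km`** — 4-knot restricted cubic spline basis and
  non-linearity LRT, Kaplan-Meier curves, logrank test for trend,
  tertile panels stratified by LVEF (< 50% vs ≥ 50%).
- **`pipeline` / `cli`** — end-to-end orchestration with CSV/JSON
  outputs and a thin `strainhet` command with per-stage subcommands.

## Worked example

```python
from strainhet import (ModelSpec, SimulationConfig, apply_qc,
                       build_modeling_frame, fit_cox, simulate_cohort)

cohort = simulate_cohort(SimulationConfig(
    n_participants=8000, seed=4, lesion_prevalence=0.25))
_, biomarkers, report = apply_qc(cohort.strain_long)
frame = build_modeling_frame(cohort.covariates, biomarkers,
                             cohort.outcomes)
fit = fit_cox(ModelSpec("hf", "cov_cs", tier=3), frame)
print(report.inclusion_fraction, fit.focal_hr, fit.focal_ci)
```

Running `examples/04_cox_model_comparison.py` (which executes exactly
this analysis plus the model-comparison battery) prints:

```
Model 1: HR per SD CoV_CS = 1.37 [1.11-1.68], events 76/7944
Model 2: HR per SD CoV_CS = 1.34 [1.09-1.65], events 76/7944
Model 3: HR per SD CoV_CS = 1.30 [0.99-1.71], events 76/7944

added value of CoV_CS in the fully adjusted model:
  Uno C-index      0.711
  delta C          +0.0145 (bootstrap p=0.003)
  NRI(>0)          +13.2%
  delta Brier (5y) -0.000003
  delta AIC        -1.5, LRT p=0.0631
```

The generator planted a hazard ratio of 1.20 per SD of CoV_CS on heart
failure; the fully adjusted model recovers an estimate whose confidence
interval covers it (76 events make the single-run estimate noisy — the
test suite verifies recovery and CI coverage over 100 replicates).
ΔC > 0 with a small bootstrap p says the biomarker improves risk
discrimination beyond clinical covariates, volumetrics and global
circumferential strain.

The other scripts in `examples/` each demonstrate one capability:
cohort simulation, the QC cascade against the injection ledger,
reference ranges and regional-abnormality flags, and the non-linearity
LRT with LVEF-stratified KM tertile panels.

There is also a shell interface for stage-by-stage runs:

```bash
strainhet simulate --out run/ --seed 2
strainhet qc --out run/
strainhet refranges --out run/
strainhet fit --out run/ --endpoint hf --biomarker cov_cs --tier 3
strainhet km --out run/
```

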