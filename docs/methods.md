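# Methods

## The biomarker

Peak systolic strain is reported per AHA segment (16 segments: 6 basal,
6 mid, 4 apical; no apical cap) and per direction. Raw values carry the
physiological sign convention — longitudinal and circumferential
shortening negative, radial thickening positive — and all biomarkers
are computed on absolute values. Global strain is the arithmetic mean
of |Y_i| over valid segments; the strain CoV is SD(|Y_i|)/mean(|Y_i|).
The SD uses the sample (n−1) denominator by default with a `ddof`
switch for the population form: with 16 segments the two differ by
~3% multiplicatively, and the reported convention is logged in the QC
report options. CoV is dimensionless; field practice labels it "%",
and we carry the raw ratio (0.16, not 16).

## Quality control

The cascade runs in a fixed order:

1. participants with no strain measurements at all are dropped;
2. values with an impossible sign (including exact zero and non-finite
   values) are invalidated per cell;
3. cohort-level outlier fences Q1 − 3·IQR and Q3 + 3·IQR (quartiles by
   linear interpolation) are computed on absolute values pooled per
   direction, and values strictly beyond a fence are invalidated;
   the same fencing is then applied to the derived global strain and
   CoV distributions (scope configurable: segmental, biomarker, or
   both — default both, recorded in the report);
4. a direction with fewer than 7 valid segments loses its CoV (global
   strain is still computed from ≥1 valid segment, since the
   segment-count rule concerns the dispersion estimate, not the mean).

Values exactly on a fence are retained (conservative reading of
"beyond"). `assess_missing_segment_impact` quantifies why ≥7 segments:
it recomputes the CoV over all (or sampled) size-k subsets of a
complete set and reports bias and spread against the full-set value;
dispersion grows quickly below ~half the segments.

Re-running the cascade on its own cleaned output reproduces the same
biomarker table on the cohorts we generate; this is verified by test,
not guaranteed in the abstract (fences re-estimated after exclusions
can in principle flag additional borderline cells).

## Reference ranges and regional abnormality

The healthy reference subset excludes participants with any of:
dyslipidemia, obesity (BMI ≥ 30), hypertension, diabetes, CKD, current
smoking, CAD, prior MI, cerebrovascular disease, PVD, AF, aortic
stenosis, mitral disease, any cardiomyopathy, or HF. The list is
exactly this enumeration and extensible via `exclusion_flags`.
Reference ranges are mean ± 2 SD of the healthy values — globally and
segment by segment (16 ranges per direction). A direction is flagged
"regionally abnormal" when ≥1 valid segment leaves its segmental range
while the global value stays inside the global range; a missing global
value yields a missing flag, and an out-of-range global value yields
False (the flag isolates regional abnormality *with preserved global
strain*).

## Survival modeling

Models are cause-specific Cox proportional-hazards fits (lifelines,
Efron ties, Newton precision 1e−9, ≤100 steps), complete-case, with
participants prevalent for the modeled endpoint excluded at baseline.
All six strain markers are z-scored on the analysis rows so hazard
ratios are per SD. Tier 1 is the focal biomarker alone; tier 2 adds
age, sex, ethnicity, smoking, BMI, dyslipidemia, hypertension,
diabetes; tier 3 adds LVMi, LVEDVi, LVEF and the reciprocal strain
marker (global paired with CoV and vice versa), optionally plus the
regional-abnormality flag. Diagnostics: scaled Schoenfeld residual
tests (rank time transform) and VIFs from auxiliary OLS regressions,
with the conventional VIF < 5 bar.

Model comparison attaches, for the focal biomarker:

- **Uno's C-index**, IPCW with weights G(t−)⁻² from the Kaplan-Meier
  censoring survival, truncated at τ (default: 95th percentile of
  observed follow-up, logged); tied risks count ½; with no censoring it
  equals Harrell's C exactly.
- **ΔC** between nested models fit on identical rows, with a p-value
  from an unpaired t test on two bootstrap C distributions (B = 200
  default, participant-level resampling, seed required). The unpaired
  test on overlapping resamples is the conventional recipe and is known
  to be anticonservative; a paired percentile alternative is available
  via `method="paired"` and both report B and failed resamples.
- **Continuous NRI(>0)** at a horizon (default 5 years), with event
  status IPCW-weighted (events by the horizon get 1/G(t−), survivors
  1/G(h), earlier-censored weight 0) and a percentile bootstrap
  interval — the interval method is an assumption, flagged in output.
- **IPCW Brier score** at 5 years.
- **LRT and ΔAIC**; "improvement" is reported at ΔAIC < −2 with LRT
  p < 0.05.
- **Bonferroni correction** with m = 15 principal comparisons:
  adjusted p = min(1, 15p), significance at raw p < 0.05/15 ≈ 0.0033.

Subgroup refits: age >65/≤65, sex, prevalent CKD/MI/AF, and the
HFpEF-risk rule (LVEF ≥ 50% plus ≥3 of age >65, obesity, hypertension,
diabetes, CKD, AF). Subgroups with zero events are reported
not-estimable rather than raising.

## Non-linearity and Kaplan-Meier

The restricted cubic spline uses the truncated-power construction
normalized by the squared boundary-knot span: 4 knots give a basis of
x plus two non-linear columns that are linear beyond the boundary
knots with continuous first and second derivatives. "Knots at
quartiles" is not well defined for 4 knots, so the default rule places
them at the 5th/25th/75th/95th percentiles and a `quartile` option uses
the 5th/25th/50th/75th (Q1/Q2/Q3 anchored with a low-tail boundary);
the rule used is part of the output. The non-linearity LRT compares
the RCS model against the linear model on identical rows (χ² = 2·Δℓ,
df = 2). Basis columns are standardized (a linear reparametrization)
and the RCS fit is warm-started at the linear solution so the nested
likelihood ordering holds at convergence; with very few events per
parameter the fit can still be singular, which is surfaced as an error
rather than a spurious χ².

KM analysis uses the product-limit estimator per group (cumulative
hazard displayed as −log S), tertiles cut at the 1/3 and 2/3 quantiles
computed *within* each LVEF stratum by default (cohort-wide optional),
ties at a cut going to the lower tertile, and the logrank test for
trend with equally spaced scores (hypergeometric variance, 1 df). The
trend statistic is invariant to affine recoding of the scores and
reduces to the standard two-sample logrank for two groups.

## The synthetic cohort generator

The generator exists so the full stack is testable without restricted
data; its defaults are the study conditions the tests assume.

Strain model, per direction: |Y_is| = m_d + b_i + e_is with cohort mean
m_d, participant effect b_i, segment noise e_is (all Normal, percent
units). Defaults: means 18.4 / 18.9 / 31.4% (longitudinal /
circumferential / radial — healthy population medians), segment-noise
SDs 6.1 / 3.0 / 8.8% chosen so healthy CoV medians land near
0.33 / 0.16 / 0.28, and participant SDs 1.3 / 2.0 / 5.1% so the global
strain spread matches healthy interquartile ranges. Between-segment
variance for healthy hearts is not published, so this calibration is a
documented modeling choice, not a data fact. Circumferential and
radial noise (segment and participant level) share correlation 0.95,
which reproduces the strong observed CoV_CS–CoV_RS correlation
(Spearman ≈ 0.89 in generated cohorts); longitudinal is independent.

Lesions: with configurable prevalence a participant receives one
contiguous patch (default 4 segments, grown on the ring/level adjacency
of the 16-segment model: rings 1–6, 7–12, 13–16; basal↔mid aligned 1:1,
mid↔apical by a coarse 6:4 alignment) whose strain magnitude is
multiplied by the attenuation factor (default 0.5). The mask is shared
between circumferential and radial (a coronary-territory insult);
longitudinal attenuation is coupled at strength 0.5 by default.
Lesion probability is concentrated in participants with prevalent CVD
(odds 12) or risk factors (odds 4) relative to flag-free participants,
renormalized to the configured prevalence — so the healthy-reference
subset is mostly lesion-free and disease groups show elevated CoV, as
in observed cohorts. Lesioned participants also lose 5 LVEF points by
default.

Covariates are independent Bernoulli/Normal draws matched to published
population prevalences (age 65.4 ± 7.7, BMI 26.5 ± 4.5, hypertension
28.7%, …). Outcomes follow Weibull proportional hazards (shape 1.3)
with endpoint-specific scales calibrated to crude event fractions of
roughly 2.9% (composite), 0.8% (MI), 0.6% (HF), 1.7% (arrhythmia),
1.4% (death); configured log hazard ratios act on z-scored *clean*
(pre-artifact) biomarkers and on binary covariates directly, so QC
quality determines how well models recover the planted effects. Death
is treated as censoring for non-fatal endpoints (cause-specific
hazards; no competing-risks machinery). Censoring is an administrative
cutoff at 6.5 years plus Uniform(0, cutoff) dropout with probability
0.65, giving follow-up quartiles near (2.4, 4.7, 6.5) years.

Artifacts: sign flips, extreme outliers (constructed beyond the clean
cohort's Q3 + 3×IQR, correct sign), per-cell segment dropout, and
whole-participant emptying, each at a configured rate, at most one per
cell, all recorded in a ledger so QC recall and the segment-count rule
can be checked cell by cell.

What the generator does **not** emulate: non-Gaussian strain
distributions, spatial noise correlation beyond the shared lesion mask
and CS–RS coupling, covariate–covariate dependence (age does not drive
hypertension), informative censoring, competing risks, or
measurement-error structure of specific software. Passing tests
therefore demonstrate correctness of the analytic machinery under a
clean proportional-hazards world, not robustness to the full messiness
of real CMR cohorts.

## Problem sizes used in the validation suite

The statistical validation tests run at sizes chosen to give adequate
power and tight Monte-Carlo error while keeping the suite practical:
effect-recovery uses 100 replicates of n = 8,000 at a ~3% event rate
(mean recovered HR within [1.17, 1.23] of the planted 1.20, CI coverage
in [0.92, 0.98]); null calibration uses 500 Wald replicates (n = 600)
and 300 RCS replicates (n = 800); the model-comparison power check uses
15 replicates with B = 60 bootstrap resamples at n = 2,000; oracle
equivalence uses 100 random instances per statistic at n ≤ 100; the
stratified-KM pattern uses 100 replicates at n = 1,500. Seeds are
fixed throughout, so every reported rate is reproducible.

## Known limitations

- The generator's independence assumptions (above) limit external
  realism; it is a test harness, not a population model.
- The unpaired bootstrap t test for ΔC inherits the anticonservatism of
  the conventional recipe; use the paired alternative for inference
  that must be calibrated.
- Per-segment reference ranges at small healthy-cohort sizes are noisy;
  the regional-abnormality flag should be interpreted with n_healthy in
  view (it is carried in the range table).
- No multiple imputation (complete-case only), no time-varying
  covariates, no Fine-Gray competing-risks models.
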