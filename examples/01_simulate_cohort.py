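"""Simulate a study-structured cohort and look at its ground truth.

Generates 2,000 participants with covariates, CMR volumetrics, raw
segmental strain in three directions, injected QC artifacts and
proportional-hazards outcomes, then prints the healthy calibration:
median global strain and strain CoV per direction.
"""

import numpy as np

from strainhet import SimulationConfig, simulate_cohort

config = SimulationConfig(
    n_participants=2000, seed=1,
    lesion_prevalence=0.25,          # 25% carry a regional lesion
    lesion_n_segments=4,             # 4 contiguous AHA segments
    lesion_attenuation=0.5,          # lesioned strain magnitude halved
    artifact_rates={"sign_flip": 0.01, "extreme_outlier": 0.01,
                    "segment_dropout": 0.05, "empty_participant": 0.005})
cohort = simulate_cohort(config)

print(f"participants: {len(cohort.covariates)}")
print(f"strain cells: {len(cohort.strain_long)} "
      f"({cohort.strain_long['value'].isna().sum()} missing)")
print(f"injected artifacts: {len(cohort.ledger)} "
      f"({dict(cohort.ledger['kind'].value_counts())})")

truth = cohort.truth
print("\nclean biomarker medians (lesion-free participants):")
for col in ("gls", "gcs", "grs", "cov_ls", "cov_cs", "cov_rs"):
    med = truth.loc[~truth["lesion"], col].median()
    print(f"  {col:7s} {med:6.3f}")
# Global strain medians sit near healthy population values (~18.4 / 18.9
# / 31.4 %) and strain CoV near 0.33 / 0.16 / 0.28 — the heterogeneity
# level of a healthy ventricle.

events = cohort.outcomes.groupby("endpoint")["event"].mean()
print("\ncrude event fractions per endpoint:")
print(events.round(4).to_string())
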