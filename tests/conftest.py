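import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # tests/oracles.py

from strainhet.synthetic_cohort import SimulationConfig, simulate_cohort
from strainhet.strain_biomarkers import apply_qc
from strainhet.survival_models import build_modeling_frame


def random_survival_instance(rng, n=60, cens_frac=0.3):
    """A small censored survival dataset with risk scores."""
    risk = rng.normal(size=n)
    t = rng.weibull(1.2, n) * 5.0 * np.exp(-0.5 * risk)
    c = rng.uniform(0, np.quantile(t, 1 - cens_frac) * 2, n)
    times = np.minimum(t, c)
    events = t <= c
    return risk, times, events


@pytest.fixture(scope="session")
def small_cohort():
    cfg = SimulationConfig(
        n_participants=800, seed=11, lesion_prevalence=0.25,
        artifact_rates={"sign_flip": 0.005, "extreme_outlier": 0.005,
                        "segment_dropout": 0.02, "empty_participant": 0.002})
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_biomarkers(small_cohort):
    clean, biomarkers, report = apply_qc(small_cohort.strain_long)
    return clean, biomarkers, report


@pytest.fixture(scope="session")
def modeling_frame(small_cohort, small_biomarkers):
    _, biomarkers, _ = small_biomarkers
    return build_modeling_frame(small_cohort.covariates, biomarkers,
                                small_cohort.outcomes)
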