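"""Synthetic survival cohorts with the structure of a population CMR study.

The generator produces, per participant: clinical covariates and
CMR volumetrics, raw signed segmental peak systolic strain for the
16 AHA segments in three directions, and time-to-event outcomes from a
Weibull proportional-hazards model.  It exists so the whole analysis
stack — QC, biomarkers, reference ranges, Cox modeling, KM analysis —
can be exercised and validated without access-restricted data.

Healthy segmental strain follows an additive model per direction
``|Y_is| = m + b_i + e_is`` (cohort mean + participant effect + segment
noise), signed by the direction convention.  Regional disease is
emulated by a "lesion": a contiguous patch of segments whose strain
magnitude is multiplied by an attenuation factor, shared between the
circumferential and radial directions (as with a coronary-territory
insult) and coupled to the longitudinal direction with configurable
strength.  Partial attenuation raises the strain CoV; uniform
attenuation of all segments does not (CoV is scale-invariant) — the
contrast that motivates heterogeneity biomarkers.

QC artifacts (sign flips, extreme outliers, segment dropout, empty
participants) are injected at configurable rates with a ledger of every
corrupted cell, so QC recall/precision is measurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .strain_biomarkers import DIRECTIONS, RAW_SIGN, N_SEGMENTS

ENDPOINTS = ("composite_cv", "mi", "hf", "arrhythmia", "death")

# Ring/level adjacency of the 16-segment model: basal ring 1-6, mid ring
# 7-12, apical ring 13-16; basal<->mid aligned 1:1, mid<->apical by a
# coarse 6:4 alignment.  Used to grow contiguous lesion patches.
_ADJACENCY: dict[int, set[int]] = {}


def _build_adjacency() -> dict[int, set[int]]:
    adj: dict[int, set[int]] = {s: set() for s in range(1, 17)}

    def link(a, b):
        adj[a].add(b)
        adj[b].add(a)

    for ring in ((1, 2, 3, 4, 5, 6), (7, 8, 9, 10, 11, 12), (13, 14, 15, 16)):
        for i, s in enumerate(ring):
            link(s, ring[(i + 1) % len(ring)])
    for s in range(1, 7):          # basal <-> mid
        link(s, s + 6)
    for a, mids in {13: (7, 8), 14: (9, 10), 15: (10, 11), 16: (12, 7)}.items():
        for m in mids:             # mid <-> apical (6:4 alignment)
            link(a, m)
    return adj


_ADJACENCY = _build_adjacency()


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort.

    Defaults place healthy cohort medians near published normal values:
    global strain magnitudes ~18.4% (longitudinal), 18.9%
    (circumferential), 31.4% (radial) and strain CoV medians near
    0.33 / 0.16 / 0.28.  Follow-up emulates a skewed accrual pattern
    (administrative cutoff at 6.5 years plus uniform dropout) giving a
    median near 5 years.
    """

    n_participants: int = 2000
    seed: int = 0

    # strain model (percent, absolute scale)
    direction_means: dict = field(default_factory=lambda: {
        "longitudinal": 18.4, "circumferential": 18.9, "radial": 31.4})
    between_participant_sd: dict = field(default_factory=lambda: {
        "longitudinal": 1.3, "circumferential": 2.0, "radial": 5.1})
    between_segment_sd: dict = field(default_factory=lambda: {
        "longitudinal": 6.1, "circumferential": 3.0, "radial": 8.8})
    #: segment-noise and participant-effect correlation between the
    #: circumferential and radial directions (emulates their strongly
    #: correlated CoV)
    cs_rs_corr: float = 0.95

    # lesion model
    lesion_prevalence: float = 0.0
    lesion_n_segments: int = 4
    lesion_attenuation: float = 0.5     # multiplies affected |strain|
    #: relative lesion odds for participants with prevalent CVD flags and
    #: with risk factors only, vs flag-free participants; probabilities
    #: are renormalized so the cohort mean stays at lesion_prevalence
    lesion_cvd_odds: float = 12.0
    lesion_risk_odds: float = 4.0
    #: how strongly the longitudinal direction shares the lesion:
    #: 0 = unaffected, 1 = same attenuation as circumferential/radial
    lesion_ls_coupling: float = 0.5
    #: LVEF points subtracted for lesioned participants
    lesion_lvef_shift: float = 5.0

    # artifact injection rates
    artifact_rates: dict = field(default_factory=lambda: {
        "sign_flip": 0.0, "extreme_outlier": 0.0,
        "segment_dropout": 0.0, "empty_participant": 0.0})

    # covariates (prevalences of binary risk factors / disease flags)
    covariate_prevalences: dict = field(default_factory=lambda: {
        "ethnicity_white": 0.97, "current_smoker": 0.034,
        "dyslipidemia": 0.312, "hypertension": 0.287, "diabetes": 0.063,
        "ckd": 0.079, "cad": 0.061, "prev_mi": 0.026,
        "cerebrovascular": 0.015, "pvd": 0.007, "af": 0.031, "va": 0.002,
        "aortic_stenosis": 0.002, "mitral_disease": 0.005,
        "acm": 0.0003, "dcm": 0.0006, "hcm": 0.0009, "prev_hf": 0.007,
        "male": 0.477})
    age_mean: float = 65.4
    age_sd: float = 7.7
    bmi_mean: float = 26.5
    bmi_sd: float = 4.5

    # outcome model: endpoint -> {term: log hazard ratio}.  Continuous
    # terms (age, bmi, true biomarkers) enter z-scored, binaries as 0/1.
    log_hazard_ratios: dict = field(default_factory=lambda: {
        "composite_cv": {"age": 0.50, "male": 0.30, "hypertension": 0.30,
                         "diabetes": 0.30, "current_smoker": 0.30,
                         "cov_cs": math.log(1.10), "gls": -0.26},
        "mi": {"age": 0.40, "male": 0.50, "current_smoker": 0.40,
               "dyslipidemia": 0.30},
        "hf": {"age": 0.50, "male": 0.30, "hypertension": 0.35,
               "diabetes": 0.40, "cov_cs": math.log(1.20), "gls": -0.40},
        "arrhythmia": {"age": 0.55, "male": 0.30,
                       "cov_cs": math.log(1.11), "gls": -0.29},
        "death": {"age": 0.70, "male": 0.35, "current_smoker": 0.40,
                  "cov_cs": math.log(1.10), "gls": -0.17}})
    #: endpoint -> (Weibull shape, Weibull scale in years)
    baseline_hazard: dict = field(default_factory=lambda: {
        "composite_cv": (1.3, 100.0), "mi": (1.3, 273.0), "hf": (1.3, 248.0),
        "arrhythmia": (1.3, 136.0), "death": (1.3, 185.0)})
    admin_censor_time: float = 6.5
    dropout_probability: float = 0.65

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ValueError("invalid config field n_participants: must be >= 1")
        if not (0 <= self.lesion_prevalence <= 1):
            raise ValueError("invalid config field lesion_prevalence: "
                             "must be in [0, 1]")
        if not (1 <= self.lesion_n_segments <= N_SEGMENTS):
            raise ValueError("invalid config field lesion_n_segments: "
                             "must be in 1..16")
        if not (0 <= self.lesion_attenuation <= 1):
            raise ValueError("invalid config field lesion_attenuation: "
                             "must be in [0, 1]")
        if self.lesion_cvd_odds <= 0 or self.lesion_risk_odds <= 0:
            raise ValueError("invalid config field lesion_*_odds: must be > 0")
        if not (0 <= self.lesion_ls_coupling <= 1):
            raise ValueError("invalid config field lesion_ls_coupling: "
                             "must be in [0, 1]")
        if not (-1 <= self.cs_rs_corr <= 1):
            raise ValueError("invalid config field cs_rs_corr: "
                             "must be in [-1, 1]")
        for k, v in self.artifact_rates.items():
            if not (0 <= v <= 1):
                raise ValueError(f"invalid config field artifact_rates[{k}]: "
                                 "must be in [0, 1]")
        for k, v in self.covariate_prevalences.items():
            if not (0 <= v <= 1):
                raise ValueError("invalid config field "
                                 f"covariate_prevalences[{k}]: must be in [0, 1]")
        if self.admin_censor_time <= 0:
            raise ValueError("invalid config field admin_censor_time: "
                             "must be > 0")
        if not (0 <= self.dropout_probability <= 1):
            raise ValueError("invalid config field dropout_probability: "
                             "must be in [0, 1]")
        for d in DIRECTIONS:
            if self.direction_means[d] <= 0:
                raise ValueError(f"invalid config field direction_means[{d}]: "
                                 "must be > 0 (absolute scale)")
            if self.between_segment_sd[d] < 0 or self.between_participant_sd[d] < 0:
                raise ValueError(f"invalid config field sd[{d}]: must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class CohortTable:
    """A simulated (or ingested) cohort ready for the analysis stack.

    ``covariates`` holds one row per participant (clinical covariates,
    volumetrics); ``strain_long`` is the long-format segmental strain
    table (participant_id, direction, segment, value); ``outcomes`` one
    row per participant × endpoint; ``truth`` and ``ledger`` carry the
    generator's ground truth (lesion status, clean biomarkers) and the
    artifact-injection ledger when simulated.
    """

    covariates: pd.DataFrame
    strain_long: pd.DataFrame
    outcomes: pd.DataFrame
    truth: pd.DataFrame | None = None
    ledger: pd.DataFrame | None = None
    config: SimulationConfig | None = None


def grow_lesion_mask(n_segments: int, rng) -> np.ndarray:
    """One contiguous lesion patch of ``n_segments`` on the AHA graph."""
    start = int(rng.integers(1, N_SEGMENTS + 1))
    patch = {start}
    while len(patch) < n_segments:
        frontier = sorted(set().union(*(_ADJACENCY[s] for s in patch)) - patch)
        patch.add(int(frontier[int(rng.integers(len(frontier)))]))
    mask = np.zeros(N_SEGMENTS, dtype=bool)
    mask[[s - 1 for s in patch]] = True
    return mask


def simulate_segmental_strain(participant_effects: dict, config: SimulationConfig,
                              rng) -> dict[str, np.ndarray]:
    """Raw signed segmental strain per direction for a block of participants.

    ``participant_effects`` maps each direction to an (n,) array of
    participant-level effects and optionally carries ``"lesion_mask"``,
    an (n, 16) boolean array of attenuated segments.  Returns a dict
    direction -> (n, 16) raw signed values.
    """
    n = len(next(iter(participant_effects[d] for d in DIRECTIONS)))
    lesion_mask = participant_effects.get("lesion_mask")
    z_cs = rng.standard_normal((n, N_SEGMENTS))
    z_rs_ind = rng.standard_normal((n, N_SEGMENTS))
    z_ls = rng.standard_normal((n, N_SEGMENTS))
    rho = config.cs_rs_corr
    noise = {
        "circumferential": config.between_segment_sd["circumferential"] * z_cs,
        "radial": config.between_segment_sd["radial"]
        * (rho * z_cs + math.sqrt(1 - rho ** 2) * z_rs_ind),
        "longitudinal": config.between_segment_sd["longitudinal"] * z_ls,
    }
    atten = {
        "circumferential": config.lesion_attenuation,
        "radial": config.lesion_attenuation,
        "longitudinal": 1.0 - config.lesion_ls_coupling
        * (1.0 - config.lesion_attenuation),
    }
    out = {}
    for d in DIRECTIONS:
        mag = (config.direction_means[d]
               + participant_effects[d][:, None] + noise[d])
        if lesion_mask is not None:
            mag = np.where(lesion_mask, mag * atten[d], mag)
        out[d] = RAW_SIGN[d] * mag
    return out


def _participant_effects(config: SimulationConfig, rng,
                         lesion: np.ndarray) -> dict:
    n = len(lesion)
    z_cs = rng.standard_normal(n)
    z_rs = rng.standard_normal(n)
    z_ls = rng.standard_normal(n)
    rho = config.cs_rs_corr
    eff = {
        "circumferential": config.between_participant_sd["circumferential"] * z_cs,
        "radial": config.between_participant_sd["radial"]
        * (rho * z_cs + math.sqrt(1 - rho ** 2) * z_rs),
        "longitudinal": config.between_participant_sd["longitudinal"] * z_ls,
    }
    if lesion.any() and config.lesion_attenuation < 1:
        masks = np.zeros((n, N_SEGMENTS), dtype=bool)
        for i in np.flatnonzero(lesion):
            masks[i] = grow_lesion_mask(config.lesion_n_segments, rng)
        eff["lesion_mask"] = masks
    return eff


def strain_arrays_to_long(arrays: dict[str, np.ndarray],
                          participant_ids) -> pd.DataFrame:
    """dict direction -> (n, 16) array into the long strain table."""
    frames = []
    pid = np.asarray(participant_ids)
    for d in DIRECTIONS:
        a = arrays[d]
        frames.append(pd.DataFrame({
            "participant_id": np.repeat(pid, N_SEGMENTS),
            "direction": d,
            "segment": np.tile(np.arange(1, N_SEGMENTS + 1), len(pid)),
            "value": a.ravel()}))
    return pd.concat(frames, ignore_index=True)


def inject_artifacts(strain_long: pd.DataFrame, artifact_rates: dict, rng):
    """Corrupt a clean strain table at the configured rates.

    Artifact kinds: ``sign_flip`` (value negated), ``extreme_outlier``
    (magnitude replaced by a value beyond the clean cohort's
    Q3 + 3×IQR fence, correct sign), ``segment_dropout`` (cell set to
    missing), ``empty_participant`` (all of a participant's cells set to
    missing).  Each cell receives at most one artifact.  Returns the
    corrupted table and a ledger recording every corrupted cell
    (participant_id, direction, segment, kind, original, corrupted).
    """
    df = strain_long.copy().reset_index(drop=True)
    rates = {k: float(artifact_rates.get(k, 0.0)) for k in
             ("sign_flip", "extreme_outlier", "segment_dropout",
              "empty_participant")}
    ledger_rows = []

    # per-direction clean-magnitude fences used to construct outliers
    fence = {}
    for d in df["direction"].unique():
        v = df.loc[df["direction"] == d, "value"].abs().dropna()
        q1, q3 = np.percentile(v, [25, 75])
        fence[d] = (q3, q3 - q1)

    pids = df["participant_id"].unique()
    n_empty = int(round(rates["empty_participant"] * len(pids)))
    empty_pids = set(rng.choice(pids, size=n_empty, replace=False)) \
        if n_empty else set()

    cells = df.index[df["value"].notna()
                     & ~df["participant_id"].isin(empty_pids)].to_numpy()
    rng.shuffle(cells)
    n_flip = int(round(rates["sign_flip"] * len(cells)))
    n_out = int(round(rates["extreme_outlier"] * len(cells)))
    n_drop = int(round(rates["segment_dropout"] * len(cells)))
    flip_idx = cells[:n_flip]
    out_idx = cells[n_flip:n_flip + n_out]
    drop_idx = cells[n_flip + n_out:n_flip + n_out + n_drop]

    def record(idx, kind, new_values):
        for i, nv in zip(idx, new_values):
            ledger_rows.append({
                "participant_id": df.at[i, "participant_id"],
                "direction": df.at[i, "direction"],
                "segment": df.at[i, "segment"],
                "kind": kind, "original": df.at[i, "value"],
                "corrupted": nv})
            df.at[i, "value"] = nv

    record(flip_idx, "sign_flip", -df.loc[flip_idx, "value"].to_numpy())

    new_out = []
    for i in out_idx:
        d = df.at[i, "direction"]
        q3, iqr = fence[d]
        mag = q3 + (3.0 + rng.uniform(1.0, 5.0)) * max(iqr, 1e-6)
        new_out.append(math.copysign(mag, df.at[i, "value"]))
    record(out_idx, "extreme_outlier", new_out)

    record(drop_idx, "segment_dropout", [math.nan] * len(drop_idx))

    empty_cells = df.index[df["participant_id"].isin(empty_pids)
                           & df["value"].notna()]
    record(empty_cells, "empty_participant", [math.nan] * len(empty_cells))

    ledger = pd.DataFrame(ledger_rows, columns=[
        "participant_id", "direction", "segment", "kind", "original",
        "corrupted"])
    return df, ledger


def simulate_outcomes(linear_predictors: pd.DataFrame,
                      config: SimulationConfig, rng,
                      prevalent: pd.DataFrame | None = None) -> pd.DataFrame:
    """Weibull proportional-hazards event times per endpoint.

    ``linear_predictors`` has one column per endpoint.  Event times are
    drawn by inverse transform from S(t) = exp(-(t/scale)^shape * e^lp)
    and censored at min(administrative cutoff, uniform dropout).  Death
    is censoring for the non-fatal endpoints (cause-specific hazards).
    """
    if not np.isfinite(linear_predictors.to_numpy(dtype=float)).all():
        raise ValueError("non-finite linear predictor")
    n = len(linear_predictors)
    admin = config.admin_censor_time
    drop = rng.random(n) < config.dropout_probability
    censor = np.where(drop, rng.uniform(0, admin, n), admin)
    censor = np.maximum(censor, 1e-9)
    records = []
    pid = linear_predictors.index.to_numpy()
    for ep in linear_predictors.columns:
        shape, scale = config.baseline_hazard[ep]
        lp = linear_predictors[ep].to_numpy(dtype=float)
        u = rng.random(n)
        t_event = scale * (-np.log(u) / np.exp(lp)) ** (1.0 / shape)
        time = np.minimum(t_event, censor)
        event = t_event <= censor
        prev = prevalent[ep].to_numpy() \
            if prevalent is not None and ep in prevalent \
            else np.zeros(n, dtype=bool)
        records.append(pd.DataFrame({
            "participant_id": pid, "endpoint": ep, "time": time,
            "event": event, "prevalent": prev}))
    return pd.concat(records, ignore_index=True)


def _true_biomarkers(arrays: dict[str, np.ndarray]) -> pd.DataFrame:
    """Clean (pre-artifact) biomarkers used to drive the hazard model."""
    out = {}
    for d, (g_col, cov_col) in {
            "longitudinal": ("gls", "cov_ls"),
            "circumferential": ("gcs", "cov_cs"),
            "radial": ("grs", "cov_rs")}.items():
        a = np.abs(arrays[d])
        out[g_col] = a.mean(axis=1)
        out[cov_col] = a.std(axis=1, ddof=1) / a.mean(axis=1)
    return pd.DataFrame(out)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def linear_predictors(covariates: pd.DataFrame, truth: pd.DataFrame,
                      config: SimulationConfig) -> pd.DataFrame:
    """Per-endpoint linear predictors from the configured log HRs."""
    cols = {}
    design = pd.concat([covariates.reset_index(drop=True),
                        truth.reset_index(drop=True)], axis=1)
    for ep, betas in config.log_hazard_ratios.items():
        lp = np.zeros(len(design))
        for term, beta in betas.items():
            if term not in design.columns:
                raise ValueError(f"unknown hazard term {term!r} for {ep!r}")
            x = design[term].to_numpy(dtype=float)
            if design[term].dtype == bool or set(np.unique(x)) <= {0.0, 1.0}:
                lp += beta * x
            else:
                lp += beta * _zscore(x)
        cols[ep] = lp
    out = pd.DataFrame(cols, index=covariates["participant_id"])
    # endpoints are those with a configured baseline hazard
    endpoints = [ep for ep in (*ENDPOINTS, *config.baseline_hazard)
                 if ep in config.baseline_hazard]
    endpoints = list(dict.fromkeys(endpoints))
    for ep in endpoints:
        if ep not in out.columns:
            out[ep] = 0.0
    return out[endpoints]


def _covariates(config: SimulationConfig, rng) -> pd.DataFrame:
    n = config.n_participants
    cov = pd.DataFrame({"participant_id": np.arange(1, n + 1)})
    cov["age"] = np.clip(rng.normal(config.age_mean, config.age_sd, n), 40, 90)
    cov["bmi"] = np.clip(rng.normal(config.bmi_mean, config.bmi_sd, n), 15, 55)
    for name, p in config.covariate_prevalences.items():
        cov[name] = rng.random(n) < p
    cov["obesity"] = cov["bmi"] >= 30.0
    return cov


def _volumetrics(config: SimulationConfig, rng, lesion: np.ndarray) -> pd.DataFrame:
    n = config.n_participants
    lvmi = np.exp(rng.normal(math.log(44.8), 0.13, n))
    lvedvi = np.exp(rng.normal(math.log(76.5), 0.12, n))
    lvef = rng.normal(60.5, 5.5, n) - config.lesion_lvef_shift * lesion
    lvef = np.clip(lvef, 10.0, 82.0)
    lvesvi = lvedvi * (1 - lvef / 100.0)
    return pd.DataFrame({"lvmi": lvmi, "lvedvi": lvedvi, "lvesvi": lvesvi,
                         "lvef": lvef, "lvmvr": lvmi / lvedvi})


_CVD_FLAGS = ("cad", "prev_mi", "cerebrovascular", "pvd", "af", "va",
              "aortic_stenosis", "mitral_disease", "acm", "dcm", "hcm",
              "prev_hf")
_RISK_FLAGS = ("hypertension", "diabetes", "dyslipidemia", "current_smoker",
               "obesity", "ckd")


def _lesion_probability(cov: pd.DataFrame, config: SimulationConfig
                        ) -> np.ndarray:
    """Per-participant lesion probability, concentrated in diseased
    participants so the healthy-reference subset is mostly lesion-free."""
    any_cvd = cov[list(_CVD_FLAGS)].any(axis=1).to_numpy()
    any_risk = ~any_cvd & cov[list(_RISK_FLAGS)].any(axis=1).to_numpy()
    w = np.where(any_cvd, config.lesion_cvd_odds,
                 np.where(any_risk, config.lesion_risk_odds, 1.0))
    if w.mean() == 0:
        return np.zeros(len(w))
    return np.clip(config.lesion_prevalence * w / w.mean(), 0.0, 1.0)


def _prevalent_flags(cov: pd.DataFrame) -> pd.DataFrame:
    """Endpoint-wise prevalent-disease indicators (baseline exclusions)."""
    prev = pd.DataFrame(index=cov.index)
    prev["mi"] = cov["prev_mi"]
    prev["hf"] = cov["prev_hf"]
    prev["arrhythmia"] = cov["af"] | cov["va"]
    prev["composite_cv"] = prev["mi"] | prev["hf"] | prev["arrhythmia"]
    prev["death"] = False
    return prev


def simulate_cohort(config: SimulationConfig) -> CohortTable:
    """Generate a full cohort: covariates, strain, outcomes, ledger.

    Deterministic under ``config.seed``.  Hazards are driven by the
    *clean* (pre-artifact) biomarkers, so QC quality determines how well
    downstream models recover the configured effects.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    cov = _covariates(config, rng)
    lesion = rng.random(config.n_participants) < _lesion_probability(cov, config)
    vol = _volumetrics(config, rng, lesion)
    cov = pd.concat([cov, vol], axis=1)

    eff = _participant_effects(config, rng, lesion)
    arrays = simulate_segmental_strain(eff, config, rng)
    truth = _true_biomarkers(arrays)
    truth["lesion"] = lesion

    lp = linear_predictors(cov, truth, config)
    outcomes = simulate_outcomes(lp, config, rng, prevalent=_prevalent_flags(cov))

    strain_long = strain_arrays_to_long(arrays, cov["participant_id"])
    strain_long, ledger = inject_artifacts(strain_long, config.artifact_rates,
                                           rng)
    truth.insert(0, "participant_id", cov["participant_id"].to_numpy())
    return CohortTable(covariates=cov, strain_long=strain_long,
                       outcomes=outcomes, truth=truth, ledger=ledger,
                       config=config)
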