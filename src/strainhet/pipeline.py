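"""End-to-end orchestration: simulate/ingest → QC → biomarkers →
reference ranges → descriptives → Cox model stack → sensitivity
analyses → KM panels → report.

All tables are comma-delimited UTF-8 with a header row; the run summary
is JSON carrying seeds, options and provenance, so a run is regenerable
bit-identically from (config, seed).
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .strain_biomarkers import (DIRECTIONS, N_SEGMENTS, apply_qc)
from .synthetic_cohort import (CohortTable, SimulationConfig, ENDPOINTS,
                               simulate_cohort)
from .cohort_descriptives import (select_healthy_reference,
                                  reference_range_table,
                                  regional_abnormality_flags,
                                  descriptive_table)
from .survival_models import (ModelSpec, build_modeling_frame, fit_cox,
                              model_comparison, subgroup_analysis)
from .nonlinearity_km import test_nonlinearity, stratified_tertile_km

COV_BIOMARKERS = ("cov_ls", "cov_cs", "cov_rs")
ALL_BIOMARKERS = ("cov_ls", "cov_cs", "cov_rs", "gls", "gcs", "grs")


@dataclass
class RunConfig:
    """Declarative configuration of a full pipeline run."""

    seed: int = 0
    out_dir: str = "strainhet_run"
    # either a simulation block or input paths
    simulation: dict | None = None
    covariates_path: str | None = None
    strain_path: str | None = None
    outcomes_path: str | None = None
    # QC options
    fence_multiplier: float = 3.0
    min_segments: int = 7
    sd_ddof: int = 1
    fence_scope: str = "both"
    # analysis options
    endpoints: tuple = ENDPOINTS
    biomarkers: tuple = COV_BIOMARKERS
    bootstrap_B: int = 200
    horizon: float = 5.0
    knot_rule: str = "tails"
    tertile_scope: str = "stratum"
    bonferroni_m: int = 15
    run_subgroups: bool = False
    run_nonlinearity: bool = True
    run_km: bool = True

    def validate(self) -> None:
        has_sim = self.simulation is not None
        has_paths = self.covariates_path is not None \
            and self.strain_path is not None \
            and self.outcomes_path is not None
        if not (has_sim or has_paths):
            raise ValueError("config needs either a simulation block or "
                             "input paths")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["endpoints"] = list(self.endpoints)
        d["biomarkers"] = list(self.biomarkers)
        return d


@dataclass
class AnalysisReport:
    """Everything a run produces, with provenance."""

    qc_waterfall: dict
    reference_ranges: pd.DataFrame
    descriptives: pd.DataFrame
    model_tables: pd.DataFrame
    nonlinearity: pd.DataFrame
    km_panels: pd.DataFrame
    subgroups: dict
    provenance: dict


# ---------------------------------------------------------------------------
# IO


def write_cohort(cohort: CohortTable, out_dir) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"covariates": out / "covariates.csv",
             "strain": out / "strain_long.csv",
             "outcomes": out / "outcomes.csv"}
    cohort.covariates.to_csv(paths["covariates"], index=False)
    cohort.strain_long.to_csv(paths["strain"], index=False)
    cohort.outcomes.to_csv(paths["outcomes"], index=False)
    if cohort.ledger is not None:
        paths["ledger"] = out / "injection_ledger.csv"
        cohort.ledger.to_csv(paths["ledger"], index=False)
    if cohort.truth is not None:
        paths["truth"] = out / "truth.csv"
        cohort.truth.to_csv(paths["truth"], index=False)
    return {k: str(v) for k, v in paths.items()}


def _strain_wide_to_long(wide: pd.DataFrame) -> pd.DataFrame:
    frames = []
    for d in DIRECTIONS:
        cols = [f"{d}_s{s}" for s in range(1, N_SEGMENTS + 1)]
        missing = [c for c in cols if c not in wide.columns]
        if missing:
            raise ValueError(f"wide strain table missing columns: {missing}")
        block = wide[["participant_id", *cols]].melt(
            id_vars="participant_id", var_name="segment", value_name="value")
        block["segment"] = block["segment"].str.rsplit("s", n=1).str[-1].astype(int)
        block["direction"] = d
        frames.append(block[["participant_id", "direction", "segment", "value"]])
    return pd.concat(frames, ignore_index=True)


def read_cohort_tables(covariates_path, strain_path, outcomes_path
                       ) -> CohortTable:
    """Load delimited cohort tables; strain accepted long or wide.

    Unparseable numeric cells become missing; duplicate
    participant-direction-segment rows are an error.
    """
    cov = pd.read_csv(covariates_path)
    if "participant_id" not in cov.columns:
        raise ValueError("covariates table missing column: participant_id")
    strain = pd.read_csv(strain_path)
    if "direction" in strain.columns:        # long dialect
        required = {"participant_id", "direction", "segment", "value"}
        missing = required - set(strain.columns)
        if missing:
            raise ValueError(f"strain table missing columns: {sorted(missing)}")
        strain = strain[list(required)].copy()
        strain["value"] = pd.to_numeric(strain["value"], errors="coerce")
        strain["segment"] = strain["segment"].astype(int)
    else:                                     # wide dialect
        for c in strain.columns:
            if c != "participant_id":
                strain[c] = pd.to_numeric(strain[c], errors="coerce")
        strain = _strain_wide_to_long(strain)
    strain = strain[["participant_id", "direction", "segment", "value"]]
    dup = strain.duplicated(["participant_id", "direction", "segment"])
    if dup.any():
        raise ValueError(f"{int(dup.sum())} duplicate "
                         "participant-direction-segment rows")
    outcomes = pd.read_csv(outcomes_path)
    required = {"participant_id", "endpoint", "time", "event"}
    missing = required - set(outcomes.columns)
    if missing:
        raise ValueError(f"outcomes table missing columns: {sorted(missing)}")
    if "prevalent" not in outcomes.columns:
        outcomes["prevalent"] = False
    for c in ("event", "prevalent"):
        outcomes[c] = outcomes[c].astype(bool)
    return CohortTable(covariates=cov, strain_long=strain, outcomes=outcomes)


# ---------------------------------------------------------------------------
# pipeline


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_or_simulate(config: RunConfig) -> CohortTable:
    if config.simulation is not None:
        sim = SimulationConfig(**config.simulation)
        if "seed" not in config.simulation:
            sim.seed = config.seed
        return simulate_cohort(sim)
    return read_cohort_tables(config.covariates_path, config.strain_path,
                              config.outcomes_path)


def run_pipeline(config: RunConfig, out_dir=None) -> AnalysisReport:
    """Execute every stage and persist all intermediate tables."""
    config.validate()
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "simulate/ingest"
    try:
        cohort = load_or_simulate(config)
        write_cohort(cohort, out)

        stage = "qc"
        clean_long, biomarkers, qc_report = apply_qc(
            cohort.strain_long, fence_multiplier=config.fence_multiplier,
            min_segments=config.min_segments, ddof=config.sd_ddof,
            fence_scope=config.fence_scope)
        biomarkers_out = biomarkers.drop(
            columns=[c for c in biomarkers.columns if c.startswith("qc_flags")])
        biomarkers_out.to_csv(out / "biomarkers.csv", index=False)

        stage = "reference_ranges"
        healthy = select_healthy_reference(cohort.covariates)
        healthy_ids = healthy["participant_id"]
        ranges = reference_range_table(biomarkers, healthy_ids,
                                       strain_long=clean_long)
        ranges.to_csv(out / "reference_ranges.csv", index=False)
        regional = regional_abnormality_flags(clean_long, biomarkers,
                                              healthy_ids)
        regional.to_csv(out / "regional_flags.csv", index=False)

        stage = "descriptives"
        joined = cohort.covariates.merge(biomarkers, on="participant_id")
        desc = descriptive_table(
            joined, joined["male"].map({True: "male", False: "female"}))
        desc.to_csv(out / "descriptives.csv", index=False)

        stage = "cox_models"
        frame = build_modeling_frame(cohort.covariates, biomarkers,
                                     cohort.outcomes, regional_flags=regional)
        model_rows = []
        comparisons = {}
        for bm in config.biomarkers:
            for ep in config.endpoints:
                for tier in (1, 2, 3):
                    spec = ModelSpec(endpoint=ep, biomarker=bm, tier=tier)
                    try:
                        fit = fit_cox(spec, frame)
                    except (ValueError, RuntimeError) as err:
                        model_rows.append({"endpoint": ep, "biomarker": bm,
                                           "tier": tier, "error": str(err)})
                        continue
                    row = {"endpoint": ep, "biomarker": bm, "tier": tier,
                           "n": fit.n, "n_events": fit.n_events,
                           "hr": fit.focal_hr,
                           "hr_lower": fit.focal_ci[0],
                           "hr_upper": fit.focal_ci[1],
                           "p_raw": float(fit.summary.loc[fit.focal, "p_raw"]),
                           "p_bonferroni": min(
                               1.0, config.bonferroni_m
                               * float(fit.summary.loc[fit.focal, "p_raw"]))}
                    if tier == 3:
                        cmp = model_comparison(spec, frame,
                                               B=config.bootstrap_B,
                                               seed=config.seed,
                                               horizon=config.horizon)
                        row.update({k: cmp[k] for k in (
                            "c_index", "delta_c", "delta_c_p", "nri_percent",
                            "delta_brier", "delta_aic", "lrt_chi2", "lrt_p")})
                        comparisons[(bm, ep)] = cmp
                    model_rows.append(row)
        model_tables = pd.DataFrame(model_rows)
        model_tables.to_csv(out / "model_tables.csv", index=False)

        stage = "subgroups"
        subgroups = {}
        if config.run_subgroups:
            for bm in config.biomarkers:
                for ep in config.endpoints:
                    spec = ModelSpec(endpoint=ep, biomarker=bm, tier=3)
                    res = subgroup_analysis(frame, spec)
                    subgroups[f"{bm}:{ep}"] = {
                        name: ({"hr": r.focal_hr, "ci": r.focal_ci,
                                "n": r.n, "n_events": r.n_events}
                               if hasattr(r, "focal_hr") else r)
                        for name, r in res.items()}

        stage = "nonlinearity"
        nl_rows = []
        if config.run_nonlinearity:
            for bm in config.biomarkers:
                for ep in config.endpoints:
                    spec = ModelSpec(endpoint=ep, biomarker=bm, tier=3)
                    try:
                        nl = test_nonlinearity(spec, frame,
                                               knot_rule=config.knot_rule)
                        nl_rows.append({"endpoint": ep, "biomarker": bm,
                                        **{k: nl[k] for k in
                                           ("chi2", "df", "p", "knot_rule")}})
                    except (ValueError, RuntimeError) as err:
                        nl_rows.append({"endpoint": ep, "biomarker": bm,
                                        "error": str(err)})
        nonlinearity = pd.DataFrame(nl_rows)
        if not nonlinearity.empty:
            nonlinearity.to_csv(out / "nonlinearity.csv", index=False)

        stage = "km"
        km_panels = pd.DataFrame()
        if config.run_km:
            km_panels = stratified_tertile_km(
                frame, biomarkers=tuple(config.biomarkers),
                endpoints=tuple(config.endpoints),
                tertile_scope=config.tertile_scope)
            km_panels.drop(columns=["curves"]).to_csv(
                out / "km_trend_tests.csv", index=False)
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    provenance = {"config_hash": _config_hash(config), "seed": config.seed,
                  "version": __version__, "config": config.to_dict()}
    report = AnalysisReport(
        qc_waterfall=qc_report.to_dict(), reference_ranges=ranges,
        descriptives=desc, model_tables=model_tables,
        nonlinearity=nonlinearity, km_panels=km_panels,
        subgroups=subgroups, provenance=provenance)
    summary = {
        "qc_waterfall": report.qc_waterfall,
        "subgroups": subgroups,
        "provenance": provenance}
    with open(out / "report.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=_jsonify)
    return report


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.ndarray, tuple, set)):
        return list(obj)
    if isinstance(obj, float) and math.isnan(obj):
        return None
    return str(obj)
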