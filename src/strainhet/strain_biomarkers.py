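"""Segmental strain quality control and heterogeneity biomarkers.

The left ventricle is divided into 16 AHA segments (6 basal, 6 mid,
4 apical; no apical cap).  Feature-tracking software reports peak
systolic strain per segment and direction with a conventional raw sign:
longitudinal and circumferential shortening are negative, radial
thickening is positive.  Biomarkers are computed on absolute values:

* global strain (GLS/GCS/GRS) — mean of |Y_i| over valid segments;
  lower values mean worse global contractile function.
* strain CoV (CoV_LS/CoV_CS/CoV_RS) — SD(|Y_i|) / mean(|Y_i|) — a
  dimensionless index of contractile heterogeneity; higher values mean
  more regional dysfunction.

The QC cascade mirrors automated-pipeline practice: drop participants
with no strain at all, invalidate physiologically non-sensical signs,
censor values beyond 3×IQR fences computed at cohort level, and refuse
to compute a CoV from 6 or fewer valid segments.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

N_SEGMENTS = 16
SEGMENTS = tuple(range(1, N_SEGMENTS + 1))

DIRECTIONS = ("longitudinal", "circumferential", "radial")

#: conventional sign of raw peak systolic strain per direction
RAW_SIGN = {"longitudinal": -1.0, "circumferential": -1.0, "radial": 1.0}

#: direction -> (global strain column, CoV column) naming used throughout
BIOMARKER_COLUMNS = {
    "longitudinal": ("gls", "cov_ls"),
    "circumferential": ("gcs", "cov_cs"),
    "radial": ("grs", "cov_rs"),
}

DEFAULT_MIN_SEGMENTS = 7  # CoV from <= 6 valid segments is not reported
DEFAULT_FENCE_MULTIPLIER = 3.0


def validate_sign(value, direction: str):
    """True iff a raw strain value has the physiologically expected sign.

    Longitudinal and circumferential strain must be negative, radial
    strain positive; zero and non-finite values are invalid everywhere.
    Accepts scalars or arrays.
    """
    if direction not in RAW_SIGN:
        raise ValueError(f"unknown direction: {direction!r}")
    v = np.asarray(value, dtype=float)
    ok = np.isfinite(v) & (v * RAW_SIGN[direction] > 0)
    return bool(ok) if np.isscalar(value) else ok


def cohort_outlier_fences(values, multiplier: float = DEFAULT_FENCE_MULTIPLIER):
    """IQR outlier fences ``(Q1 - m*IQR, Q3 + m*IQR)`` for a cohort metric.

    Quartiles use linear interpolation between order statistics.  Values
    strictly outside the fences are considered outliers; values exactly
    on a fence are retained.  Requires at least 4 finite values.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 4:
        raise ValueError("outlier fences need at least 4 finite values")
    q1, q3 = np.percentile(v, [25.0, 75.0])
    iqr = q3 - q1
    return q1 - multiplier * iqr, q3 + multiplier * iqr


def global_strain(values):
    """Mean absolute strain over valid (finite) segments; NaN if none."""
    v = np.abs(np.asarray(values, dtype=float))
    v = v[np.isfinite(v)]
    if v.size == 0:
        return math.nan
    return float(v.mean())


def strain_cov(values, min_segments: int = DEFAULT_MIN_SEGMENTS, ddof: int = 1):
    """Coefficient of variation SD(|Y|)/mean(|Y|) of valid segments.

    Returns NaN when fewer than ``min_segments`` valid values are
    available or when the mean is zero.  ``ddof=1`` (sample SD) is the
    default; ``ddof=0`` gives the population SD.
    """
    v = np.abs(np.asarray(values, dtype=float))
    v = v[np.isfinite(v)]
    if v.size < max(min_segments, 2):
        return math.nan
    m = v.mean()
    if m == 0:
        return math.nan
    return float(v.std(ddof=ddof) / m)


def standardize(values):
    """Z-scores (x - mean)/SD over non-missing entries; NaN propagates.

    Raises on fewer than 2 non-missing values or zero spread.
    """
    s = pd.Series(np.asarray(values, dtype=float))
    ok = s.notna()
    if ok.sum() < 2:
        raise ValueError("standardize needs at least 2 non-missing values")
    sd = s[ok].std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("standardize: zero spread")
    out = (s - s[ok].mean()) / sd
    return out.to_numpy()


def assess_missing_segment_impact(values, k_range=range(2, N_SEGMENTS + 1),
                                  n_draws: int = 2000, rng=None, ddof: int = 1):
    """Bias/dispersion of CoV when only k of 16 segments are available.

    For each subset size ``k`` the CoV is recomputed over random size-k
    subsets (exhaustively when the number of subsets is within
    ``n_draws``) and compared with the full-set CoV.  The resulting table
    (k, mean CoV, bias vs full set, SD across subsets, whether
    exhaustive) is the evidence surface behind the ≥7-valid-segment rule.
    """
    v = np.abs(np.asarray(values, dtype=float))
    if v.size != N_SEGMENTS or not np.all(np.isfinite(v)):
        raise ValueError("impact assessment needs a complete 16-segment set")
    rng = np.random.default_rng(rng)
    full = strain_cov(v, min_segments=2, ddof=ddof)
    rows = []
    for k in k_range:
        if k < 2:
            raise ValueError("CoV undefined for k < 2 segments")
        n_subsets = math.comb(N_SEGMENTS, k)
        if n_subsets <= n_draws:
            covs = [strain_cov(v[list(idx)], min_segments=2, ddof=ddof)
                    for idx in itertools.combinations(range(N_SEGMENTS), k)]
        else:
            covs = [strain_cov(rng.choice(v, size=k, replace=False),
                               min_segments=2, ddof=ddof)
                    for _ in range(n_draws)]
        covs = np.asarray(covs)
        rows.append({"k": k, "mean_cov": covs.mean(),
                     "bias": covs.mean() - full, "sd": covs.std(ddof=0),
                     "exhaustive": n_subsets <= n_draws})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# QC cascade


@dataclass
class QCReport:
    """Per-step exclusion counts of the strain QC cascade."""

    n_participants_in: int = 0
    n_no_strain: int = 0
    n_cells_in: int = 0
    n_bad_sign: int = 0
    n_segmental_outliers: int = 0
    n_biomarker_outliers: int = 0
    n_too_few_segments: int = 0  # participant-directions losing their CoV
    n_participants_out: int = 0
    fences: dict = field(default_factory=dict)
    options: dict = field(default_factory=dict)

    @property
    def inclusion_fraction(self) -> float:
        if self.n_participants_in == 0:
            return math.nan
        return self.n_participants_out / self.n_participants_in

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "n_participants_in", "n_no_strain", "n_cells_in", "n_bad_sign",
            "n_segmental_outliers", "n_biomarker_outliers",
            "n_too_few_segments", "n_participants_out")}
        d["inclusion_fraction"] = self.inclusion_fraction
        d["fences"] = self.fences
        d["options"] = self.options
        return d


def _check_long_schema(strain_long: pd.DataFrame) -> None:
    required = {"participant_id", "direction", "segment", "value"}
    missing = required - set(strain_long.columns)
    if missing:
        raise ValueError(f"strain table missing columns: {sorted(missing)}")


def apply_qc(strain_long: pd.DataFrame,
             fence_multiplier: float = DEFAULT_FENCE_MULTIPLIER,
             min_segments: int = DEFAULT_MIN_SEGMENTS,
             ddof: int = 1,
             fence_scope: str = "both"):
    """Run the QC cascade on a long-format cohort strain table.

    Steps, in order: (1) drop participants with no strain measurements
    at all; (2) invalidate wrong-sign values; (3) compute cohort-level
    3×IQR fences on absolute values per direction and invalidate
    segmental outliers, then (optionally) fence the derived global and
    CoV biomarkers; (4) mark participant-directions with fewer than
    ``min_segments`` valid segments as CoV-ineligible.

    ``fence_scope`` chooses what the IQR fences censor: ``"segmental"``,
    ``"biomarker"`` or ``"both"`` (default).

    Returns ``(clean_long, biomarkers, report)``: the input table with a
    boolean ``valid`` column and a ``qc_flag`` string per cell, the
    per-participant biomarker table, and a :class:`QCReport`.
    """
    _check_long_schema(strain_long)
    if fence_scope not in ("segmental", "biomarker", "both"):
        raise ValueError(f"unknown fence_scope: {fence_scope!r}")
    df = strain_long.copy()
    report = QCReport(options={"fence_multiplier": fence_multiplier,
                               "min_segments": min_segments, "ddof": ddof,
                               "fence_scope": fence_scope})
    report.n_participants_in = df["participant_id"].nunique()
    if report.n_participants_in == 0:
        raise ValueError("empty cohort")

    # step 1: participants with no strain measurements
    n_measured = df["value"].notna().groupby(df["participant_id"]).transform("sum")
    has_any = n_measured > 0
    report.n_no_strain = df.loc[~has_any, "participant_id"].nunique()
    df = df[has_any].copy()

    df["valid"] = df["value"].notna()
    df["qc_flag"] = np.where(df["valid"], "", "no_strain")
    report.n_cells_in = int(df["valid"].sum())

    # step 2: sign validity
    for direction in DIRECTIONS:
        sel = (df["direction"] == direction) & df["valid"]
        bad = sel & ~pd.Series(
            validate_sign(df["value"].to_numpy(), direction), index=df.index)
        df.loc[bad, ["valid", "qc_flag"]] = [False, "bad_sign"]
        report.n_bad_sign += int(bad.sum())

    # step 3a: segmental fences on absolute values, per direction
    if fence_scope in ("segmental", "both"):
        for direction in DIRECTIONS:
            sel = (df["direction"] == direction) & df["valid"]
            absval = df.loc[sel, "value"].abs()
            if absval.size < 4:
                continue
            lo, hi = cohort_outlier_fences(absval, fence_multiplier)
            out = sel & ((df["value"].abs() < lo) | (df["value"].abs() > hi))
            df.loc[out, ["valid", "qc_flag"]] = [False, "outlier"]
            report.n_segmental_outliers += int(out.sum())
            report.fences[f"segmental_{direction}"] = (float(lo), float(hi))

    # derived biomarkers from surviving cells
    biomarkers = _biomarker_table(df, min_segments=min_segments, ddof=ddof)

    # step 3b: fences on the derived biomarkers themselves
    if fence_scope in ("biomarker", "both"):
        for direction in DIRECTIONS:
            for col in BIOMARKER_COLUMNS[direction]:
                vals = biomarkers[col]
                if vals.notna().sum() < 4:
                    continue
                lo, hi = cohort_outlier_fences(vals, fence_multiplier)
                out = vals.notna() & ((vals < lo) | (vals > hi))
                biomarkers.loc[out, col] = np.nan
                flag_col = f"qc_flags_{direction}"
                biomarkers.loc[out, flag_col] = biomarkers.loc[
                    out, flag_col].apply(lambda s: s | {"outlier"})
                report.n_biomarker_outliers += int(out.sum())
                report.fences[col] = (float(lo), float(hi))

    for direction in DIRECTIONS:
        n_col = f"n_valid_{direction}"
        few = (biomarkers[n_col] > 0) & (biomarkers[n_col] < min_segments)
        report.n_too_few_segments += int(few.sum())

    report.n_participants_out = int(len(biomarkers))
    return df, biomarkers, report


def _biomarker_table(clean_long: pd.DataFrame, min_segments: int,
                     ddof: int) -> pd.DataFrame:
    """Per-participant biomarker table from a QC-flagged long table."""
    pids = pd.Index(clean_long["participant_id"].unique(),
                    name="participant_id")
    valid = clean_long[clean_long["valid"]].copy()
    valid["absval"] = valid["value"].abs()
    g = valid.groupby(["participant_id", "direction"])["absval"]
    agg = g.agg(n="count", mean="mean", sd="std")  # sample SD (ddof=1)
    if ddof == 0:
        agg["sd"] = agg["sd"] * np.sqrt((agg["n"] - 1) / agg["n"])
    out = pd.DataFrame(index=pids)
    for direction in DIRECTIONS:
        g_col, cov_col = BIOMARKER_COLUMNS[direction]
        try:
            sub = agg.xs(direction, level="direction").reindex(pids)
        except KeyError:
            sub = pd.DataFrame(index=pids,
                               columns=["n", "mean", "sd"], dtype=float)
        n = sub["n"].fillna(0).astype(int)
        out[f"n_valid_{direction}"] = n
        out[g_col] = sub["mean"]
        cov = sub["sd"] / sub["mean"]
        cov[n < max(min_segments, 2)] = np.nan
        out[cov_col] = cov
        out[f"qc_flags_{direction}"] = [
            {"no_strain"} if k == 0
            else ({"too_few_segments"} if k < min_segments else set())
            for k in n]
    return out.reset_index()


def compute_biomarkers(strain_long: pd.DataFrame, **qc_kwargs) -> pd.DataFrame:
    """Convenience wrapper: QC a raw strain table and return biomarkers."""
    _, biomarkers, _ = apply_qc(strain_long, **qc_kwargs)
    return biomarkers
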