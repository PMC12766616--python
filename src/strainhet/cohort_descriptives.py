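"""Healthy-reference selection, reference ranges, and group descriptives.

A "healthy reference" subset (no prevalent cardiometabolic risk factors
or cardiovascular disease) defines normal ranges as mean ± 2 SD for each
biomarker — globally and segment by segment.  Regional abnormality is
flagged when at least one segment falls outside its segmental range
while the global value stays inside the global range: the signature of
regional dysfunction invisible to global strain.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: prevalent conditions that exclude a participant from the healthy
#: reference cohort
HEALTHY_EXCLUSION_FLAGS = (
    "dyslipidemia", "obesity", "hypertension", "diabetes", "ckd",
    "current_smoker", "cad", "prev_mi", "cerebrovascular", "pvd", "af",
    "aortic_stenosis", "mitral_disease", "acm", "dcm", "hcm", "prev_hf")

EXACT_MW_MAX_N = 12  # exact Mann-Whitney enumeration up to this combined n


@dataclass(frozen=True)
class ReferenceRange:
    """Normal range (mean ± 2 SD) of a metric in the healthy subset."""

    metric: str
    mean: float
    sd: float
    n_healthy: int

    @property
    def lower(self) -> float:
        return self.mean - 2.0 * self.sd

    @property
    def upper(self) -> float:
        return self.mean + 2.0 * self.sd

    def contains(self, value) -> bool:
        return bool(self.lower <= value <= self.upper)


def select_healthy_reference(covariates: pd.DataFrame,
                             exclusion_flags=HEALTHY_EXCLUSION_FLAGS
                             ) -> pd.DataFrame:
    """Participants free of every prevalent risk factor and CVD flag."""
    present = [f for f in exclusion_flags if f in covariates.columns]
    missing = set(exclusion_flags) - set(present)
    if missing:
        raise ValueError(f"covariates missing exclusion flags: {sorted(missing)}")
    mask = ~covariates[present].any(axis=1)
    healthy = covariates[mask]
    if healthy.empty:
        raise ValueError("healthy reference cohort is empty; "
                         "a larger cohort is needed")
    return healthy


def compute_reference_range(values, metric: str = "") -> ReferenceRange:
    """Mean ± 2 SD range from healthy values (sample SD, n−1)."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise ValueError("reference range needs at least 2 healthy values")
    return ReferenceRange(metric=metric, mean=float(v.mean()),
                          sd=float(v.std(ddof=1)), n_healthy=int(v.size))


def flag_regional_abnormality(segment_values, segment_ranges,
                              global_value, global_range: ReferenceRange):
    """True iff ≥1 valid segment is outside its segmental range while the
    global value lies inside the global range.

    ``segment_ranges`` maps segment index -> ReferenceRange (or is a
    sequence aligned with ``segment_values``).  Returns NaN when the
    global value is missing.
    """
    if global_value is None or (isinstance(global_value, float)
                                and math.isnan(global_value)):
        return math.nan
    if not global_range.contains(global_value):
        return False
    vals = np.asarray(segment_values, dtype=float)
    if isinstance(segment_ranges, dict):
        ranges = [segment_ranges[s] for s in sorted(segment_ranges)]
    else:
        ranges = list(segment_ranges)
    for v, r in zip(vals, ranges):
        if np.isfinite(v) and not r.contains(v):
            return True
    return False


def group_compare(values, grouping):
    """Two-sided Mann-Whitney U comparison of a biomarker across 2 groups.

    Exact p by enumeration of all label assignments when the combined
    sample size is ≤ 12 (valid under ties), tie-corrected normal
    approximation with continuity correction otherwise.  Returns
    ``(U, p)`` with U counted for the first group.
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(grouping)
    ok = np.isfinite(v)
    v, g = v[ok], g[ok]
    labels = np.unique(g)
    if len(labels) != 2:
        raise ValueError(f"group_compare needs exactly 2 groups, got {len(labels)}")
    x, y = v[g == labels[0]], v[g == labels[1]]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    u = _u_statistic(x, y)
    n = len(x) + len(y)
    if n <= EXACT_MW_MAX_N:
        p = _exact_mw_p(x, y, u)
    else:
        res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic", use_continuity=True)
        p = float(res.pvalue)
    return float(u), float(p)


def _u_statistic(x, y) -> float:
    """Mann-Whitney U for x via midranks (ties count 1/2)."""
    ranks = stats.rankdata(np.concatenate([x, y]))
    r1 = ranks[:len(x)].sum()
    return r1 - len(x) * (len(x) + 1) / 2.0


def _exact_mw_p(x, y, u_obs: float) -> float:
    """Exact two-sided p: permutation over all label assignments."""
    pooled = np.concatenate([x, y])
    n1, n = len(x), len(pooled)
    mu = len(x) * len(y) / 2.0
    count = total = 0
    for idx in itertools.combinations(range(n), n1):
        rest = [i for i in range(n) if i not in idx]
        u = _u_statistic(pooled[list(idx)], pooled[rest])
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
    return count / total


def correlate(x, y):
    """Spearman rank correlation over pairwise-complete observations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        raise ValueError("correlate needs at least 3 paired values")
    rx, ry = stats.rankdata(x[ok]), stats.rankdata(y[ok])
    if rx.std() == 0 or ry.std() == 0:
        return math.nan
    return float(stats.spearmanr(x[ok], y[ok]).statistic)


def tertile_split(values) -> pd.Series:
    """Tertile labels T1/T2/T3 cut at the 1/3 and 2/3 quantiles.

    Ties at a cut point go to the lower tertile.  Missing values get a
    missing label.  Raises on degenerate (constant) input.
    """
    s = pd.Series(np.asarray(values, dtype=float))
    ok = s.notna()
    if ok.sum() < 3:
        raise ValueError("tertile_split needs at least 3 non-missing values")
    q1, q2 = s[ok].quantile([1 / 3, 2 / 3])
    if q1 == q2:
        raise ValueError("degenerate biomarker spread: tertile cuts coincide")
    code = 1 + (s > q1).astype(int) + (s > q2).astype(int)
    labels = code.map({1: "T1", 2: "T2", 3: "T3"})
    labels[~ok] = np.nan
    return labels


def reference_range_table(biomarkers: pd.DataFrame, healthy_ids,
                          strain_long: pd.DataFrame | None = None,
                          metrics=("gls", "gcs", "grs",
                                   "cov_ls", "cov_cs", "cov_rs")
                          ) -> pd.DataFrame:
    """Reference ranges for global biomarkers and, optionally, for every
    segment of each direction (from the valid cells of ``strain_long``).
    """
    healthy_ids = set(healthy_ids)
    rows = []
    hb = biomarkers[biomarkers["participant_id"].isin(healthy_ids)]
    for m in metrics:
        r = compute_reference_range(hb[m].dropna(), metric=m)
        rows.append({"metric": m, "mean": r.mean, "sd": r.sd,
                     "lower": r.lower, "upper": r.upper,
                     "n_healthy": r.n_healthy})
    if strain_long is not None:
        sl = strain_long
        valid = sl["valid"] if "valid" in sl.columns else sl["value"].notna()
        hsl = sl[valid & sl["participant_id"].isin(healthy_ids)]
        for (d, seg), grp in hsl.groupby(["direction", "segment"]):
            r = compute_reference_range(grp["value"].abs(),
                                        metric=f"{d}_segment_{seg}")
            rows.append({"metric": r.metric, "mean": r.mean, "sd": r.sd,
                         "lower": r.lower, "upper": r.upper,
                         "n_healthy": r.n_healthy})
    return pd.DataFrame(rows)


def regional_abnormality_flags(strain_long: pd.DataFrame,
                               biomarkers: pd.DataFrame,
                               healthy_ids) -> pd.DataFrame:
    """Per-participant regional-abnormality flag for each direction."""
    from .strain_biomarkers import DIRECTIONS, BIOMARKER_COLUMNS

    healthy_ids = set(healthy_ids)
    valid = strain_long["valid"] if "valid" in strain_long.columns \
        else strain_long["value"].notna()
    sl = strain_long[valid].copy()
    sl["absval"] = sl["value"].abs()
    out = pd.DataFrame({"participant_id": biomarkers["participant_id"]})
    for d in DIRECTIONS:
        g_col, _ = BIOMARKER_COLUMNS[d]
        hb = biomarkers[biomarkers["participant_id"].isin(healthy_ids)]
        g_range = compute_reference_range(hb[g_col].dropna(), metric=g_col)
        sub = sl[sl["direction"] == d]
        seg_ranges = {}
        for seg, grp in sub[sub["participant_id"].isin(healthy_ids)].groupby(
                "segment"):
            seg_ranges[seg] = compute_reference_range(
                grp["absval"], metric=f"{d}_segment_{seg}")
        # vectorized: outside-own-range per cell, any per participant
        lo = sub["segment"].map({s: r.lower for s, r in seg_ranges.items()})
        hi = sub["segment"].map({s: r.upper for s, r in seg_ranges.items()})
        outside = (sub["absval"] < lo) | (sub["absval"] > hi)
        any_outside = outside.groupby(sub["participant_id"]).any()
        flags = []
        for pid, g in zip(biomarkers["participant_id"], biomarkers[g_col]):
            if pd.isna(g):
                flags.append(math.nan)
            elif not g_range.contains(g):
                flags.append(False)
            else:
                flags.append(bool(any_outside.get(pid, False)))
        out[f"regional_abnormal_{d}"] = flags
    return out


def descriptive_table(biomarkers: pd.DataFrame, grouping: pd.Series,
                      metrics=("gls", "gcs", "grs",
                               "cov_ls", "cov_cs", "cov_rs")) -> pd.DataFrame:
    """Median (Q1, Q3) per group with Mann-Whitney p per metric."""
    rows = []
    for m in metrics:
        v = biomarkers[m]
        ok = v.notna() & grouping.notna()
        u, p = group_compare(v[ok], grouping[ok])
        for lab, grp in v[ok].groupby(grouping[ok]):
            q1, med, q3 = grp.quantile([0.25, 0.5, 0.75])
            rows.append({"metric": m, "group": lab, "median": med,
                         "q1": q1, "q3": q3, "n": len(grp), "U": u, "p": p})
    return pd.DataFrame(rows)
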