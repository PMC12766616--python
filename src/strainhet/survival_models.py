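"""Nested Cox models and the model-comparison battery.

Cox proportional-hazards models are built in three nested tiers around a
focal strain biomarker (a strain CoV or a global strain, z-scored):

* Model 1 — the biomarker alone;
* Model 2 — plus clinical risk factors (age, sex, ethnicity, smoking,
  BMI, dyslipidemia, hypertension, diabetes);
* Model 3 — plus CMR volumetrics (LVMi, LVEDVi, LVEF) and the
  reciprocal strain marker (the global strain paired with a CoV and
  vice versa), optionally plus a regional-abnormality flag.

Added value of the focal biomarker is quantified by Uno's IPCW C-index
(with a bootstrap comparison of nested models), the continuous net
reclassification improvement NRI(>0), the IPCW Brier score at a 5-year
horizon, the likelihood-ratio test and the AIC, with Bonferroni
correction (factor 15) for the principal comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.statistics import proportional_hazard_test
from scipy import stats

BONFERRONI_M = 15  # principal biomarker-endpoint comparisons

TIER2_COVARIATES = ("age", "male", "ethnicity_white", "current_smoker",
                    "bmi", "dyslipidemia", "hypertension", "diabetes")
TIER3_EXTRA = ("lvmi", "lvedvi", "lvef")

RECIPROCAL_MARKER = {"cov_ls": "gls", "cov_cs": "gcs", "cov_rs": "grs",
                     "gls": "cov_ls", "gcs": "cov_cs", "grs": "cov_rs"}

STRAIN_MARKERS = tuple(RECIPROCAL_MARKER)


@dataclass(frozen=True)
class ModelSpec:
    """One Cox model: endpoint, focal strain biomarker, and tier."""

    endpoint: str
    biomarker: str
    tier: int = 3
    adjust_regional: bool = False
    include_focal: bool = True   # False gives the matching reduced model

    def __post_init__(self):
        if self.biomarker not in RECIPROCAL_MARKER:
            raise ValueError(f"unknown biomarker: {self.biomarker!r}")
        if self.tier not in (1, 2, 3):
            raise ValueError(f"tier must be 1, 2 or 3, got {self.tier}")

    def covariates(self) -> list[str]:
        cols = [f"{self.biomarker}_z"] if self.include_focal else []
        if self.tier >= 2:
            cols += list(TIER2_COVARIATES)
        if self.tier >= 3:
            cols += list(TIER3_EXTRA)
            cols.append(f"{RECIPROCAL_MARKER[self.biomarker]}_z")
        if self.adjust_regional:
            direction = {"ls": "longitudinal", "cs": "circumferential",
                         "rs": "radial"}[self.biomarker.split("_")[-1][-2:]]
            cols.append(f"regional_abnormal_{direction}")
        return cols

    def reduced(self) -> "ModelSpec":
        """Same adjustment set without the focal biomarker."""
        return ModelSpec(self.endpoint, self.biomarker, self.tier,
                         self.adjust_regional, include_focal=False)


@dataclass
class CoxFitResult:
    """A fitted Cox model plus everything needed for model comparison."""

    spec: ModelSpec
    summary: pd.DataFrame          # coef, HR, CI, p, p_bonferroni per term
    log_likelihood: float
    aic: float
    n: int
    n_events: int
    model: CoxPHFitter
    design: pd.DataFrame           # rows actually fitted (incl. time/event)
    duration_col: str
    event_col: str
    focal: str | None
    metrics: dict = field(default_factory=dict)

    @property
    def focal_hr(self) -> float:
        return float(self.summary.loc[self.focal, "hr"]) if self.focal else math.nan

    @property
    def focal_ci(self) -> tuple[float, float]:
        if not self.focal:
            return (math.nan, math.nan)
        row = self.summary.loc[self.focal]
        return float(row["hr_lower_95"]), float(row["hr_upper_95"])

    def risk_score(self, frame: pd.DataFrame | None = None) -> np.ndarray:
        """Linear predictor (log partial hazard) on the fitted rows."""
        X = (frame if frame is not None else self.design)
        return self.model.predict_log_partial_hazard(X).to_numpy()

    def predicted_risk(self, horizon: float,
                       frame: pd.DataFrame | None = None) -> np.ndarray:
        """Predicted event probability by ``horizon`` years."""
        X = frame if frame is not None else self.design
        surv = self.model.predict_survival_function(X, times=[horizon])
        return 1.0 - surv.iloc[0].to_numpy()


def bonferroni_adjust(p, m: int = BONFERRONI_M):
    """min(1, m·p); significance at raw p < 0.05/m (0.0033 for m = 15)."""
    p_arr = np.asarray(p, dtype=float)
    if np.any((p_arr < 0) | (p_arr > 1) | ~np.isfinite(p_arr)):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.minimum(1.0, m * p_arr)
    return float(out) if np.isscalar(p) else out


def build_modeling_frame(covariates: pd.DataFrame, biomarkers: pd.DataFrame,
                         outcomes: pd.DataFrame,
                         regional_flags: pd.DataFrame | None = None
                         ) -> pd.DataFrame:
    """Join covariates, biomarkers and per-endpoint outcome columns.

    Outcome columns become ``time_<endpoint>``, ``event_<endpoint>``,
    ``prevalent_<endpoint>``.
    """
    frame = covariates.merge(biomarkers, on="participant_id", how="inner")
    if regional_flags is not None:
        frame = frame.merge(regional_flags, on="participant_id", how="left")
    for ep, grp in outcomes.groupby("endpoint"):
        grp = grp.set_index("participant_id")
        frame[f"time_{ep}"] = frame["participant_id"].map(grp["time"])
        frame[f"event_{ep}"] = frame["participant_id"].map(grp["event"])
        frame[f"prevalent_{ep}"] = frame["participant_id"].map(grp["prevalent"])
    return frame


def _prepare_rows(spec: ModelSpec, data: pd.DataFrame) -> pd.DataFrame:
    """Prevalent-exclusion, complete-case filtering, and strain z-scoring."""
    dur, ev = f"time_{spec.endpoint}", f"event_{spec.endpoint}"
    prev = f"prevalent_{spec.endpoint}"
    if dur not in data.columns or ev not in data.columns:
        raise ValueError(f"data lacks outcome columns for {spec.endpoint!r}")
    df = data.copy()
    if prev in df.columns:
        df = df[~df[prev].fillna(False).astype(bool)]
    raw_needed = {c[:-2] if c.endswith("_z") else c
                  for c in set(spec.covariates()) | set(spec.reduced().covariates())}
    df = df.dropna(subset=[dur, ev, *sorted(raw_needed)])
    if df.empty:
        raise ValueError("no complete-case rows for model")
    for marker in STRAIN_MARKERS:
        if marker in df.columns:
            sd = df[marker].std(ddof=1)
            if sd > 0:
                df[f"{marker}_z"] = (df[marker] - df[marker].mean()) / sd
    df[ev] = df[ev].astype(bool)
    return df


def fit_cox(spec: ModelSpec, data: pd.DataFrame,
            ties: str = "efron", rows: pd.DataFrame | None = None
            ) -> CoxFitResult:
    """Fit one Cox model by Efron-tied partial likelihood maximization.

    Participants with the endpoint prevalent at baseline are excluded
    and covariates are complete-case; strain biomarkers are z-scored on
    the analysis rows.  Pass ``rows`` to reuse a pre-filtered frame
    (e.g. to fit nested models on identical rows).
    """
    dur, ev = f"time_{spec.endpoint}", f"event_{spec.endpoint}"
    df = rows if rows is not None else _prepare_rows(spec, data)
    cols = spec.covariates()
    fit_df = df[[dur, ev, *cols]].astype(float)
    if fit_df[ev].sum() == 0:
        raise ValueError("zero events: model not estimable")
    cph = CoxPHFitter()
    try:
        cph.fit(fit_df, duration_col=dur, event_col=ev,
                fit_options={"precision": 1e-9, "max_steps": 100})
    except Exception as err:  # convergence / singularity
        raise RuntimeError(f"Cox fit failed for {spec}: {err}") from err
    summ = cph.summary.rename(columns={
        "exp(coef)": "hr", "exp(coef) lower 95%": "hr_lower_95",
        "exp(coef) upper 95%": "hr_upper_95", "p": "p_raw"})
    summ = summ[["coef", "se(coef)", "hr", "hr_lower_95", "hr_upper_95",
                 "p_raw"]]
    summ["p_bonferroni"] = np.minimum(1.0, BONFERRONI_M * summ["p_raw"])
    ll = float(cph.log_likelihood_)
    return CoxFitResult(
        spec=spec, summary=summ, log_likelihood=ll,
        aic=-2.0 * ll + 2.0 * len(cols),
        n=len(fit_df), n_events=int(fit_df[ev].sum()), model=cph,
        design=df, duration_col=dur, event_col=ev,
        focal=f"{spec.biomarker}_z" if spec.include_focal else None)


def check_diagnostics(fit: CoxFitResult, vif_threshold: float = 5.0) -> dict:
    """Schoenfeld proportional-hazards test and VIF per covariate.

    Scaled Schoenfeld residuals are tested for correlation with (rank)
    time; VIFs come from auxiliary OLS regressions on the design matrix.
    ``pass`` requires all VIF below 5.
    """
    cols = list(fit.summary.index)
    ph = proportional_hazard_test(fit.model,
                                  fit.design[[fit.duration_col,
                                              fit.event_col, *cols]],
                                  time_transform="rank")
    schoenfeld_p = {c: float(ph.summary.loc[(c, "rank"), "p"])
                    if (c, "rank") in ph.summary.index
                    else float(ph.summary.loc[c, "p"]) for c in cols}
    vif = variance_inflation_factors(fit.design[cols])
    return {"schoenfeld_p": schoenfeld_p, "vif": vif,
            "pass": all(v < vif_threshold for v in vif.values())}


def variance_inflation_factors(design: pd.DataFrame) -> dict[str, float]:
    """VIF per column from auxiliary OLS regressions (with intercept)."""
    cols = list(design.columns)
    X = design.to_numpy(dtype=float)
    vif = {}
    for i, c in enumerate(cols):
        if len(cols) == 1:
            vif[c] = 1.0
            continue
        others = np.column_stack([np.ones(len(X)), np.delete(X, i, axis=1)])
        beta, *_ = np.linalg.lstsq(others, X[:, i], rcond=None)
        resid = X[:, i] - others @ beta
        tss = ((X[:, i] - X[:, i].mean()) ** 2).sum()
        rss = (resid ** 2).sum()
        r2 = 1.0 - rss / tss if tss > 0 else 0.0
        vif[c] = math.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return vif


# ---------------------------------------------------------------------------
# IPCW machinery


def censoring_survival(times, events):
    """Kaplan-Meier estimate of the censoring survival G(t).

    Returns a callable evaluating the left-continuous G(t-) by default
    (``left=True``) or the right-continuous G(t).
    """
    t = np.asarray(times, dtype=float)
    d = ~np.asarray(events, dtype=bool)      # censoring is the "event"
    order = np.argsort(t, kind="stable")
    t_sorted, d_sorted = t[order], d[order]
    uniq, idx = np.unique(t_sorted, return_index=True)
    n = len(t)
    at_risk = n - idx
    n_cens = np.add.reduceat(d_sorted.astype(int), idx)
    factors = 1.0 - n_cens / at_risk
    surv = np.cumprod(factors)

    def g(query, left=True):
        q = np.asarray(query, dtype=float)
        side = "left" if left else "right"
        pos = np.searchsorted(uniq, q, side=side) - 1
        out = np.where(pos < 0, 1.0, surv[np.clip(pos, 0, len(surv) - 1)])
        return out if q.shape else float(out)

    return g


def uno_c_index(risk, times, events, tau=None) -> float:
    """Uno's IPCW concordance index truncated at ``tau``.

    Comparable pairs (i, j): i has an event at t_i < min(t_j, tau); the
    pair is weighted by G(t_i-)^-2 where G is the Kaplan-Meier censoring
    survival.  Tied risk scores count one half.  With no censoring this
    reduces exactly to Harrell's C.
    """
    r = np.asarray(risk, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if tau is None:
        tau = np.quantile(t, 0.95)
    g = censoring_survival(t, e)
    w = np.where(e & (t < tau), 1.0 / g(t, left=True) ** 2, 0.0)
    num = den = 0.0
    idx = np.flatnonzero(w > 0)
    for start in range(0, len(idx), 256):
        block = idx[start:start + 256]
        later = t[None, :] > t[block, None]          # t_i < t_j
        n_pairs = later.sum(axis=1)
        conc = (later & (r[None, :] < r[block, None])).sum(axis=1)
        ties = (later & (r[None, :] == r[block, None])).sum(axis=1)
        num += float((w[block] * (conc + 0.5 * ties)).sum())
        den += float((w[block] * n_pairs).sum())
    if den == 0:
        raise ValueError("no comparable pairs for the concordance index")
    return num / den


def brier_score(predicted_risk, times, events, horizon: float = 5.0) -> float:
    """IPCW Brier score at ``horizon``: mean squared error between the
    predicted event probability and the observed status, with censored-
    before-horizon subjects reweighted away."""
    pi = np.asarray(predicted_risk, dtype=float)
    if np.any((pi < 0) | (pi > 1)):
        raise ValueError("predicted risks must lie in [0, 1]")
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    g = censoring_survival(t, e)
    g_h = g(horizon, left=False)
    if g_h <= 0:
        raise ValueError("censoring survival is 0 at the horizon")
    had_event = (t <= horizon) & e
    event_free = t > horizon
    w_event = np.where(had_event, 1.0 / g(t, left=True), 0.0)
    contrib = (w_event * (pi - 1.0) ** 2
               + event_free / g_h * (pi - 0.0) ** 2)
    return float(contrib.mean())


def continuous_nri(risk_old, risk_new, times, events,
                   horizon: float = 5.0, n_boot: int = 0,
                   seed: int | None = None):
    """Continuous NRI(>0) in percent, censoring-adjusted by IPCW.

    NRI = [P(up|event) − P(down|event)] + [P(down|non-event) −
    P(up|non-event)] where "up" means the new model assigns a higher
    risk.  Event status is taken at ``horizon``; subjects censored
    earlier get zero weight and the rest are IPCW-reweighted.  Returns
    ``(nri_percent, (lo, hi))`` with a percentile bootstrap interval
    when ``n_boot > 0``.
    """
    ro = np.asarray(risk_old, dtype=float)
    rn = np.asarray(risk_new, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)

    def _nri(ro, rn, t, e):
        g = censoring_survival(t, e)
        is_event = (t <= horizon) & e
        is_nonevent = t > horizon
        w_e = np.where(is_event, 1.0 / g(t, left=True), 0.0)
        w_ne = np.where(is_nonevent, 1.0 / g(horizon, left=False), 0.0)
        if w_e.sum() == 0:
            raise ValueError("no events by the horizon")
        up, down = rn > ro, rn < ro
        p_up_e = (w_e * up).sum() / w_e.sum()
        p_down_e = (w_e * down).sum() / w_e.sum()
        if w_ne.sum() == 0:
            p_up_ne = p_down_ne = 0.0
        else:
            p_up_ne = (w_ne * up).sum() / w_ne.sum()
            p_down_ne = (w_ne * down).sum() / w_ne.sum()
        return 100.0 * ((p_up_e - p_down_e) + (p_down_ne - p_up_ne))

    point = _nri(ro, rn, t, e)
    if n_boot <= 0:
        return point, (math.nan, math.nan)
    rng = np.random.default_rng(seed)
    reps = []
    for _ in range(n_boot):
        b = rng.integers(0, len(t), len(t))
        try:
            reps.append(_nri(ro[b], rn[b], t[b], e[b]))
        except ValueError:
            continue
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return point, (float(lo), float(hi))


def compare_c_index(spec_full: ModelSpec, spec_reduced: ModelSpec,
                    data: pd.DataFrame, B: int = 200,
                    seed: int | None = None, tau=None,
                    method: str = "unpaired_t") -> dict:
    """ΔC between nested models with a bootstrap p-value.

    Both models are fit on identical rows; ΔC = C_full − C_reduced on
    the full data.  ``B`` participant-level bootstrap resamples refit
    both models, and the two bootstrap C distributions are compared by
    an unpaired t test (the conventional recipe; ``method="paired"``
    uses the percentile distribution of the paired ΔC instead).
    Resamples whose refit fails are dropped and counted.
    """
    import warnings
    if B < 50:
        warnings.warn("B < 50 bootstrap resamples is unreliable")
    rows = _prepare_rows(spec_full, data)
    fit_f = fit_cox(spec_full, data, rows=rows)
    fit_r = fit_cox(spec_reduced, data, rows=rows)
    dur, ev = fit_f.duration_col, fit_f.event_col
    t = rows[dur].to_numpy(dtype=float)
    e = rows[ev].to_numpy(dtype=bool)
    if tau is None:
        tau = float(np.quantile(t, 0.95))
    c_f = uno_c_index(fit_f.risk_score(rows), t, e, tau)
    c_r = uno_c_index(fit_r.risk_score(rows), t, e, tau)
    rng = np.random.default_rng(seed)
    boots_f, boots_r, n_failed = [], [], 0
    for _ in range(B):
        b = rng.integers(0, len(rows), len(rows))
        rb = rows.iloc[b].reset_index(drop=True)
        tb, eb = t[b], e[b]
        try:
            bf = fit_cox(spec_full, data, rows=rb)
            br = fit_cox(spec_reduced, data, rows=rb)
            boots_f.append(uno_c_index(bf.risk_score(rb), tb, eb, tau))
            boots_r.append(uno_c_index(br.risk_score(rb), tb, eb, tau))
        except (RuntimeError, ValueError):
            n_failed += 1
    boots_f, boots_r = np.asarray(boots_f), np.asarray(boots_r)
    if method == "paired":
        delta = boots_f - boots_r
        centered = np.abs(delta - delta.mean())
        p = float(np.mean(centered >= abs(delta.mean()) + abs(c_f - c_r)))
    else:
        if np.allclose(boots_f, boots_r):
            p = 1.0
        else:
            p = float(stats.ttest_ind(boots_f, boots_r).pvalue)
    return {"c_full": c_f, "c_reduced": c_r, "delta_c": c_f - c_r,
            "p": p, "tau": tau, "B": B, "n_failed": n_failed,
            "seed": seed, "method": method}


def lrt_and_aic(fit_full: CoxFitResult, fit_reduced: CoxFitResult) -> dict:
    """Likelihood-ratio test and ΔAIC between nested Cox fits."""
    full_cols = set(fit_full.summary.index)
    red_cols = set(fit_reduced.summary.index)
    if not red_cols <= full_cols:
        raise ValueError("models are not nested")
    if fit_full.n != fit_reduced.n:
        raise ValueError("nested models must be fit on identical rows")
    df = len(full_cols) - len(red_cols)
    chi2 = 2.0 * (fit_full.log_likelihood - fit_reduced.log_likelihood)
    p = float(stats.chi2.sf(max(chi2, 0.0), df)) if df > 0 else 1.0
    return {"chi2": chi2, "df": df, "p": p,
            "delta_aic": fit_full.aic - fit_reduced.aic}


def model_comparison(spec: ModelSpec, data: pd.DataFrame, B: int = 200,
                     seed: int | None = None, horizon: float = 5.0,
                     tau=None) -> dict:
    """Full added-value battery for one focal biomarker and endpoint.

    Fits the spec and its focal-free reduction on identical rows and
    reports HR/CI/p (Bonferroni-adjusted), ΔC with bootstrap p, NRI(>0),
    Brier change at the horizon, LRT and ΔAIC.
    """
    rows = _prepare_rows(spec, data)
    fit_f = fit_cox(spec, data, rows=rows)
    fit_r = fit_cox(spec.reduced(), data, rows=rows)
    t = rows[fit_f.duration_col].to_numpy(dtype=float)
    e = rows[fit_f.event_col].to_numpy(dtype=bool)
    cmp_c = compare_c_index(spec, spec.reduced(), data, B=B, seed=seed,
                            tau=tau)
    risk_f = fit_f.predicted_risk(horizon, rows)
    risk_r = fit_r.predicted_risk(horizon, rows)
    nri, nri_ci = continuous_nri(risk_r, risk_f, t, e, horizon=horizon,
                                 n_boot=min(B, 200), seed=seed)
    brier_f = brier_score(risk_f, t, e, horizon)
    brier_r = brier_score(risk_r, t, e, horizon)
    lrt = lrt_and_aic(fit_f, fit_r)
    return {
        "endpoint": spec.endpoint, "biomarker": spec.biomarker,
        "tier": spec.tier, "n": fit_f.n, "n_events": fit_f.n_events,
        "hr": fit_f.focal_hr, "ci": fit_f.focal_ci,
        "p_raw": float(fit_f.summary.loc[fit_f.focal, "p_raw"]),
        "p_bonferroni": float(fit_f.summary.loc[fit_f.focal, "p_bonferroni"]),
        "c_index": cmp_c["c_full"], "delta_c": cmp_c["delta_c"],
        "delta_c_p": cmp_c["p"], "nri_percent": nri, "nri_ci": nri_ci,
        "delta_brier": brier_f - brier_r, "delta_aic": lrt["delta_aic"],
        "lrt_chi2": lrt["chi2"], "lrt_p": lrt["p"], "tau": cmp_c["tau"],
        "B": B, "seed": seed,
        "fit_full": fit_f, "fit_reduced": fit_r}


# ---------------------------------------------------------------------------
# Subgroups


def hfpef_risk_mask(frame: pd.DataFrame) -> pd.Series:
    """Preserved LVEF (≥50%) with ≥3 of: age>65, obesity, hypertension,
    diabetes, CKD, AF — the at-risk-of-HFpEF rule."""
    criteria = ((frame["age"] > 65).astype(int)
                + frame["obesity"].astype(int)
                + frame["hypertension"].astype(int)
                + frame["diabetes"].astype(int)
                + frame["ckd"].astype(int)
                + frame["af"].astype(int))
    return (frame["lvef"] >= 50.0) & (criteria >= 3)


def default_subgroups(frame: pd.DataFrame) -> dict[str, pd.Series]:
    return {
        "age_gt_65": frame["age"] > 65,
        "age_le_65": frame["age"] <= 65,
        "male": frame["male"].astype(bool),
        "female": ~frame["male"].astype(bool),
        "prevalent_ckd": frame["ckd"].astype(bool),
        "prevalent_mi": frame["prev_mi"].astype(bool),
        "prevalent_af": frame["af"].astype(bool),
        "hfpef_risk": hfpef_risk_mask(frame),
    }


def subgroup_analysis(data: pd.DataFrame, spec: ModelSpec,
                      subgroups: dict[str, pd.Series] | None = None
                      ) -> dict[str, CoxFitResult | dict]:
    """Refit a (tier-3) spec within each subgroup.

    Subgroups with zero events or failed fits are reported as
    not-estimable rather than raising.
    """
    if subgroups is None:
        subgroups = default_subgroups(data)
    results: dict[str, CoxFitResult | dict] = {}
    for name, mask in subgroups.items():
        sub = data[mask.reindex(data.index).fillna(False).astype(bool)]
        try:
            results[name] = fit_cox(spec, sub)
        except (ValueError, RuntimeError) as err:
            results[name] = {"not_estimable": True, "reason": str(err),
                             "n": len(sub)}
    return results
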