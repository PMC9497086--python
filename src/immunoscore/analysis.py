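"""Cohort-level analyses: bivariable (Table-1-style) sweeps, the
center-stratified multivariable model, subgroup analyses, the age
association screen, and two-cohort covariate comparison.

Conventions mirrored from the study design:

* All Cox models are stratified by participating center (a flag exposes
  unstratified unadjusted fits).
* Missingness is handled complete-case **per variable**, never listwise, so
  each variable row carries its own denominator.
* Landmark rates are Kaplan–Meier survival percentages at 36 and 60 months.
* In the five-category scheme the hazard-ratio reference is I3 and the RMST
  reference is I4; categories without events are reported as an infinite
  hazard ratio with an undefined p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import survival as sv
from .endpoints import risk_group_column
from .scoring import CHANNELS
from .survival import TestResult

__all__ = [
    "AnalysisConfig",
    "BivariableRow",
    "bivariable_table",
    "multivariable_model",
    "subgroup_analysis",
    "age_association",
    "compare_cohorts",
    "km_curves_table",
]

log = logging.getLogger("immunoscore")

AGE_EDGES = (0.0, 60.0, 70.0, 85.0, np.inf)
AGE_LABELS = ("<60", ">=60-70", ">=70-85", ">=85")

LANDMARKS = (36.0, 60.0)


@dataclass
class AnalysisConfig:
    endpoint: str = "TTR"
    scheme: str = "three"
    subgroup: str = "none"
    landmarks: tuple = LANDMARKS
    seed: int = 0
    stratify_unadjusted: bool = True


@dataclass
class BivariableRow:
    variable: str
    level: str
    n: int
    percent: float
    rate_36: float
    rate_36_ci: tuple
    rate_60: float
    rate_60_ci: tuple
    hr: float
    hr_ci: tuple
    hr_p: float
    is_reference: bool
    c_index: float
    c_index_ci: tuple
    rmst_diff: float
    rmst_ci: tuple
    rmst_p: float
    is_rmst_reference: bool = False

    def as_dict(self) -> dict:
        d = dict(self.__dict__)
        for key in ("rate_36_ci", "rate_60_ci", "hr_ci", "c_index_ci", "rmst_ci"):
            lo, hi = d.pop(key)
            d[f"{key}_lo"], d[f"{key}_hi"] = lo, hi
        return d


def age_bin(age: float) -> str:
    """Age group with left-closed, right-open bins (<60, >=60-70, ...)."""
    idx = np.searchsorted(AGE_EDGES, age, side="right") - 1
    return AGE_LABELS[min(idx, len(AGE_LABELS) - 1)]


def _yes_no(x) -> str:
    return "YES" if bool(x) else "NO"


def _combined_is_risk(df: pd.DataFrame) -> pd.Series:
    # the combined row pairs two-category Immunoscore with the strictest
    # risk definition: high risk = T4 and VELIPI+, low risk = all others
    high = (df["t_stage"] == "T4") & df["velipi"].astype(bool)
    return pd.Series(
        np.where(df["is2"] == "Lo",
                 np.where(high, "Lo / High Risk", "Lo / Low Risk"),
                 np.where(high, "Int+Hi / High Risk", "Int+Hi / Low Risk")),
        index=df.index,
    )


def _variable_plan() -> list[dict]:
    def col(name):
        return lambda df: df[name].where(df[name].notna() & (df[name] != ""))

    def yn(name):
        return lambda df: df[name].map(_yes_no)

    return [
        dict(name="age_group", levels=list(AGE_LABELS), ref="<60",
             build=lambda df: df["age_years"].map(age_bin)),
        dict(name="gender", levels=["Male", "Female"], ref="Male", build=col("gender")),
        dict(name="t_stage", levels=["T1", "T2", "T3", "T4"], ref="T1", build=col("t_stage")),
        dict(name="n_stage", levels=["N0", "N1", "N2"], ref="N0", build=col("n_stage")),
        dict(name="tnm_stage", levels=["I", "II", "III"], ref="I", build=col("tnm_stage")),
        dict(name="differentiation", levels=["Well", "Moderate", "Poor-undiff"],
             ref="Well", build=col("differentiation")),
        dict(name="sidedness", levels=["Proximal", "Distal"], ref="Proximal",
             build=col("sidedness")),
        dict(name="velipi", levels=["NO", "YES"], ref="NO", build=yn("velipi")),
        dict(name="mucinous", levels=["NO", "YES"], ref="NO", build=yn("mucinous")),
        dict(name="msi_status", levels=["MSS", "MSI-H"], ref="MSS", build=col("msi_status")),
        dict(name="chemo", levels=["NO", "YES"], ref="NO", build=yn("chemo")),
        dict(name="immunoscore_2cat", levels=["Lo", "Int+Hi"], ref="Int+Hi",
             build=col("is2")),
        dict(name="immunoscore_3cat", levels=["Lo", "Int", "Hi"], ref="Hi",
             build=col("is3")),
        dict(name="immunoscore_5cat", levels=["I0", "I1", "I2", "I3", "I4"],
             ref="I3", rmst_ref="I4", build=col("is5")),
        dict(name="immunoscore_2cat_x_risk",
             levels=["Lo / High Risk", "Lo / Low Risk",
                     "Int+Hi / High Risk", "Int+Hi / Low Risk"],
             ref="Int+Hi / Low Risk", build=_combined_is_risk),
    ]


def merge_scored(cohort: pd.DataFrame, scores: pd.DataFrame,
                 endpoints_df: pd.DataFrame, endpoint: str) -> pd.DataFrame:
    """Scored, QC-passed patients with their chosen endpoint attached."""
    if endpoint not in ("TTR", "OS", "DFS"):
        raise ValueError(f"unknown endpoint: {endpoint!r}")
    ep = endpoints_df[endpoints_df["endpoint"] == endpoint][
        ["patient_id", "time_months", "event"]]
    df = cohort.merge(scores, on="patient_id", how="inner")
    df = df.merge(ep, on="patient_id", how="inner")
    return df.reset_index(drop=True)


def _stratified_factor_fit(df, level_col, levels, ref, stratify):
    """Unadjusted Cox fit of one factor (dummy per non-reference level)."""
    design = {f"{lv}": (df[level_col] == lv).to_numpy(float)
              for lv in levels if lv != ref and (df[level_col] == lv).any()}
    strata = df["center"].to_numpy() if stratify else None
    fit = sv.cox_fit(design, df["time_months"].to_numpy(),
                     df["event"].to_numpy(bool), strata=strata)
    return fit


def bivariable_table(cohort, scores, endpoints_df, config: AnalysisConfig) -> pd.DataFrame:
    """Per-variable, per-level survival summary over the Table-1 variable
    list: n (%), 36/60-month KM rates, unadjusted (center-stratified) hazard
    ratios versus the reference level, variable-level concordance, and RMST
    differences versus the RMST reference.
    """
    base = merge_scored(cohort, scores, endpoints_df, config.endpoint)
    rows: list[BivariableRow] = []
    for plan in _variable_plan():
        name, levels, ref = plan["name"], plan["levels"], plan["ref"]
        rmst_ref = plan.get("rmst_ref", ref)
        try:
            labels = plan["build"](base)
        except KeyError:
            log.warning("bivariable table: variable %s absent from cohort, skipped", name)
            continue
        mask = labels.notna()
        df = base[mask].assign(_level=labels[mask])
        present = [lv for lv in levels if (df["_level"] == lv).any()]
        if len(present) < 2 or not df["event"].any():
            log.warning("bivariable table: variable %s has <2 informative levels, skipped",
                        name)
            continue
        total = len(df)
        fit = _stratified_factor_fit(df, "_level", present, ref,
                                     config.stratify_unadjusted)
        # variable-level concordance from the single-variable linear predictor
        beta = np.array([fit.coefficients.get(lv, 0.0) for lv in present])
        lp = beta[pd.Categorical(df["_level"], categories=present).codes]
        try:
            conc = sv.harrell_c(lp, df["time_months"], df["event"], seed=config.seed)
            c_index, c_ci = conc.c_index, conc.ci_95
        except ValueError:
            c_index, c_ci = float("nan"), (float("nan"), float("nan"))

        ref_grp = df[df["_level"] == rmst_ref]
        for lv in present:
            grp = df[df["_level"] == lv]
            curve = sv.km_estimate(grp["time_months"], grp["event"])
            r36 = sv.rate_at(curve, config.landmarks[0])
            r60 = sv.rate_at(curve, config.landmarks[1])
            if lv == ref:
                hr, hr_ci, hr_p = 1.0, (1.0, 1.0), float("nan")
            else:
                w = sv.wald_summary(fit, lv)
                hr, hr_ci, hr_p = w["hr"], w["ci_95"], w["p_value"]
            if lv == rmst_ref or len(ref_grp) == 0:
                rdiff, rci, rp = 0.0, (0.0, 0.0), float("nan")
            else:
                tau = min(grp["time_months"].max(), ref_grp["time_months"].max())
                res = sv.rmst_compare((grp["time_months"], grp["event"]),
                                      (ref_grp["time_months"], ref_grp["event"]), tau)
                rdiff, rci, rp = res.difference, res.ci_95, res.p_value
            rows.append(BivariableRow(
                variable=name, level=lv, n=len(grp),
                percent=100.0 * len(grp) / total,
                rate_36=r36["rate"], rate_36_ci=r36["ci_95"],
                rate_60=r60["rate"], rate_60_ci=r60["ci_95"],
                hr=hr, hr_ci=hr_ci, hr_p=hr_p, is_reference=lv == ref,
                c_index=c_index, c_index_ci=c_ci,
                rmst_diff=rdiff, rmst_ci=rci, rmst_p=rp,
                is_rmst_reference=lv == rmst_ref,
            ))
    return pd.DataFrame([r.as_dict() for r in rows])


MULTIVARIABLE_BLOCKS = {
    "immunoscore": ["is_lo"],
    "age": ["age"],
    "gender": ["female"],
    "t_stage": ["t3", "t4"],
    "n_stage": ["n1", "n2"],
    "sidedness": ["distal"],
    "msi": ["msi_h"],
}


def multivariable_model(cohort, scores, endpoints_df, config: AnalysisConfig) -> dict:
    """Center-stratified multivariable Cox model of the chosen endpoint.

    Covariates: two-category Immunoscore, age (per year), gender, T-stage
    (T3/T4 vs T1–2), N-stage (N1/N2 vs N0), sidedness, and MSI; complete
    cases on all seven.  Returns the fit, per-term Wald summaries,
    chi-square importance proportions, and the likelihood-ratio test of the
    clinical-only model against clinical + Immunoscore.
    """
    df = merge_scored(cohort, scores, endpoints_df, config.endpoint)
    df = df[(df["msi_status"].notna()) & (df["msi_status"] != "")]
    df = df.dropna(subset=["age_years", "gender", "t_stage", "n_stage", "sidedness", "is2"])
    df = df.reset_index(drop=True)

    # strata without events carry no partial-likelihood information
    ev_by_center = df.groupby("center")["event"].sum()
    dead_strata = ev_by_center[ev_by_center == 0].index.tolist()
    if dead_strata:
        log.warning("multivariable model: dropping event-free strata %s", dead_strata)
        df = df[~df["center"].isin(dead_strata)].reset_index(drop=True)

    design = {
        "is_lo": (df["is2"] == "Lo").to_numpy(float),
        "age": df["age_years"].to_numpy(float),
        "female": (df["gender"] == "Female").to_numpy(float),
        "t3": (df["t_stage"] == "T3").to_numpy(float),
        "t4": (df["t_stage"] == "T4").to_numpy(float),
        "n1": (df["n_stage"] == "N1").to_numpy(float),
        "n2": (df["n_stage"] == "N2").to_numpy(float),
        "distal": (df["sidedness"] == "Distal").to_numpy(float),
        "msi_h": (df["msi_status"] == "MSI-H").to_numpy(float),
    }
    t = df["time_months"].to_numpy()
    e = df["event"].to_numpy(bool)
    strata = df["center"].to_numpy()
    full = sv.cox_fit(design, t, e, strata=strata)
    clinical = sv.cox_fit({k: v for k, v in design.items() if k != "is_lo"},
                          t, e, strata=strata)
    lrt = sv.likelihood_ratio_test(clinical, full)
    wald = {term: sv.wald_summary(full, term) for term in full.term_names}
    importance = None
    if full.converged:
        blocks = {v: terms for v, terms in MULTIVARIABLE_BLOCKS.items()
                  if all(t_ in full.term_names for t_ in terms)}
        importance = sv.chi2_importance(full, blocks)
    return {"fit": full, "clinical_fit": clinical, "wald": wald,
            "importance": importance, "lrt": lrt, "n": len(df),
            "n_events": int(e.sum())}


SUBGROUP_FILTERS = ("none", "mss", "stage2", "stage2_low_risk",
                    "stage2_high_risk", "stage2_very_high_risk")


def _subgroup_mask(cohort: pd.DataFrame, subgroup: str) -> pd.Series:
    if subgroup == "none":
        return pd.Series(True, index=cohort.index)
    if subgroup == "mss":
        return cohort["msi_status"] == "MSS"
    if subgroup.startswith("stage2"):
        mask = cohort["tnm_stage"] == "II"
        if subgroup == "stage2":
            return mask
        risk = risk_group_column(cohort)
        wanted = subgroup.removeprefix("stage2_").removesuffix("_risk")
        return mask & (risk == wanted)
    raise ValueError(f"unknown subgroup filter: {subgroup!r}")


def subgroup_analysis(cohort, scores, endpoints_df, subgroup: str,
                      config: AnalysisConfig | None = None) -> dict:
    """Run the bivariable machinery on a filtered subset.

    Filters: ``mss`` (microsatellite-stable tumors), ``stage2`` and its
    pathology risk strata, or ``none``.
    """
    config = config or AnalysisConfig()
    mask = _subgroup_mask(cohort, subgroup)
    sub = cohort[mask.fillna(False)].reset_index(drop=True)
    if sub.empty:
        raise ValueError(f"subgroup filter {subgroup!r} selects no patients")
    table = bivariable_table(sub, scores, endpoints_df, config)
    merged = merge_scored(sub, scores, endpoints_df, config.endpoint)
    return {"subgroup": subgroup, "n_cohort": len(sub),
            "n_scored": len(merged), "table": table}


def age_association(cohort, markers, scores) -> dict[str, TestResult]:
    """Test whether immune densities and Immunoscore depend on patient age.

    Kruskal–Wallis for each of the four densities across the age bins, plus
    a chi-square association test of the two-category Immunoscore by age
    bin.  Bins without patients are merged into their lower neighbour.
    """
    df = cohort.merge(markers, on="patient_id").merge(scores, on="patient_id")
    bins = df["age_years"].map(age_bin)
    present = [lb for lb in AGE_LABELS if (bins == lb).any()]
    if len(present) < len(AGE_LABELS):
        log.warning("age association: empty bins merged (%s present)", present)
    if len(present) < 2:
        raise ValueError("age association needs at least two non-empty age bins")
    out: dict[str, TestResult] = {}
    for ch in CHANNELS:
        groups = [df.loc[bins == lb, ch].dropna() for lb in present]
        stat, p = sps.kruskal(*groups)
        out[ch] = TestResult(float(stat), len(present) - 1, float(p), "kruskal")
    tab = pd.crosstab(bins, df["is2"] == "Lo")
    chi2, p, dof, _ = sps.chi2_contingency(tab)
    out["immunoscore_2cat"] = TestResult(float(chi2), int(dof), float(p), "chisq_assoc")
    return out


COMPARE_CATEGORICAL = ("gender", "t_stage", "n_stage", "tnm_stage", "sidedness",
                       "differentiation", "mucinous", "velipi", "msi_status", "chemo")


def compare_cohorts(cohort_a: pd.DataFrame, cohort_b: pd.DataFrame) -> dict[str, TestResult]:
    """Descriptive covariate comparison of two cohorts.

    Age by two-sample t-test; categorical variables by chi-square, falling
    back to Fisher's exact test for 2x2 tables with any expected cell < 5.
    """
    needed = {"age_years"} | set(COMPARE_CATEGORICAL)
    if not (needed <= set(cohort_a.columns) and needed <= set(cohort_b.columns)):
        raise ValueError("cohorts do not share the required column schema")
    out: dict[str, TestResult] = {}
    t, p = sps.ttest_ind(cohort_a["age_years"].dropna(), cohort_b["age_years"].dropna())
    out["age_years"] = TestResult(abs(float(t)),
                                  len(cohort_a) + len(cohort_b) - 2, float(p), "ttest")
    for var in COMPARE_CATEGORICAL:
        a = cohort_a[var].replace("", np.nan).dropna()
        b = cohort_b[var].replace("", np.nan).dropna()
        levels = sorted(set(a) | set(b), key=str)
        counts = np.array([[ (a == lv).sum() for lv in levels],
                           [ (b == lv).sum() for lv in levels]], dtype=float)
        counts = counts[:, counts.sum(axis=0) > 0]
        if counts.shape[1] < 2:
            continue
        chi2, p, dof, expected = sps.chi2_contingency(counts)
        if counts.shape == (2, 2) and (expected < 5).any():
            _, p = sps.fisher_exact(counts.astype(int))
            out[var] = TestResult(float("nan"), 1, float(p), "fisher")
        else:
            out[var] = TestResult(float(chi2), int(dof), float(p), "chisq_assoc")
    return out


def km_curves_table(cohort, scores, endpoints_df, config: AnalysisConfig) -> pd.DataFrame:
    """Per-category KM step functions for the chosen scheme, for plotting."""
    col = {"two": "is2", "three": "is3", "five": "is5"}[config.scheme]
    df = merge_scored(cohort, scores, endpoints_df, config.endpoint)
    rows = []
    for lv, grp in df.groupby(col):
        curve = sv.km_estimate(grp["time_months"], grp["event"])
        for t_, s_, v_, nr, de in zip(curve.event_times, curve.survival,
                                      curve.greenwood_var, curve.n_at_risk,
                                      curve.n_events):
            rows.append({"group": lv, "time_months": t_, "survival": s_,
                         "greenwood_var": v_, "n_at_risk": int(nr),
                         "n_events": int(de)})
    return pd.DataFrame(rows, columns=["group", "time_months", "survival",
                                       "greenwood_var", "n_at_risk", "n_events"])
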