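"""Discrete-time 6-hour-window dataset construction.

Each stay contributes records at feature times 6, 12, 18, ... h. A record's
outcome H is 1 when the first hypoglycemia onset falls in the half-open
outcome window ``(t, t+6]``; the stay is censored afterwards (no records at
or beyond the first onset). Continuous covariates are binned to the model's
categorical levels; a hospital-level insulin-prevalence filter mirrors the
multi-hospital-site exclusion rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import covariates as cov
from . import glycemia
from .data_model import BMI_GROUPS, Cohort

WINDOW_H = 6.0

GLUCOSE_LEVELS = ("glucose[70-108]", "glucose[108-144]", "glucose[144-180]", "glucose[>180]")
INSULIN_LEVELS = ("insulin[0]", "insulin[0-2.5]", "insulin[2.5-5]", "insulin[>5]")
LACTATE_LEVELS = ("lactate[0-2]", "lactate[2-5]", "lactate[>5]")
DEXTROSE_LEVELS = ("dextrose[0]", "dextrose[0-25]", "dextrose[>25]")

LEVELS = {
    "bmi_group": tuple(BMI_GROUPS),
    "glucose_bin": GLUCOSE_LEVELS,
    "insulin_bin": INSULIN_LEVELS,
    "lactate_bin": LACTATE_LEVELS,
    "dextrose_bin": DEXTROSE_LEVELS,
}

REFERENTS = {
    "bmi_group": "bmi[18.5-25]",
    "glucose_bin": "glucose[70-108]",
    "insulin_bin": "insulin[0]",
    "lactate_bin": "lactate[0-2]",
    "dextrose_bin": "dextrose[0]",
}

BOOL_TERMS = ("shock", "pn", "en", "steroids")

RECORD_COLUMNS = [
    "stay_id", "database", "feature_time_h", "H", "bmi_group", "glucose_bin",
    "insulin_bin", "lactate_bin", "shock", "pn", "en", "steroids",
    "dextrose_bin", "sofa_no_cardio", "diabetes",
]


@dataclass
class DesignTable:
    """Pooled window records plus the referent level of every term."""

    records: pd.DataFrame
    referents: dict = field(default_factory=dict)
    window_h: float = WINDOW_H
    adjust_diabetes: bool = False

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def n_events(self) -> int:
        return int(self.records["H"].sum())


def build_windows(los_icu_h: float, first_onset_h: float | None, window_h: float = WINDOW_H):
    """Feature times and outcomes for one stay.

    Returns ``[(feature_time, H), ...]``. Records run at ``window_h`` steps
    while the feature time precedes ``min(discharge, first onset)``; the
    record whose outcome window ``(t, t+window_h]`` contains the first onset
    gets H=1 and terminates the sequence. An onset before the first feature
    time yields no records; a partial terminal window is kept with H=0.
    """
    end = los_icu_h if first_onset_h is None else min(los_icu_h, first_onset_h)
    out = []
    t = window_h
    while t < end - 1e-9:
        if first_onset_h is not None and t < first_onset_h <= t + window_h:
            out.append((t, 1))
            return out
        out.append((t, 0))
        t += window_h
    return out


def bin_glucose(v: float) -> str:
    if v < 70.0:
        warnings.warn(f"glucose {v} below hypoglycemia threshold at a feature time; assigned to referent bin")
        return GLUCOSE_LEVELS[0]
    if v < 108.0:
        return GLUCOSE_LEVELS[0]
    if v < 144.0:
        return GLUCOSE_LEVELS[1]
    if v < 180.0:
        return GLUCOSE_LEVELS[2]
    return GLUCOSE_LEVELS[3]


def bin_insulin(v: float) -> str:
    if v <= 0.0:
        return INSULIN_LEVELS[0]
    if v <= 2.5:
        return INSULIN_LEVELS[1]
    if v <= 5.0:
        return INSULIN_LEVELS[2]
    return INSULIN_LEVELS[3]


def bin_lactate(v: float) -> str:
    if v < 2.0:
        return LACTATE_LEVELS[0]
    if v < 5.0:
        return LACTATE_LEVELS[1]
    return LACTATE_LEVELS[2]


def bin_dextrose(v: float) -> str:
    if v <= 0.0:
        return DEXTROSE_LEVELS[0]
    if v < 25.0:
        return DEXTROSE_LEVELS[1]
    return DEXTROSE_LEVELS[2]


def bin_covariates(vector: cov.CovariateVector) -> dict:
    """Map one covariate vector to its categorical model levels."""
    return {
        "glucose_bin": bin_glucose(vector.glucose_mgdl),
        "insulin_bin": bin_insulin(vector.insulin_max12_uh),
        "lactate_bin": bin_lactate(vector.lactate_mmoll),
        "dextrose_bin": bin_dextrose(vector.dextrose_d10_mlh),
        "shock": bool(vector.shock),
        "pn": bool(vector.pn),
        "en": bool(vector.en),
        "steroids": bool(vector.steroids),
        "sofa_no_cardio": int(vector.sofa_no_cardio),
    }


def _bin_table(cov_table: pd.DataFrame) -> pd.DataFrame:
    """Vectorized covariate binning of a batch covariate table."""
    glu = cov_table["glucose_mgdl"].to_numpy(float)
    low = glu < 70.0
    if low.any():
        warnings.warn(f"{int(low.sum())} feature-time glucose value(s) below threshold; assigned to referent bin")
        glu = np.where(low, 70.0, glu)
    out = pd.DataFrame(index=cov_table.index)
    out["glucose_bin"] = np.asarray(GLUCOSE_LEVELS, object)[
        np.searchsorted([108.0, 144.0, 180.0], glu, side="right")]
    ins = cov_table["insulin_max12_uh"].to_numpy(float)
    out["insulin_bin"] = np.asarray(INSULIN_LEVELS, object)[
        np.searchsorted([0.0, 2.5, 5.0], ins, side="left")]
    out["lactate_bin"] = np.asarray(LACTATE_LEVELS, object)[
        np.searchsorted([2.0, 5.0], cov_table["lactate_mmoll"].to_numpy(float), side="right")]
    dex = cov_table["dextrose_d10_mlh"].to_numpy(float)
    out["dextrose_bin"] = np.asarray(DEXTROSE_LEVELS, object)[
        (dex > 0.0).astype(int) + (dex >= 25.0).astype(int)]
    for b in BOOL_TERMS:
        out[b] = cov_table[b].astype(bool).to_numpy()
    out["sofa_no_cardio"] = cov_table["sofa_no_cardio"].astype(int).to_numpy()
    return out


def insulin_prevalence(cohort: Cohort) -> pd.Series:
    """Fraction of stays with any insulin therapy, per hospital_id."""
    ins = cohort.rates[(cohort.rates["drug"] == "insulin") & (cohort.rates["rate"] > 0)]
    treated = set(ins["stay_id"])
    has = cohort.stays["stay_id"].isin(treated)
    return has.groupby(cohort.stays["hospital_id"]).mean()


def filter_hospitals(
    cohort: Cohort,
    min_insulin_prevalence: float = 0.20,
    sites: list[str] | None = None,
) -> Cohort:
    """Drop stays from low-insulin-prevalence hospitals.

    Within the configured multi-hospital site(s) — by default every database
    with more than one hospital — hospitals where strictly fewer than
    ``min_insulin_prevalence`` of stays received insulin are excluded.
    """
    stays = cohort.stays
    if sites is None:
        per_site = stays.groupby("database")["hospital_id"].nunique()
        sites = list(per_site[per_site > 1].index)
    prev = insulin_prevalence(cohort)
    in_scope = stays["database"].isin(sites)
    hosp_prev = stays["hospital_id"].map(prev).fillna(0.0)
    keep = ~in_scope | (hosp_prev >= min_insulin_prevalence)
    return cohort.subset(stays.loc[keep, "stay_id"])


def window_queries(cohort: Cohort, onsets: dict, window_h: float = WINDOW_H) -> pd.DataFrame:
    """All (stay_id, feature_time_h, H) rows for a cohort."""
    rows_sid, rows_t, rows_h = [], [], []
    for sid, los in zip(cohort.stays["stay_id"], cohort.stays["los_icu_h"]):
        for t, h in build_windows(float(los), onsets.get(sid), window_h):
            rows_sid.append(sid)
            rows_t.append(t)
            rows_h.append(h)
    return pd.DataFrame({"stay_id": rows_sid, "time_h": rows_t, "H": rows_h})


def assemble_design(
    cohort: Cohort,
    adjust_diabetes: bool = False,
    subset: str = "all",
    window_h: float = WINDOW_H,
    hypo_threshold: float = glycemia.HYPO_THRESHOLD_MGDL,
    min_insulin_prevalence: float = 0.20,
    multi_hospital_sites: list[str] | None = None,
    apply_hospital_filter: bool = True,
    lactate_missing_cap: float = 0.15,
    bmi_missing_cap: float = 0.05,
) -> DesignTable:
    """Full cohort-to-design pipeline: filter, censor, impute, bin, pool.

    ``subset='low_missingness'`` keeps only databases whose stay-level BMI
    and lactate missingness fall under the configured caps.
    ``adjust_diabetes`` restricts to stays carrying a diabetes flag and adds
    the flag as a predictor.
    """
    if apply_hospital_filter:
        cohort = filter_hospitals(cohort, min_insulin_prevalence, multi_hospital_sites)

    if subset == "low_missingness":
        stays = cohort.stays
        lac = cohort.measurements[cohort.measurements["variable"] == "lactate_mmoll"]
        has_lac = stays["stay_id"].isin(set(lac["stay_id"]))
        lac_missing = (~has_lac).groupby(stays["database"]).mean()
        bmi_missing = stays["bmi"].isna().groupby(stays["database"]).mean()
        ok = (lac_missing < lactate_missing_cap) & (bmi_missing < bmi_missing_cap)
        keep_sites = set(ok[ok].index)
        cohort = cohort.subset(stays.loc[stays["database"].isin(keep_sites), "stay_id"])
    elif subset != "all":
        raise ValueError(f"unknown subset {subset!r}")

    if adjust_diabetes:
        flagged = cohort.stays["diabetes"].notna()
        if not flagged.any():
            raise ValueError("adjust_diabetes requested but no stay carries a diabetes flag")
        cohort = cohort.subset(cohort.stays.loc[flagged, "stay_id"])

    onsets = glycemia.first_onsets(cohort, hypo_threshold)
    queries = window_queries(cohort, onsets, window_h)
    index = cov.index_cohort(cohort)
    medians = cov.cohort_medians(cohort)
    cov_table = cov.covariate_table(index, queries[["stay_id", "time_h"]], medians)
    binned = _bin_table(cov_table)

    stat = cohort.stays.set_index("stay_id")
    records = pd.DataFrame({
        "stay_id": queries["stay_id"],
        "database": queries["stay_id"].map(stat["database"]),
        "feature_time_h": queries["time_h"],
        "H": queries["H"].astype(int),
        "bmi_group": queries["stay_id"].map(stat["bmi_group"]),
    })
    records = pd.concat([records, binned.reset_index(drop=True)], axis=1)
    records["diabetes"] = queries["stay_id"].map(stat["diabetes"])
    records = records[RECORD_COLUMNS]

    site_labels = sorted(cohort.stays["database"].unique())
    referents = dict(REFERENTS)
    referents["database"] = site_labels[0] if site_labels else None
    return DesignTable(records=records, referents=referents, window_h=window_h,
                       adjust_diabetes=adjust_diabetes)


def design_matrix(design: DesignTable) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Dummy-coded predictor matrix (intercept first) and term→columns map.

    Categorical terms are expanded to indicator columns named by level, the
    referent omitted; booleans and SOFA-without-cardiovascular enter as
    single columns; the database term uses the configured referent site.
    """
    rec = design.records
    X = pd.DataFrame(index=rec.index)
    X["intercept"] = 1.0
    terms: dict[str, list[str]] = {}

    for term, levels in LEVELS.items():
        ref = design.referents[term]
        cols = []
        for lev in levels:
            if lev == ref:
                continue
            X[lev] = (rec[term] == lev).astype(float)
            cols.append(lev)
        terms[term] = cols
    for b in BOOL_TERMS:
        X[b] = rec[b].astype(float)
        terms[b] = [b]
    X["sofa_no_cardio"] = rec["sofa_no_cardio"].astype(float)
    terms["sofa_no_cardio"] = ["sofa_no_cardio"]

    ref_db = design.referents.get("database")
    db_levels = sorted(rec["database"].unique())
    cols = []
    for lev in db_levels:
        if lev == ref_db:
            continue
        name = f"db[{lev}]"
        X[name] = (rec["database"] == lev).astype(float)
        cols.append(name)
    terms["database"] = cols

    if design.adjust_diabetes:
        X["diabetes"] = rec["diabetes"].astype(float)
        terms["diabetes"] = ["diabetes"]
    return X, terms
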