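"""Synthetic ICU cohort generator with known ground-truth hazard coefficients.

The generator emulates the statistical structure the analysis assumes:
irregular glucose sampling, BMI-group proportions near a large-EHR mix,
per-6-h-window hypoglycemia driven by a configurable logistic hazard on the
*binned* covariate scale (exactly the design matrix the fitter sees, so
parameter-recovery tests are not confounded by binning error), and
mortality driven by BMI group and hypoglycemia occurrence.

Latent glucose is kept above the hypoglycemia threshold so that every
hypoglycemic measurement is injected by the hazard mechanism; sampling
cadences stay inside the carry-forward horizons so imputation medians never
enter the generated design.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import covariates as cov
from . import windows as win
from .data_model import BMI_GROUPS, Cohort, validate_cohort

_BMI_RANGES = ((14.0, 18.5), (18.5, 25.0), (25.0, 30.0), (30.0, 35.0), (35.0, 40.0), (40.0, 50.0))

#: floor for non-event latent glucose, just above the 70 mg/dL threshold
_GLUCOSE_FLOOR = 72.0

DEFAULT_SITE_LABELS = ("aumc_syn", "hirid_syn", "mimic_syn", "eicu_syn")


def default_hazard_beta(
    bmi_ors=(1.6, 1.0, 0.72, 0.65, 0.61, 0.53),
    base_rate: float = 0.10,
) -> dict[str, float]:
    """Ground-truth log-odds vector for the default scenario.

    BMI odds ratios default to a monotone-decreasing, large-EHR-like
    pattern; treatment/physiology effects are plausible fixed values.
    """
    beta = {"intercept": float(logit(base_rate))}
    for group, or_ in zip(BMI_GROUPS, bmi_ors):
        if group != win.REFERENTS["bmi_group"]:
            beta[group] = float(np.log(or_))
    beta.update({
        "glucose[108-144]": np.log(0.30),
        "glucose[144-180]": np.log(0.26),
        "glucose[>180]": np.log(0.29),
        "insulin[0-2.5]": np.log(2.18),
        "insulin[2.5-5]": np.log(5.07),
        "insulin[>5]": np.log(6.41),
        "lactate[2-5]": np.log(1.6),
        "lactate[>5]": np.log(3.24),
        "shock": np.log(1.48),
        "pn": np.log(0.66),
        "en": np.log(0.83),
        "steroids": np.log(0.85),
        "dextrose[0-25]": np.log(1.06),
        "dextrose[>25]": np.log(2.04),
        "sofa_no_cardio": np.log(1.07),
        "db[hirid_syn]": np.log(0.43),
        "db[mimic_syn]": np.log(0.92),
        "db[eicu_syn]": np.log(1.51),
    })
    return {k: float(v) for k, v in beta.items()}


def default_mortality_beta() -> dict[str, float]:
    beta = {"intercept": float(logit(0.07)), "any_hypo": float(np.log(2.5))}
    for group, or_ in zip(BMI_GROUPS, (1.6, 1.0, 0.75, 0.62, 0.60, 0.65)):
        if group != win.REFERENTS["bmi_group"]:
            beta[group] = float(np.log(or_))
    return beta


@dataclass
class TreatmentRules:
    """Parameters linking treatment generation to glucose and severity."""

    insulin_prob_midpoint_mgdl: float = 135.0
    insulin_prob_scale_mgdl: float = 12.0
    insulin_rate_origin_mgdl: float = 115.0
    insulin_rate_per_mgdl: float = 1.0 / 12.0
    insulin_rate_max_uh: float = 8.0
    bolus_prob: float = 0.15
    dextrose_prob: float = 0.12
    dextrose_concentrations: tuple = (5.0, 10.0, 20.0)
    dextrose_conc_probs: tuple = (0.3, 0.5, 0.2)
    pn_prob: float = 0.10
    en_prob: float = 0.35
    steroid_prob: float = 0.12
    shock_prob: float = 0.15


@dataclass
class GeneratorConfig:
    n_stays: int = 2000
    seed: int = 0
    bmi_group_probs: tuple = (0.03, 0.31, 0.34, 0.18, 0.07, 0.07)
    diabetes_probs: tuple = (0.12, 0.15, 0.22, 0.30, 0.36, 0.42)
    mean_glucose_nondiabetic: tuple = (112.0, 116.0, 121.0, 126.0, 130.0, 133.0)
    mean_glucose_diabetic: tuple = (162.0, 152.0, 146.0, 142.0, 139.0, 137.0)
    glucose_sd: float = 22.0
    glucose_ar1: float = 0.6
    measurement_gap_mean_h: float = 4.0
    measurement_gap_min_h: float = 0.5
    measurement_gap_max_h: float = 20.0
    los_mean_h: float = 48.0
    los_max_h: float = 240.0
    site_labels: tuple = DEFAULT_SITE_LABELS
    site_probs: tuple = (0.15, 0.15, 0.20, 0.50)
    hospitals_per_site: dict = field(default_factory=lambda: {"eicu_syn": 8})
    diabetes_recorded_sites: tuple = ("mimic_syn", "eicu_syn")
    hba1c_recorded_site: str = "mimic_syn"
    hba1c_recorded_prob: float = 0.25
    hazard_beta: dict = field(default_factory=default_hazard_beta)
    mortality_beta: dict = field(default_factory=default_mortality_beta)
    treatment_rules: TreatmentRules = field(default_factory=TreatmentRules)
    window_h: float = 6.0

    def validate(self) -> None:
        if self.n_stays <= 0:
            raise ValueError("n_stays must be > 0")
        probs = np.asarray(self.bmi_group_probs, float)
        if len(probs) != 6 or np.any(probs < 0) or np.any(probs > 1):
            raise ValueError("bmi_group_probs must be 6 probabilities")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("bmi_group_probs must sum to 1")
        if not (0 <= self.glucose_ar1 < 1):
            raise ValueError("glucose_ar1 must be in [0, 1)")
        if self.los_mean_h <= 12:
            raise ValueError("los_mean_h must be > 12")
        if len(self.site_labels) != len(self.site_probs):
            raise ValueError("site_labels and site_probs must align")

    def replace(self, **kwargs) -> "GeneratorConfig":
        return dataclasses.replace(self, **kwargs)


def truth_table(config: GeneratorConfig) -> pd.DataFrame:
    """True coefficients on the OR scale, keyed like the fitted OR table."""
    config.validate()
    rows = [{"level": k, "beta": v, "or": float(np.exp(v))}
            for k, v in config.hazard_beta.items()]
    return pd.DataFrame(rows)


def _stay_statics(config: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_stays
    grp_idx = rng.choice(6, size=n, p=np.asarray(config.bmi_group_probs, float))
    lo = np.array([r[0] for r in _BMI_RANGES])[grp_idx]
    hi = np.array([r[1] for r in _BMI_RANGES])[grp_idx]
    bmi = rng.uniform(lo, hi)
    height = np.clip(rng.normal(1.70, 0.10, n), 1.40, 2.10)
    weight = bmi * height**2
    site_idx = rng.choice(len(config.site_labels), size=n, p=np.asarray(config.site_probs, float))
    sites = np.asarray(config.site_labels, object)[site_idx]
    hosp = np.empty(n, dtype=object)
    for i, s in enumerate(sites):
        k = config.hospitals_per_site.get(s, 1)
        hosp[i] = f"{s}_h{rng.integers(k) + 1}"
    diabetic = rng.random(n) < np.asarray(config.diabetes_probs, float)[grp_idx]
    diab_recorded = np.isin(sites, config.diabetes_recorded_sites)
    hba1c = np.where(diabetic, rng.normal(7.6, 1.1, n), rng.normal(5.5, 0.4, n))
    hba1c = np.clip(hba1c, 3.5, 15.0)
    hba1c_rec = (sites == config.hba1c_recorded_site) & (rng.random(n) < config.hba1c_recorded_prob)
    los = np.minimum(12.0 + rng.exponential(config.los_mean_h - 12.0, n), config.los_max_h)
    return pd.DataFrame({
        "stay_id": [f"s{i:06d}" for i in range(n)],
        "database": sites,
        "hospital_id": hosp,
        "age_years": np.round(np.clip(rng.normal(65, 15, n), 18, 100), 1),
        "sex": np.where(rng.random(n) < 0.55, "male", "female"),
        # full precision so the BMI derived downstream reproduces the
        # sampled group exactly (no boundary flips from rounding)
        "height_m": height,
        "weight_kg": weight,
        "bmi": np.nan,  # derived from height/weight at validation
        "admission_type": np.asarray(("medical", "surgical", "other"), object)[
            rng.choice(3, size=n, p=(0.5, 0.4, 0.1))],
        "diabetes": [bool(d) if r else None for d, r in zip(diabetic, diab_recorded)],
        "hba1c_pct": np.where(hba1c_rec, np.round(hba1c, 2), np.nan),
        "los_icu_h": np.round(los, 2),
        "hospital_mortality": False,  # filled after event generation
        "grp_idx": grp_idx,
        "diabetic_true": diabetic,
    })


def _renewal_times(rng, los, mean_gap, min_gap, max_gap, t0=0.5):
    est = int(los / mean_gap * 2) + 12
    gaps = np.clip(rng.exponential(mean_gap, est), min_gap, max_gap)
    times = t0 + np.concatenate(([0.0], np.cumsum(gaps)))
    while times[-1] < los:  # rare top-up
        gaps = np.clip(rng.exponential(mean_gap, est), min_gap, max_gap)
        times = np.concatenate((times, times[-1] + np.cumsum(gaps)))
    return times[times < los]


def _generate_series(config: GeneratorConfig, rng: np.random.Generator, statics: pd.DataFrame):
    """Measurements, rate intervals and flag intervals for every stay."""
    rules = config.treatment_rules
    mu_nd = np.asarray(config.mean_glucose_nondiabetic, float)
    mu_d = np.asarray(config.mean_glucose_diabetic, float)
    m_rows = {"stay_id": [], "variable": [], "time_h": [], "value": []}
    r_rows = {"stay_id": [], "drug": [], "start_h": [], "end_h": [], "rate": [],
              "concentration_pct": [], "bolus": []}
    f_rows = {"stay_id": [], "exposure": [], "start_h": [], "end_h": []}

    def add_meas(sid, var, times, values):
        m_rows["stay_id"].extend([sid] * len(times))
        m_rows["variable"].extend([var] * len(times))
        m_rows["time_h"].extend(np.round(times, 4))
        m_rows["value"].extend(np.round(values, 3))

    def add_rate(sid, drug, s, e, rate, conc=np.nan, bolus=False):
        r_rows["stay_id"].append(sid)
        r_rows["drug"].append(drug)
        r_rows["start_h"].append(round(s, 4))
        r_rows["end_h"].append(round(e, 4))
        r_rows["rate"].append(round(rate, 4))
        r_rows["concentration_pct"].append(conc)
        r_rows["bolus"].append(bolus)

    for row in statics.itertuples(index=False):
        sid, los, g = row.stay_id, row.los_icu_h, row.grp_idx
        mu = (mu_d if row.diabetic_true else mu_nd)[g] + rng.normal(0, 6)

        # glucose: AR(1) around the stay mean, floored above the hypo threshold
        gt = _renewal_times(rng, los, config.measurement_gap_mean_h,
                            config.measurement_gap_min_h, config.measurement_gap_max_h)
        eps = rng.normal(0, 1, len(gt))
        gv = np.empty(len(gt))
        prev = mu + config.glucose_sd * eps[0]
        gv[0] = prev
        innov_sd = config.glucose_sd * np.sqrt(1 - config.glucose_ar1**2)
        for i in range(1, len(gt)):
            prev = mu + config.glucose_ar1 * (prev - mu) + innov_sd * eps[i]
            gv[i] = prev
        gv = np.clip(gv, _GLUCOSE_FLOOR, 600.0)
        add_meas(sid, "glucose_mgdl", gt, gv)

        shock_stay = rng.random() < rules.shock_prob

        lt = _renewal_times(rng, los, 8.0, 1.0, 18.0)
        lac_base = 3.5 if shock_stay else 1.3
        add_meas(sid, "lactate_mmoll", lt, np.clip(lac_base * np.exp(rng.normal(0, 0.35, len(lt))), 0.2, 20.0))

        mt = _renewal_times(rng, los, 2.0, 0.5, 12.0, t0=0.25)
        map_mean = 66.0 if shock_stay else 78.0
        add_meas(sid, "map_mmhg", mt, np.clip(rng.normal(map_mean, 8, len(mt)), 35.0, 130.0))

        lab_t = np.arange(0.1, los, 24.0)
        nlab = len(lab_t)
        add_meas(sid, "bilirubin_mgdl", lab_t, np.clip(np.exp(rng.normal(-0.5, 0.8, nlab)), 0.1, 30.0))
        add_meas(sid, "platelets_e3ul", lab_t, np.clip(rng.normal(220, 90, nlab), 10.0, 600.0))
        add_meas(sid, "creatinine_mgdl", lab_t, np.clip(np.exp(rng.normal(0.0, 0.5, nlab)), 0.2, 10.0))
        add_meas(sid, "pao2fio2", lab_t, np.clip(rng.normal(280, 90, nlab), 50.0, 550.0))
        add_meas(sid, "gcs", lab_t, rng.choice(
            [15, 14, 13, 12, 10, 8, 6, 4], size=nlab,
            p=[0.55, 0.12, 0.08, 0.07, 0.06, 0.05, 0.04, 0.03]))

        # insulin: treated with probability increasing in the stay glucose mean
        if rng.random() < expit((mu - rules.insulin_prob_midpoint_mgdl) / rules.insulin_prob_scale_mgdl):
            base = np.clip((mu - rules.insulin_rate_origin_mgdl) * rules.insulin_rate_per_mgdl,
                           0.5, rules.insulin_rate_max_uh)
            half = los / 2.0
            r1 = float(base * np.exp(rng.normal(0, 0.2)))
            r2 = float(base * np.exp(rng.normal(0, 0.3)))
            add_rate(sid, "insulin", 0.0, half, r1)
            add_rate(sid, "insulin", half, los, r2)
            if rng.random() < rules.bolus_prob:
                tb = float(rng.uniform(0.5, los))
                add_rate(sid, "insulin", tb, tb, float(rng.uniform(2.0, 6.0)), bolus=True)

        if shock_stay:
            add_rate(sid, "vasopressor", 0.0, float(rng.uniform(6.0, los)), float(rng.uniform(2.0, 20.0)))

        if rng.random() < rules.dextrose_prob:
            s = float(rng.uniform(0.0, los / 2))
            e = float(min(los, s + rng.uniform(4.0, 48.0)))
            conc = float(rng.choice(rules.dextrose_concentrations, p=rules.dextrose_conc_probs))
            add_rate(sid, "dextrose", s, e, float(rng.uniform(5.0, 60.0)), conc=conc)

        for exposure, prob in (("parenteral_nutrition", rules.pn_prob),
                               ("enteral_nutrition", rules.en_prob),
                               ("corticosteroids", rules.steroid_prob)):
            if rng.random() < prob:
                s = float(rng.uniform(0.0, los / 2))
                e = float(min(los, s + rng.uniform(12.0, 96.0)))
                f_rows["stay_id"].append(sid)
                f_rows["exposure"].append(exposure)
                f_rows["start_h"].append(round(s, 4))
                f_rows["end_h"].append(round(e, 4))

    return pd.DataFrame(m_rows), pd.DataFrame(r_rows), pd.DataFrame(f_rows)


def _hazard_logit(config: GeneratorConfig, records: pd.DataFrame) -> np.ndarray:
    """True log-odds for binned window records under ``hazard_beta``."""
    beta = config.hazard_beta
    logit_v = np.full(len(records), beta["intercept"], dtype=float)
    for col in ("bmi_group", "glucose_bin", "insulin_bin", "lactate_bin", "dextrose_bin"):
        logit_v += records[col].map(lambda lev: beta.get(lev, 0.0)).to_numpy(float)
    for col in ("shock", "pn", "en", "steroids"):
        logit_v += beta.get(col, 0.0) * records[col].to_numpy(float)
    logit_v += beta.get("sofa_no_cardio", 0.0) * records["sofa_no_cardio"].to_numpy(float)
    logit_v += records["database"].map(lambda s: beta.get(f"db[{s}]", 0.0)).to_numpy(float)
    if "diabetes" in records:
        diab = np.array([0.0 if pd.isna(x) else float(x) for x in records["diabetes"]])
        logit_v += beta.get("diabetes", 0.0) * diab
    return logit_v


def generate_cohort(config: GeneratorConfig) -> Cohort:
    """Generate a full cohort; deterministic given ``config`` (incl. seed).

    Hypoglycemia events are drawn per 6-h window from the logistic hazard
    applied to the stay's current binned covariates; an event injects a
    glucose measurement uniform in [40, 70] mg/dL into that outcome window
    and censors further event draws for the stay. Mortality then follows
    ``mortality_beta`` given BMI group and event history.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    statics = _stay_statics(config, rng)
    meas, rates, flags = _generate_series(config, rng, statics)

    stays = statics.drop(columns=["grp_idx", "diabetic_true"]).copy()
    # generator output satisfies the invariants by construction; a single
    # full validation happens on the final cohort below
    stays["bmi"] = stays["weight_kg"] / stays["height_m"] ** 2
    stays["bmi_group"] = np.asarray(BMI_GROUPS, object)[statics["grp_idx"].to_numpy()]
    base = Cohort(stays=stays, measurements=meas, rates=rates, flags=flags)

    # all candidate windows as if no event occurred (an event only censors
    # later windows, never alters earlier covariates)
    onsets_none: dict[str, None] = {}
    queries = win.window_queries(base, onsets_none, config.window_h)
    index = cov.index_cohort(base)
    medians = cov.cohort_medians(base)
    cov_table = cov.covariate_table(index, queries[["stay_id", "time_h"]], medians)
    binned = win._bin_table(cov_table)
    stat = base.stays.set_index("stay_id")
    records = pd.concat([
        pd.DataFrame({
            "stay_id": queries["stay_id"],
            "database": queries["stay_id"].map(stat["database"]),
            "bmi_group": queries["stay_id"].map(stat["bmi_group"]),
            "time_h": queries["time_h"],
        }),
        binned.reset_index(drop=True),
    ], axis=1)

    p = expit(_hazard_logit(config, records))
    hit = rng.random(len(p)) < p
    event_time_u = rng.uniform(0.005, 1.0, len(p))
    value_u = rng.uniform(40.0, 70.0, len(p))

    los_map = stat["los_icu_h"]
    first_hit = (
        records.loc[hit, ["stay_id", "time_h"]]
        .groupby("stay_id", sort=False)["time_h"].min()
    )
    extra_rows = []
    hit_idx = records.index[hit]
    chosen = set()
    for i in hit_idx:
        sid = records.at[i, "stay_id"]
        t = records.at[i, "time_h"]
        if first_hit.get(sid) != t or sid in chosen:
            continue
        chosen.add(sid)
        los = float(los_map[sid])
        end = min(t + config.window_h, los)
        te = t + (end - t) * event_time_u[i]  # full precision: avoids grid collisions
        extra_rows.append({"stay_id": sid, "variable": "glucose_mgdl",
                           "time_h": float(te), "value": round(float(value_u[i]), 3)})

    if extra_rows:
        meas = pd.concat([meas, pd.DataFrame(extra_rows)], ignore_index=True)

    any_hypo = stays["stay_id"].isin(chosen).to_numpy()
    mb = config.mortality_beta
    mlogit = np.full(len(stays), mb["intercept"])
    grp_labels = np.asarray(BMI_GROUPS, object)[statics["grp_idx"].to_numpy()]
    mlogit += np.array([mb.get(g, 0.0) for g in grp_labels])
    mlogit += mb.get("any_hypo", 0.0) * any_hypo
    stays = stays.copy()
    stays["hospital_mortality"] = rng.random(len(stays)) < expit(mlogit)

    return validate_cohort(stays, meas, rates, flags)


def generate_design(config: GeneratorConfig, n_stays: int | None = None,
                    seed: int | None = None) -> win.DesignTable:
    """Directly simulate a window-level design table (fast path).

    Stay-level covariates are drawn once per stay from plausible marginals
    and held constant over windows; H follows the discrete-time hazard with
    censoring at the first event. Used for calibration and power studies
    where the full measurement-level pipeline would be needlessly slow.
    """
    config.validate()
    n = n_stays if n_stays is not None else config.n_stays
    rng = np.random.default_rng(config.seed if seed is None else seed)

    grp = rng.choice(6, size=n, p=np.asarray(config.bmi_group_probs, float))
    site = np.asarray(config.site_labels, object)[
        rng.choice(len(config.site_labels), size=n, p=np.asarray(config.site_probs, float))]
    los = np.minimum(12.0 + rng.exponential(config.los_mean_h - 12.0, n), config.los_max_h)
    k_max = np.ceil(los / config.window_h).astype(int) - 1

    stay = pd.DataFrame({
        "stay_id": [f"s{i:06d}" for i in range(n)],
        "database": site,
        "bmi_group": np.asarray(BMI_GROUPS, object)[grp],
        "glucose_bin": np.asarray(win.GLUCOSE_LEVELS, object)[
            rng.choice(4, size=n, p=(0.25, 0.45, 0.20, 0.10))],
        "insulin_bin": np.asarray(win.INSULIN_LEVELS, object)[
            rng.choice(4, size=n, p=(0.55, 0.20, 0.15, 0.10))],
        "lactate_bin": np.asarray(win.LACTATE_LEVELS, object)[
            rng.choice(3, size=n, p=(0.75, 0.20, 0.05))],
        "shock": rng.random(n) < 0.2,
        "pn": rng.random(n) < 0.08,
        "en": rng.random(n) < 0.30,
        "steroids": rng.random(n) < 0.10,
        "dextrose_bin": np.asarray(win.DEXTROSE_LEVELS, object)[
            rng.choice(3, size=n, p=(0.90, 0.05, 0.05))],
        "sofa_no_cardio": np.minimum(rng.poisson(3.0, n), 20),
        "diabetes": np.where(np.isin(site, config.diabetes_recorded_sites),
                             rng.random(n) < 0.25, None),
    })
    p = expit(_hazard_logit(config, stay))
    g = rng.geometric(np.clip(p, 1e-12, 1 - 1e-12))
    n_rec = np.minimum(g, np.maximum(k_max, 0))
    event = g <= k_max

    reps = np.repeat(np.arange(n), n_rec)
    records = stay.iloc[reps].reset_index(drop=True)
    within = np.concatenate([np.arange(k) for k in n_rec]) if len(reps) else np.array([], int)
    records["feature_time_h"] = (within + 1) * config.window_h
    records["H"] = 0
    last = np.cumsum(n_rec) - 1
    ev_rows = last[(n_rec > 0) & event]
    records.loc[ev_rows, "H"] = 1
    records = records[win.RECORD_COLUMNS]

    referents = dict(win.REFERENTS)
    referents["database"] = sorted(config.site_labels)[0]
    return win.DesignTable(records=records, referents=referents, window_h=config.window_h)
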