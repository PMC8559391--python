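"""Rule-based covariate engineering at arbitrary query times.

Point values are resolved by bounded last-observation-carried-forward:
frequently measured variables (glucose, lactate, MAP) carry forward for at
most 24 h, daily labs for at most 48 h, after which the cohort median (per
database) is substituted. Treatment doses are derived from infusion
intervals; SOFA components follow the original six-organ 0-4 scoring.

Scalar operations define the contract; :func:`covariate_table` is the
vectorized batch path used by the pipeline and the synthetic generator and
is property-tested against the scalar route.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass

import numpy as np
import pandas as pd

CARRY_FORWARD_FREQUENT_H = 24.0
CARRY_FORWARD_INFREQUENT_H = 48.0
FREQUENT_VARIABLES = ("glucose_mgdl", "lactate_mmoll", "map_mmhg")
INFREQUENT_VARIABLES = ("bilirubin_mgdl", "platelets_e3ul", "creatinine_mgdl", "pao2fio2", "gcs")

SHOCK_MAP_MMHG = 60.0
INSULIN_LOOKBACK_H = 12
GCS_DEFAULT = 15.0

_SOFA_EDGES = {
    "respiratory": ([100.0, 200.0, 300.0, 400.0], True),   # PaO2/FiO2, lower is worse
    "coagulation": ([20.0, 50.0, 100.0, 150.0], True),     # platelets
    "cns": ([6.0, 10.0, 13.0, 15.0], True),                # GCS
    "hepatic": ([1.2, 2.0, 6.0, 12.0], False),             # bilirubin, higher is worse
    "renal": ([1.2, 2.0, 3.5, 5.0], False),                # creatinine
}


def carry_horizon(variable: str) -> float:
    if variable in FREQUENT_VARIABLES:
        return CARRY_FORWARD_FREQUENT_H
    if variable in INFREQUENT_VARIABLES:
        return CARRY_FORWARD_INFREQUENT_H
    raise KeyError(f"no carry-forward class for variable {variable!r}")


@dataclass(frozen=True)
class SofaComponents:
    respiratory: int
    coagulation: int
    hepatic: int
    cardiovascular: int
    cns: int
    renal: int

    @property
    def total(self) -> int:
        return (self.respiratory + self.coagulation + self.hepatic
                + self.cardiovascular + self.cns + self.renal)

    @property
    def total_no_cardio(self) -> int:
        return self.total - self.cardiovascular


@dataclass(frozen=True)
class CovariateVector:
    stay_id: str
    time_h: float
    glucose_mgdl: float
    lactate_mmoll: float
    shock: bool
    insulin_max12_uh: float
    dextrose_d10_mlh: float
    pn: bool
    en: bool
    steroids: bool
    sofa_total: int
    sofa_no_cardio: int
    imputed_flags: dict


def value_at(times, values, t: float, variable: str, cohort_median: float):
    """Bounded-LOCF lookup: ``(value, provenance)`` at time ``t``.

    Provenance is ``observed`` at an observation time, ``carried`` while the
    last observation is within the variable's horizon, and ``median`` beyond
    it (or when nothing has been observed yet). GCS falls back to 15, the
    convention for unrecorded sedation-free patients, before the median.
    """
    if t < 0:
        raise ValueError("query time must be >= 0")
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(times) > 1 and np.any(np.diff(times) < 0):
        raise ValueError("series must be sorted by time")
    horizon = carry_horizon(variable)
    idx = bisect_right(times, t) - 1
    if idx >= 0 and t - times[idx] <= horizon:
        prov = "observed" if t == times[idx] else "carried"
        return float(values[idx]), prov
    if variable == "gcs":
        return GCS_DEFAULT, "default"
    if cohort_median is None or not np.isfinite(cohort_median):
        raise ValueError(f"no observation usable at t={t} for {variable} and cohort median undefined")
    return float(cohort_median), "median"


def _interval_active(start: float, end: float, t: float) -> bool:
    # half-open [start, end); an instantaneous interval never covers t
    return start <= t < end


def shock_flag(map_times, map_values, vasopressor_intervals, t: float, cohort_median_map: float) -> bool:
    """True iff MAP at ``t`` (bounded LOCF) < 60 mmHg or a vasopressor runs at ``t``."""
    for s, e in vasopressor_intervals:
        if _interval_active(s, e, t):
            return True
    map_v, _ = value_at(map_times, map_values, t, "map_mmhg", cohort_median_map)
    return bool(map_v < SHOCK_MAP_MMHG)


def _max_infusion_rate_in_bin(infusions, a: float, b: float) -> float:
    """Max instantaneous sum of active infusion rates over the bin (a, b]."""
    pts = [a, b]
    for s, e, _ in infusions:
        if s < b and e > a:
            pts.extend((max(s, a), min(e, b)))
    pts = sorted(set(pts))
    best = 0.0
    for x0, x1 in zip(pts, pts[1:]):
        m = 0.5 * (x0 + x1)
        tot = sum(r for s, e, r in infusions if s <= m < e)
        if tot > best:
            best = tot
    return best


def max_insulin_12h(insulin_records, t: float, lookback_h: int = INSULIN_LOOKBACK_H) -> float:
    """Maximum hourly insulin dose (u/h) over the ``lookback_h`` hours before ``t``.

    The lookback ``(t-12, t]`` is split into hourly bins; each bin scores the
    maximum concurrent infusion rate plus the total bolus units delivered in
    the bin, and the maximum over bins is returned (0 with no insulin).

    ``insulin_records``: iterable of ``(start_h, end_h, rate, bolus)``;
    boluses have ``start_h == end_h`` and ``rate`` holding total units.
    """
    infusions = [(s, e, r) for s, e, r, bol in insulin_records if not bol and e > s]
    boluses = [(s, r) for s, e, r, bol in insulin_records if bol]
    best = 0.0
    for k in range(lookback_h):
        a = t - lookback_h + k
        b = a + 1.0
        if b <= 0:
            continue
        val = _max_infusion_rate_in_bin(infusions, a, b)
        val += sum(units for ts, units in boluses if a < ts <= b)
        if val > best:
            best = val
    return best


def dextrose_d10_rate(dextrose_intervals, t: float) -> float:
    """Dextrose dose at ``t`` in mL/h of dextrose-10% equivalents.

    Sums ``rate * concentration/10`` over intervals active at ``t``;
    dextrose 5% is excluded by convention.
    """
    total = 0.0
    for s, e, rate, conc in dextrose_intervals:
        if conc is None or not np.isfinite(conc) or conc <= 0:
            raise ValueError(f"dextrose interval with unknown concentration: {conc!r}")
        if conc == 5:
            continue
        if _interval_active(s, e, t):
            total += rate * conc / 10.0
    return total


def _band(component: str, value: float) -> int:
    edges, reverse = _SOFA_EDGES[component]
    pos = int(np.searchsorted(edges, value, side="right"))
    return 4 - pos if reverse else pos


def sofa_components(
    labs: dict,
    map_value: float,
    vasopressor_active: bool,
) -> SofaComponents:
    """Six SOFA organ components (0-4 each) from resolved input values.

    ``labs`` maps ``pao2fio2``, ``platelets_e3ul``, ``bilirubin_mgdl``,
    ``gcs``, ``creatinine_mgdl`` to their values at the query time.
    Cardiovascular: any vasopressor scores 2 (lowest qualifying band, as
    drug-specific doses are not modelled), else MAP < 70 scores 1.
    """
    if vasopressor_active:
        cardio = 2
    elif map_value < 70.0:
        cardio = 1
    else:
        cardio = 0
    return SofaComponents(
        respiratory=_band("respiratory", labs["pao2fio2"]),
        coagulation=_band("coagulation", labs["platelets_e3ul"]),
        hepatic=_band("hepatic", labs["bilirubin_mgdl"]),
        cardiovascular=cardio,
        cns=_band("cns", labs["gcs"]),
        renal=_band("renal", labs["creatinine_mgdl"]),
    )


def cohort_medians(cohort, per_database: bool = True) -> dict:
    """Imputation medians from all observed measurement values.

    Keys are ``(database, variable)`` plus plain ``variable`` entries holding
    the pooled median, used as fallback when a database never observes a
    variable; ``per_database=False`` keeps only the pooled entries.
    """
    out: dict = cohort.measurements.groupby("variable")["value"].median().to_dict()
    if per_database:
        meas = cohort.measurements.merge(cohort.stays[["stay_id", "database"]], on="stay_id")
        out.update(meas.groupby(["database", "variable"])["value"].median().to_dict())
    return out


def _median_for(medians: dict, database: str, variable: str):
    if (database, variable) in medians:
        return medians[(database, variable)]
    return medians.get(variable, float("nan"))


class StayData:
    """Per-stay precomputed arrays for fast repeated covariate queries."""

    __slots__ = ("stay_id", "database", "los_icu_h", "series", "insulin", "dextrose", "vaso", "flags")

    def __init__(self, stay_id, database, los_icu_h):
        self.stay_id = str(stay_id)
        self.database = database
        self.los_icu_h = float(los_icu_h)
        self.series: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        self.insulin: list[tuple[float, float, float, bool]] = []
        self.dextrose: list[tuple[float, float, float, float]] = []
        self.vaso: list[tuple[float, float]] = []
        self.flags: dict[str, list[tuple[float, float]]] = {
            "parenteral_nutrition": [], "enteral_nutrition": [], "corticosteroids": []}

    def get_series(self, variable):
        return self.series.get(variable, (np.empty(0), np.empty(0)))


def index_cohort(cohort) -> dict[str, StayData]:
    """Build the per-stay index used by the batch covariate path."""
    out: dict[str, StayData] = {}
    st = cohort.stays
    for sid, db, los in zip(st["stay_id"].to_numpy(), st["database"].to_numpy(),
                            st["los_icu_h"].to_numpy(float)):
        out[sid] = StayData(sid, db, los)

    m = cohort.measurements
    if len(m):
        # rows are sorted by (stay_id, variable, time_h): groups are contiguous
        sid_a = m["stay_id"].to_numpy()
        var_a = m["variable"].to_numpy()
        t_a = m["time_h"].to_numpy(float)
        v_a = m["value"].to_numpy(float)
        change = np.flatnonzero((sid_a[1:] != sid_a[:-1]) | (var_a[1:] != var_a[:-1]))
        starts = np.concatenate(([0], change + 1))
        ends = np.concatenate((change + 1, [len(m)]))
        for a, b in zip(starts, ends):
            sd = out.get(sid_a[a])
            if sd is not None:
                sd.series[var_a[a]] = (t_a[a:b], v_a[a:b])

    r = cohort.rates
    for sid, drug, s, e, rate, conc, bol in zip(
            r["stay_id"].to_numpy(), r["drug"].to_numpy(),
            r["start_h"].to_numpy(float), r["end_h"].to_numpy(float),
            r["rate"].to_numpy(float), r["concentration_pct"].to_numpy(float),
            r["bolus"].to_numpy(bool)):
        sd = out.get(sid)
        if sd is None:
            continue
        if drug == "insulin":
            sd.insulin.append((s, e, rate, bool(bol)))
        elif drug == "dextrose":
            sd.dextrose.append((s, e, rate, conc))
        else:
            sd.vaso.append((s, e))

    f = cohort.flags
    for sid, exp, s, e in zip(f["stay_id"].to_numpy(), f["exposure"].to_numpy(),
                              f["start_h"].to_numpy(float), f["end_h"].to_numpy(float)):
        sd = out.get(sid)
        if sd is not None:
            sd.flags[exp].append((s, e))
    return out


def covariate_vector(stay_data: StayData, t: float, medians: dict) -> CovariateVector:
    """Assemble the full covariate vector for one stay at one time."""
    db = stay_data.database
    prov: dict[str, str] = {}

    def lookup(var):
        times, vals = stay_data.get_series(var)
        v, p = value_at(times, vals, t, var, _median_for(medians, db, var))
        prov[var] = p
        return v

    glucose = lookup("glucose_mgdl")
    lactate = lookup("lactate_mmoll")
    map_v = lookup("map_mmhg")
    labs = {var: lookup(var) for var in INFREQUENT_VARIABLES}

    vaso_active = any(_interval_active(s, e, t) for s, e in stay_data.vaso)
    shock = vaso_active or map_v < SHOCK_MAP_MMHG
    sofa = sofa_components(labs, map_v, vaso_active)
    return CovariateVector(
        stay_id=stay_data.stay_id,
        time_h=t,
        glucose_mgdl=glucose,
        lactate_mmoll=lactate,
        shock=bool(shock),
        insulin_max12_uh=max_insulin_12h(stay_data.insulin, t),
        dextrose_d10_mlh=dextrose_d10_rate(stay_data.dextrose, t),
        pn=any(_interval_active(s, e, t) for s, e in stay_data.flags["parenteral_nutrition"]),
        en=any(_interval_active(s, e, t) for s, e in stay_data.flags["enteral_nutrition"]),
        steroids=any(_interval_active(s, e, t) for s, e in stay_data.flags["corticosteroids"]),
        sofa_total=sofa.total,
        sofa_no_cardio=sofa.total_no_cardio,
        imputed_flags=prov,
    )


def _locf_batch(times, vals, query, horizon, median):
    if len(times) == 0:
        return np.full(len(query), median)
    idx = np.searchsorted(times, query, side="right") - 1
    safe = np.maximum(idx, 0)
    out = vals[safe]  # fancy indexing: already a copy
    bad = (idx < 0) | (query - times[safe] > horizon)
    if bad.any():
        out[bad] = median
    return out


def _hourly_insulin_profile(records, n_hours: int) -> np.ndarray:
    """Per hourly bin (h, h+1]: max concurrent infusion rate + bolus units."""
    infusions = sorted((s, e, r) for s, e, r, bol in records if not bol and e > s)
    prof = np.zeros(n_hours)
    overlapping = any(infusions[i][0] < infusions[i - 1][1] for i in range(1, len(infusions)))
    if overlapping:
        for h in range(n_hours):
            prof[h] = _max_infusion_rate_in_bin(infusions, float(h), float(h + 1))
    else:
        # disjoint infusions: the bin max is just the per-interval max
        for s, e, r in infusions:
            lo = max(0, int(np.floor(s)))
            hi = min(n_hours, int(np.ceil(e)))
            for h in range(lo, hi):
                if min(e, h + 1.0) - max(s, float(h)) > 0:
                    prof[h] = max(prof[h], r)
    for s, e, r, bol in records:
        if bol:
            h = int(np.ceil(s)) - 1  # bolus at s falls in bin (h, h+1] with h < s <= h+1
            if 0 <= h < n_hours:
                prof[h] += r
    return prof


def covariate_table(cohort_index: dict[str, StayData], queries: pd.DataFrame, medians: dict) -> pd.DataFrame:
    """Covariate vectors for all ``(stay_id, time_h)`` rows of ``queries``.

    Vectorized per stay; equals row-wise :func:`covariate_vector` assembly
    (without provenance columns). Query times must be non-negative.
    """
    n = len(queries)
    sid_all = queries["stay_id"].to_numpy()
    t_all = queries["time_h"].to_numpy(float)
    if n == 0:
        return pd.DataFrame(columns=["stay_id", "time_h"])

    order = np.argsort(sid_all, kind="stable")
    sid_s, t_s = sid_all[order], t_all[order]
    change = np.flatnonzero(sid_s[1:] != sid_s[:-1])
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [n]))

    value_cols = list(FREQUENT_VARIABLES + INFREQUENT_VARIABLES) + [
        "insulin_max12_uh", "dextrose_d10_mlh", "sofa_no_cardio", "sofa_total"]
    bool_cols = ["shock", "pn", "en", "steroids"]
    out = {c: np.zeros(n) for c in value_cols}
    out.update({c: np.zeros(n, dtype=bool) for c in bool_cols})

    for a, b in zip(starts, ends):
        sd = cohort_index[sid_s[a]]
        t = t_s[a:b]
        sl = slice(a, b)
        db = sd.database

        for var in FREQUENT_VARIABLES + INFREQUENT_VARIABLES:
            times, vals = sd.get_series(var)
            # GCS falls back to 15 (not the median), matching value_at
            med = GCS_DEFAULT if var == "gcs" else _median_for(medians, db, var)
            out[var][sl] = _locf_batch(times, vals, t, carry_horizon(var), med)

        vaso = np.zeros(len(t), dtype=bool)
        for s, e in sd.vaso:
            vaso |= (t >= s) & (t < e)
        out["shock"][sl] = vaso | (out["map_mmhg"][sl] < SHOCK_MAP_MMHG)

        if sd.insulin:
            if not np.allclose(t, np.round(t)):
                # hourly profile bins only align with integer query times
                ins = np.array([max_insulin_12h(sd.insulin, ti) for ti in t])
            else:
                n_hours = int(np.ceil(max(sd.los_icu_h, t.max()))) + 1
                prof = _hourly_insulin_profile(sd.insulin, n_hours)
                ins = np.zeros(len(t))
                for i, ti in enumerate(t):
                    hi = min(n_hours, int(round(ti)))  # lookback (t-12, t] = bins t-12 .. t-1
                    lo = max(0, hi - INSULIN_LOOKBACK_H)
                    ins[i] = prof[lo:hi].max() if hi > lo else 0.0
            out["insulin_max12_uh"][sl] = ins

        if sd.dextrose:
            dex = np.zeros(len(t))
            for s, e, r, conc in sd.dextrose:
                if conc == 5:
                    continue
                dex += np.where((t >= s) & (t < e), r * conc / 10.0, 0.0)
            out["dextrose_d10_mlh"][sl] = dex

        for name, key in (("pn", "parenteral_nutrition"), ("en", "enteral_nutrition"),
                          ("steroids", "corticosteroids")):
            if sd.flags[key]:
                flag = np.zeros(len(t), dtype=bool)
                for s, e in sd.flags[key]:
                    flag |= (t >= s) & (t < e)
                out[name][sl] = flag

        cardio = np.where(vaso, 2, np.where(out["map_mmhg"][sl] < 70.0, 1, 0))
        no_cardio = (
            (4 - np.searchsorted(_SOFA_EDGES["respiratory"][0], out["pao2fio2"][sl], side="right"))
            + (4 - np.searchsorted(_SOFA_EDGES["coagulation"][0], out["platelets_e3ul"][sl], side="right"))
            + (4 - np.searchsorted(_SOFA_EDGES["cns"][0], out["gcs"][sl], side="right"))
            + np.searchsorted(_SOFA_EDGES["hepatic"][0], out["bilirubin_mgdl"][sl], side="right")
            + np.searchsorted(_SOFA_EDGES["renal"][0], out["creatinine_mgdl"][sl], side="right")
        )
        out["sofa_no_cardio"][sl] = no_cardio
        out["sofa_total"][sl] = no_cardio + cardio

    inv = np.empty(n, dtype=np.intp)
    inv[order] = np.arange(n)
    cols = {"stay_id": sid_all, "time_h": t_all}
    cols.update({c: out[c][inv] for c in value_cols + bool_cols})
    return pd.DataFrame(cols)


def missingness_report(cohort, t: float = 24.0) -> pd.DataFrame:
    """Fraction of stays with no usable observation at ``t`` (before any
    imputation), per variable and BMI group."""
    variables = FREQUENT_VARIABLES + INFREQUENT_VARIABLES
    stays = cohort.stays[["stay_id", "bmi_group"]]
    meas = cohort.measurements
    rows = []
    for var in variables:
        horizon = carry_horizon(var)
        sub = meas[(meas["variable"] == var) & (meas["time_h"] <= t) & (meas["time_h"] >= t - horizon)]
        observed = set(sub["stay_id"])
        has = stays["stay_id"].isin(observed)
        frac = (~has).groupby(stays["bmi_group"]).mean()
        for grp, f in frac.items():
            rows.append({"variable": var, "bmi_group": grp, "missing_fraction": float(f)})
    return pd.DataFrame(rows)
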