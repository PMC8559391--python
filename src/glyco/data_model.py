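"""Domain types, unit conventions and long-format CSV I/O with validation.

A cohort is a bundle of four long-format tables:

* ``stays`` — one row per ICU stay (demographics, BMI, outcome),
* ``measurements`` — timestamped point values (glucose, lactate, labs, ...),
* ``rates`` — interval-valued infusions (insulin, dextrose, vasopressors),
* ``flags`` — on/off exposure intervals (nutrition, corticosteroids).

All times are hours from ICU admission (decimal, 0-based, per-stay clock).
Glucose is carried in mg/dL throughout.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: mg/dL per mmol/L (molar mass of glucose, 180.16 g/mol).
MGDL_PER_MMOLL = 18.016

#: WHO BMI cut-points; bins are left-closed, right-open.
BMI_EDGES = (18.5, 25.0, 30.0, 35.0, 40.0)
BMI_GROUPS = (
    "bmi[0-18.5]",
    "bmi[18.5-25]",
    "bmi[25-30]",
    "bmi[30-35]",
    "bmi[35-40]",
    "bmi[>40]",
)

HBA1C_GROUPS = ("hba1c[<6.1]", "hba1c[6.1-6.5]", "hba1c[6.6-7.0]", "hba1c[>7.0]")

MEASUREMENT_VARIABLES = (
    "glucose_mgdl",
    "lactate_mmoll",
    "map_mmhg",
    "bilirubin_mgdl",
    "platelets_e3ul",
    "creatinine_mgdl",
    "pao2fio2",
    "gcs",
    "urine_mlh",
)

DRUGS = ("insulin", "dextrose", "vasopressor")
EXPOSURES = ("parenteral_nutrition", "enteral_nutrition", "corticosteroids")

SEXES = ("male", "female")
ADMISSION_TYPES = ("medical", "surgical", "other")

STAY_COLUMNS = [
    "stay_id",
    "database",
    "hospital_id",
    "age_years",
    "sex",
    "height_m",
    "weight_kg",
    "bmi",
    "admission_type",
    "diabetes",
    "hba1c_pct",
    "los_icu_h",
    "hospital_mortality",
]
MEASUREMENT_COLUMNS = ["stay_id", "variable", "time_h", "value"]
RATE_COLUMNS = ["stay_id", "drug", "start_h", "end_h", "rate", "concentration_pct", "bolus"]
FLAG_COLUMNS = ["stay_id", "exposure", "start_h", "end_h"]

_FILE_NAMES = {
    "stays": "stays.csv",
    "measurements": "measurements.csv",
    "rates": "rates.csv",
    "flags": "flags.csv",
}


class SchemaError(ValueError):
    """A required column is missing or a table cannot be parsed."""


class ValidationError(ValueError):
    """Rows violate a domain invariant; message lists the offending rows."""


def mmoll_to_mgdl(value: float) -> float:
    """Convert a glucose concentration from mmol/L to mg/dL.

    Uses the molar-mass factor 18.016, under which the common 3.9 mmol/L
    threshold maps to 70.26 mg/dL (~70 mg/dL).
    """
    value = float(value)
    if not np.isfinite(value) or value < 0:
        raise ValueError(f"glucose concentration must be finite and >= 0, got {value}")
    return value * MGDL_PER_MMOLL


def assign_bmi_group(bmi: float) -> str:
    """Map a BMI (kg/m²) to its WHO group label; bins left-closed right-open."""
    bmi = float(bmi)
    if not np.isfinite(bmi) or bmi <= 0:
        raise ValueError(f"BMI must be finite and > 0, got {bmi}")
    idx = int(np.searchsorted(BMI_EDGES, bmi, side="right"))
    return BMI_GROUPS[idx]


def assign_bmi_group_vec(bmi: pd.Series | np.ndarray) -> np.ndarray:
    """Vectorized :func:`assign_bmi_group`; NaN maps to NaN."""
    bmi = np.asarray(bmi, dtype=float)
    idx = np.searchsorted(BMI_EDGES, bmi, side="right")
    out = np.asarray(BMI_GROUPS, dtype=object)[idx]
    out[~np.isfinite(bmi)] = np.nan
    return out


def assign_hba1c_group(hba1c: float) -> str:
    """Map an HbA1c (%) to its group.

    Bins: < 6.1, [6.1, 6.5] (closed on both ends, so 6.5 does not spill into
    the neighbouring 6.6–7.0 bin), (6.5, 7.0], > 7.0.
    """
    hba1c = float(hba1c)
    if not np.isfinite(hba1c) or hba1c <= 0:
        raise ValueError(f"HbA1c must be finite and > 0, got {hba1c}")
    if hba1c < 6.1:
        return HBA1C_GROUPS[0]
    if hba1c <= 6.5:
        return HBA1C_GROUPS[1]
    if hba1c <= 7.0:
        return HBA1C_GROUPS[2]
    return HBA1C_GROUPS[3]


@dataclass(frozen=True)
class PatientStay:
    """Static attributes of one ICU stay."""

    stay_id: str
    database: str
    hospital_id: str
    age_years: float
    sex: str
    admission_type: str
    los_icu_h: float
    hospital_mortality: bool
    height_m: float | None = None
    weight_kg: float | None = None
    bmi: float | None = None
    diabetes: bool | None = None
    hba1c_pct: float | None = None

    @property
    def bmi_group(self) -> str:
        return assign_bmi_group(self.bmi)


@dataclass(frozen=True)
class TimedValue:
    stay_id: str
    variable: str
    time_h: float
    value: float


@dataclass(frozen=True)
class RateInterval:
    stay_id: str
    drug: str
    start_h: float
    end_h: float
    rate: float
    concentration_pct: float | None = None
    bolus: bool = False


@dataclass(frozen=True)
class FlagInterval:
    stay_id: str
    exposure: str
    start_h: float
    end_h: float


@dataclass
class Cohort:
    """Validated bundle of the four cohort tables.

    ``stays.bmi`` is always populated (derived from height/weight when the
    recorded value is absent; recorded height/weight win on disagreement) and
    ``stays.bmi_group`` holds the WHO group label.
    """

    stays: pd.DataFrame
    measurements: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=MEASUREMENT_COLUMNS))
    rates: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=RATE_COLUMNS))
    flags: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=FLAG_COLUMNS))

    @property
    def n_stays(self) -> int:
        return len(self.stays)

    def stay(self, stay_id) -> PatientStay:
        row = self.stays.loc[self.stays["stay_id"] == stay_id]
        if row.empty:
            raise KeyError(f"unknown stay_id {stay_id!r}")
        r = row.iloc[0]

        def _opt(x):
            return None if pd.isna(x) else x

        return PatientStay(
            stay_id=r["stay_id"],
            database=r["database"],
            hospital_id=r["hospital_id"],
            age_years=float(r["age_years"]),
            sex=r["sex"],
            admission_type=r["admission_type"],
            los_icu_h=float(r["los_icu_h"]),
            hospital_mortality=bool(r["hospital_mortality"]),
            height_m=_opt(r["height_m"]),
            weight_kg=_opt(r["weight_kg"]),
            bmi=_opt(r["bmi"]),
            diabetes=_opt(r["diabetes"]),
            hba1c_pct=_opt(r["hba1c_pct"]),
        )

    def subset(self, stay_ids) -> "Cohort":
        """Restrict every table to the given stays (order of ``stays`` kept)."""
        keep = set(stay_ids)
        return Cohort(
            stays=self.stays[self.stays["stay_id"].isin(keep)].reset_index(drop=True),
            measurements=self.measurements[self.measurements["stay_id"].isin(keep)].reset_index(drop=True),
            rates=self.rates[self.rates["stay_id"].isin(keep)].reset_index(drop=True),
            flags=self.flags[self.flags["stay_id"].isin(keep)].reset_index(drop=True),
        )


def _require_columns(df: pd.DataFrame, cols, table: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{table}: missing required column(s) {missing}")


def _bad_rows(msg_prefix: str, mask: pd.Series) -> str | None:
    if mask.any():
        rows = list(mask[mask].index[:20])
        return f"{msg_prefix} (rows {rows}{', ...' if mask.sum() > 20 else ''})"
    return None


def validate_cohort(
    stays: pd.DataFrame,
    measurements: pd.DataFrame,
    rates: pd.DataFrame,
    flags: pd.DataFrame,
    drop_missing_bmi: bool = True,
) -> Cohort:
    """Validate raw tables and return a :class:`Cohort`.

    Stays with no recorded BMI and no height/weight pair are dropped when
    ``drop_missing_bmi`` (the loader's default), mirroring a
    BMI-recorded-only study population. All other invariant violations raise
    :class:`ValidationError` with row-level diagnostics.
    """
    stays = stays.copy()
    measurements = measurements.copy()
    rates = rates.copy()
    flags = flags.copy()

    _require_columns(stays, STAY_COLUMNS, "stays")
    _require_columns(measurements, MEASUREMENT_COLUMNS, "measurements")
    _require_columns(rates, RATE_COLUMNS, "rates")
    _require_columns(flags, FLAG_COLUMNS, "flags")

    for col in ("age_years", "height_m", "weight_kg", "bmi", "hba1c_pct", "los_icu_h"):
        stays[col] = pd.to_numeric(stays[col], errors="coerce")
    for col in ("diabetes", "hospital_mortality"):
        stays[col] = _to_bool(stays[col])
    stays["stay_id"] = stays["stay_id"].astype(str)

    errors: list[str] = []

    # derive BMI from height/weight; recorded height/weight take precedence
    derivable = stays["height_m"].notna() & stays["weight_kg"].notna()
    derived = stays.loc[derivable, "weight_kg"] / stays.loc[derivable, "height_m"] ** 2
    stays.loc[derivable, "bmi"] = derived
    missing_bmi = stays["bmi"].isna()
    if drop_missing_bmi:
        stays = stays[~missing_bmi].reset_index(drop=True)
    elif missing_bmi.any():
        errors.append(_bad_rows("stays: BMI neither recorded nor derivable", missing_bmi))

    for msg in (
        _bad_rows("stays: age_years must be >= 18", ~(stays["age_years"] >= 18)),
        _bad_rows("stays: los_icu_h must be > 0", ~(stays["los_icu_h"] > 0)),
        _bad_rows("stays: bmi must be > 0", ~(stays["bmi"] > 0)),
        _bad_rows("stays: unknown sex", ~stays["sex"].isin(SEXES)),
        _bad_rows("stays: unknown admission_type", ~stays["admission_type"].isin(ADMISSION_TYPES)),
        _bad_rows("stays: duplicate stay_id", stays["stay_id"].duplicated()),
    ):
        if msg:
            errors.append(msg)

    stays["bmi_group"] = assign_bmi_group_vec(stays["bmi"])

    known = set(stays["stay_id"])

    measurements["stay_id"] = measurements["stay_id"].astype(str)
    measurements = measurements[measurements["stay_id"].isin(known)].reset_index(drop=True)
    for col in ("time_h", "value"):
        measurements[col] = pd.to_numeric(measurements[col], errors="coerce")
    glu = measurements["variable"] == "glucose_mgdl"
    for msg in (
        _bad_rows("measurements: unknown variable", ~measurements["variable"].isin(MEASUREMENT_VARIABLES)),
        _bad_rows("measurements: time_h must be >= 0", ~(measurements["time_h"] >= 0)),
        _bad_rows("measurements: value must be finite",
                  pd.Series(~np.isfinite(measurements["value"].to_numpy(float)),
                            index=measurements.index)),
        _bad_rows("measurements: glucose must be > 0", glu & ~(measurements["value"] > 0)),
        _bad_rows(
            "measurements: duplicate (stay_id, variable, time_h)",
            measurements.duplicated(subset=["stay_id", "variable", "time_h"]),
        ),
    ):
        if msg:
            errors.append(msg)

    rates["stay_id"] = rates["stay_id"].astype(str)
    rates = rates[rates["stay_id"].isin(known)].reset_index(drop=True)
    for col in ("start_h", "end_h", "rate", "concentration_pct"):
        rates[col] = pd.to_numeric(rates[col], errors="coerce")
    rates["bolus"] = _to_bool(rates["bolus"]).fillna(False).astype(bool)
    for msg in (
        _bad_rows("rates: unknown drug", ~rates["drug"].isin(DRUGS)),
        _bad_rows("rates: start_h must be >= 0", ~(rates["start_h"] >= 0)),
        _bad_rows("rates: start_h must be <= end_h", ~(rates["start_h"] <= rates["end_h"])),
        _bad_rows("rates: rate must be >= 0 and finite", ~(rates["rate"] >= 0)),
        _bad_rows(
            "rates: dextrose requires concentration_pct",
            (rates["drug"] == "dextrose") & rates["concentration_pct"].isna(),
        ),
        _bad_rows(
            "rates: bolus only valid for insulin with start_h == end_h",
            rates["bolus"] & ((rates["drug"] != "insulin") | (rates["start_h"] != rates["end_h"])),
        ),
    ):
        if msg:
            errors.append(msg)

    flags["stay_id"] = flags["stay_id"].astype(str)
    flags = flags[flags["stay_id"].isin(known)].reset_index(drop=True)
    for col in ("start_h", "end_h"):
        flags[col] = pd.to_numeric(flags[col], errors="coerce")
    for msg in (
        _bad_rows("flags: unknown exposure", ~flags["exposure"].isin(EXPOSURES)),
        _bad_rows("flags: start_h must be >= 0", ~(flags["start_h"] >= 0)),
        _bad_rows("flags: start_h must be < end_h", ~(flags["start_h"] < flags["end_h"])),
    ):
        if msg:
            errors.append(msg)

    # event times must lie inside the stay
    los = stays.set_index("stay_id")["los_icu_h"]
    if len(measurements):
        m_los = measurements["stay_id"].map(los)
        msg = _bad_rows("measurements: time_h beyond stay discharge", measurements["time_h"] > m_los + 1e-9)
        if msg:
            errors.append(msg)

    if errors:
        raise ValidationError("; ".join(errors))

    measurements = measurements.sort_values(["stay_id", "variable", "time_h"], kind="mergesort").reset_index(drop=True)
    rates = rates.sort_values(["stay_id", "drug", "start_h"], kind="mergesort").reset_index(drop=True)
    flags = flags.sort_values(["stay_id", "exposure", "start_h"], kind="mergesort").reset_index(drop=True)
    return Cohort(stays=stays, measurements=measurements, rates=rates, flags=flags)


def _to_bool(s: pd.Series) -> pd.Series:
    mapping = {
        "true": True, "false": False, "True": True, "False": False,
        True: True, False: False, 1: True, 0: False, 1.0: True, 0.0: False,
        "1": True, "0": False,
    }
    return s.map(lambda x: mapping.get(x, pd.NA) if not pd.isna(x) else pd.NA)


def read_cohort(path: str | os.PathLike, drop_missing_bmi: bool = True) -> Cohort:
    """Read and validate a cohort from a directory of the four CSV files."""
    paths = {k: os.path.join(path, v) for k, v in _FILE_NAMES.items()}
    for name, p in paths.items():
        if not os.path.exists(p):
            raise SchemaError(f"missing input file: {p}")
    tables = {}
    for name, p in paths.items():
        try:
            tables[name] = pd.read_csv(p)
        except Exception as exc:  # pragma: no cover - pandas message passthrough
            raise SchemaError(f"cannot parse {p}: {exc}") from exc
    return validate_cohort(
        tables["stays"], tables["measurements"], tables["rates"], tables["flags"],
        drop_missing_bmi=drop_missing_bmi,
    )


def write_cohort(cohort: Cohort, path: str | os.PathLike) -> None:
    """Write the four cohort CSVs into a directory (created if needed)."""
    os.makedirs(path, exist_ok=True)
    cohort.stays.drop(columns=["bmi_group"], errors="ignore").to_csv(
        os.path.join(path, _FILE_NAMES["stays"]), index=False
    )
    cohort.measurements.to_csv(os.path.join(path, _FILE_NAMES["measurements"]), index=False)
    cohort.rates.to_csv(os.path.join(path, _FILE_NAMES["rates"]), index=False)
    cohort.flags.to_csv(os.path.join(path, _FILE_NAMES["flags"]), index=False)
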