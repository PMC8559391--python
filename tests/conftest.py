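import numpy as np
import pandas as pd
import pytest

from glyco.data_model import (
    FLAG_COLUMNS,
    MEASUREMENT_COLUMNS,
    RATE_COLUMNS,
    STAY_COLUMNS,
    validate_cohort,
)

DEFAULT_STAY = {
    "stay_id": "s1",
    "database": "site_a",
    "hospital_id": "site_a_h1",
    "age_years": 60.0,
    "sex": "female",
    "height_m": 1.70,
    "weight_kg": 70.0,
    "bmi": None,
    "admission_type": "medical",
    "diabetes": None,
    "hba1c_pct": None,
    "los_icu_h": 48.0,
    "hospital_mortality": False,
}


def make_stays(rows):
    full = [{**DEFAULT_STAY, **r} for r in rows]
    return pd.DataFrame(full, columns=STAY_COLUMNS)


def make_measurements(rows):
    """rows: (stay_id, variable, time_h, value) tuples."""
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)


def make_rates(rows):
    """rows: (stay_id, drug, start_h, end_h, rate, concentration_pct, bolus)."""
    return pd.DataFrame(rows, columns=RATE_COLUMNS)


def make_flags(rows):
    """rows: (stay_id, exposure, start_h, end_h)."""
    return pd.DataFrame(rows, columns=FLAG_COLUMNS)


def make_cohort(stays_rows, meas_rows=(), rate_rows=(), flag_rows=()):
    return validate_cohort(
        make_stays(stays_rows),
        make_measurements(list(meas_rows)),
        make_rates(list(rate_rows)),
        make_flags(list(flag_rows)),
    )


@pytest.fixture
def three_stay_cohort():
    stays = [
        {"stay_id": "s1", "height_m": 1.70, "weight_kg": 60.0, "los_icu_h": 30.0},
        {"stay_id": "s2", "height_m": 1.80, "weight_kg": 90.0, "los_icu_h": 50.0,
         "diabetes": True, "hba1c_pct": 7.4},
        {"stay_id": "s3", "height_m": 1.60, "weight_kg": 110.0, "los_icu_h": 24.0,
         "hospital_mortality": True, "database": "site_b", "hospital_id": "site_b_h1"},
    ]
    meas = [
        ("s1", "glucose_mgdl", 1.0, 110.0),
        ("s1", "glucose_mgdl", 5.0, 130.0),
        ("s1", "lactate_mmoll", 1.0, 1.4),
        ("s1", "map_mmhg", 0.5, 80.0),
        ("s2", "glucose_mgdl", 2.0, 160.0),
        ("s2", "glucose_mgdl", 8.0, 65.0),
        ("s2", "glucose_mgdl", 10.0, 120.0),
        ("s2", "map_mmhg", 1.0, 55.0),
        ("s3", "glucose_mgdl", 3.0, 95.0),
    ]
    rates = [
        ("s2", "insulin", 0.0, 10.0, 2.0, None, False),
        ("s2", "dextrose", 4.0, 9.0, 30.0, 10.0, False),
        ("s3", "vasopressor", 0.0, 12.0, 5.0, None, False),
    ]
    flags = [
        ("s1", "enteral_nutrition", 0.0, 20.0),
        ("s2", "corticosteroids", 2.0, 30.0),
    ]
    return make_cohort(stays, meas, rates, flags)


def random_glucose_series(rng, n_max=30, gap_lo=0.5, gap_hi=12.0, hypo_frac=0.35):
    """Sparse random glucose series for oracle-equivalence tests."""
    n = int(rng.integers(0, n_max + 1))
    gaps = rng.uniform(gap_lo, gap_hi, size=n)
    times = np.cumsum(gaps)
    values = np.where(rng.random(n) < hypo_frac,
                      rng.uniform(40.0, 70.0, n),
                      rng.uniform(70.5, 250.0, n))
    los = float(times[-1] + rng.uniform(0.0, 12.0)) if n else float(rng.uniform(1.0, 48.0))
    return times, values, los
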