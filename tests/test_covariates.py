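import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glyco import covariates as cov

from conftest import make_cohort


class TestValueAt:
    def test_infrequent_carried_47h(self):
        v, prov = cov.value_at([0.0], [2.5], 47.0, "bilirubin_mgdl", 1.0)
        assert (v, prov) == (2.5, "carried")

    def test_frequent_median_beyond_24h(self):
        v, prov = cov.value_at([0.0], [100.0], 25.0, "glucose_mgdl", 123.0)
        assert (v, prov) == (123.0, "median")

    def test_observed_at_exact_time(self):
        v, prov = cov.value_at([0.0, 4.0], [90.0, 95.0], 4.0, "glucose_mgdl", 123.0)
        assert (v, prov) == (95.0, "observed")

    def test_infrequent_median_beyond_48h(self):
        v, prov = cov.value_at([0.0], [2.5], 49.0, "bilirubin_mgdl", 0.7)
        assert (v, prov) == (0.7, "median")

    def test_gcs_default_15(self):
        v, prov = cov.value_at([], [], 10.0, "gcs", float("nan"))
        assert (v, prov) == (15.0, "default")

    def test_no_data_no_median_errors(self):
        with pytest.raises(ValueError):
            cov.value_at([], [], 10.0, "glucose_mgdl", float("nan"))

    def test_step_function_idempotent_between_observations(self):
        times, vals = [0.0, 10.0], [100.0, 120.0]
        for t in (10.0, 12.5, 15.0, 20.0):
            v, _ = cov.value_at(times, vals, t, "glucose_mgdl", 999.0)
            assert v == 120.0

    def test_provenance_transitions_with_age(self):
        times, vals = [0.0], [100.0]
        provs = [cov.value_at(times, vals, t, "glucose_mgdl", 1.0)[1] for t in (0.0, 12.0, 30.0)]
        assert provs == ["observed", "carried", "median"]


class TestShockFlag:
    def test_low_map(self):
        assert cov.shock_flag([0.0], [55.0], [], 1.0, 80.0)

    def test_vasopressor_overrides_map(self):
        assert cov.shock_flag([0.0], [65.0], [(0.0, 10.0)], 1.0, 80.0)

    def test_neither(self):
        assert not cov.shock_flag([0.0], [72.0], [], 1.0, 80.0)


class TestMaxInsulin12h:
    def test_stepwise_rates(self):
        records = [(0.0, 5.0, 2.0, False), (5.0, 8.0, 4.0, False)]
        assert cov.max_insulin_12h(records, 10.0) == 4.0

    def test_no_insulin(self):
        assert cov.max_insulin_12h([], 10.0) == 0.0

    def test_bolus_added_to_background(self):
        records = [(0.0, 24.0, 1.0, False), (9.0, 9.0, 3.0, True)]
        assert cov.max_insulin_12h(records, 10.0) == 4.0

    def test_rate_outside_lookback_ignored(self):
        records = [(0.0, 2.0, 6.0, False), (20.0, 30.0, 1.0, False)]
        assert cov.max_insulin_12h(records, 24.0) == 1.0

    def test_concurrent_infusions_sum(self):
        records = [(0.0, 10.0, 2.0, False), (3.0, 6.0, 1.5, False)]
        assert cov.max_insulin_12h(records, 10.0) == 3.5

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_monotone_under_added_infusion(self, seed):
        rng = np.random.default_rng(seed)
        records = [(float(rng.uniform(0, 30)), 0.0, float(rng.uniform(0, 5)), False)
                   for _ in range(rng.integers(0, 4))]
        records = [(s, s + float(rng.uniform(0.5, 20)), r, False) for s, _, r, _ in records]
        t = float(rng.uniform(1, 40))
        base = cov.max_insulin_12h(records, t)
        s0 = float(rng.uniform(0, 30))
        more = records + [(s0, s0 + 5.0, 2.0, False)]
        assert cov.max_insulin_12h(more, t) >= base - 1e-12


class TestDextrose:
    def test_d10_identity(self):
        assert cov.dextrose_d10_rate([(0.0, 10.0, 30.0, 10.0)], 5.0) == 30.0

    def test_d20_doubles(self):
        assert cov.dextrose_d10_rate([(0.0, 10.0, 20.0, 20.0)], 5.0) == 40.0

    def test_d5_excluded(self):
        assert cov.dextrose_d10_rate([(0.0, 10.0, 100.0, 5.0)], 5.0) == 0.0

    def test_unknown_concentration_errors(self):
        with pytest.raises(ValueError):
            cov.dextrose_d10_rate([(0.0, 10.0, 30.0, float("nan"))], 5.0)

    def test_linear_in_rate_and_concentration(self):
        base = cov.dextrose_d10_rate([(0.0, 10.0, 15.0, 10.0)], 5.0)
        assert cov.dextrose_d10_rate([(0.0, 10.0, 30.0, 10.0)], 5.0) == pytest.approx(2 * base)
        assert cov.dextrose_d10_rate([(0.0, 10.0, 15.0, 20.0)], 5.0) == pytest.approx(2 * base)

    def test_inactive_interval(self):
        assert cov.dextrose_d10_rate([(0.0, 4.0, 30.0, 10.0)], 5.0) == 0.0


class TestSofa:
    NORMAL = {"pao2fio2": 450.0, "platelets_e3ul": 300.0, "bilirubin_mgdl": 0.5,
              "gcs": 15.0, "creatinine_mgdl": 0.8}

    def test_all_normal_zero(self):
        s = cov.sofa_components(self.NORMAL, map_value=80.0, vasopressor_active=False)
        assert s.total == 0

    def test_platelets_90_coag_2(self):
        labs = {**self.NORMAL, "platelets_e3ul": 90.0}
        assert cov.sofa_components(labs, 80.0, False).coagulation == 2

    def test_map_55_cardio_1(self):
        assert cov.sofa_components(self.NORMAL, 55.0, False).cardiovascular == 1

    def test_vasopressor_cardio_2(self):
        assert cov.sofa_components(self.NORMAL, 80.0, True).cardiovascular == 2

    def test_no_cardio_identity(self):
        s = cov.sofa_components({**self.NORMAL, "bilirubin_mgdl": 3.0}, 55.0, False)
        assert s.total_no_cardio + s.cardiovascular == s.total

    @pytest.mark.parametrize("component,var,worse,better", [
        ("respiratory", "pao2fio2", 150.0, 350.0),
        ("coagulation", "platelets_e3ul", 30.0, 120.0),
        ("hepatic", "bilirubin_mgdl", 7.0, 1.5),
        ("cns", "gcs", 5.0, 14.0),
        ("renal", "creatinine_mgdl", 4.0, 1.5),
    ])
    def test_monotone_in_severity(self, component, var, worse, better):
        a = getattr(cov.sofa_components({**self.NORMAL, var: worse}, 80.0, False), component)
        b = getattr(cov.sofa_components({**self.NORMAL, var: better}, 80.0, False), component)
        assert a > b


@pytest.fixture
def rich_cohort():
    stays = [
        {"stay_id": "a1", "los_icu_h": 60.0, "height_m": 1.7, "weight_kg": 70.0},
        {"stay_id": "a2", "los_icu_h": 40.0, "height_m": 1.7, "weight_kg": 95.0,
         "database": "site_b", "hospital_id": "site_b_h1"},
    ]
    meas = [
        ("a1", "glucose_mgdl", 1.0, 110.0), ("a1", "glucose_mgdl", 7.0, 150.0),
        ("a1", "lactate_mmoll", 2.0, 2.4),
        ("a1", "map_mmhg", 0.5, 58.0), ("a1", "map_mmhg", 9.0, 75.0),
        ("a1", "bilirubin_mgdl", 0.5, 2.2), ("a1", "platelets_e3ul", 0.5, 80.0),
        ("a1", "creatinine_mgdl", 0.5, 1.5), ("a1", "pao2fio2", 0.5, 250.0),
        ("a1", "gcs", 0.5, 12.0),
        ("a2", "glucose_mgdl", 2.0, 200.0),
        ("a2", "lactate_mmoll", 1.0, 1.0),
        ("a2", "map_mmhg", 1.0, 80.0),
    ]
    rates = [
        ("a1", "insulin", 0.0, 8.0, 3.0, None, False),
        ("a1", "insulin", 9.5, 9.5, 2.0, None, True),
        ("a1", "dextrose", 0.0, 20.0, 20.0, 20.0, False),
        ("a2", "vasopressor", 0.0, 12.0, 4.0, None, False),
    ]
    flags = [
        ("a1", "enteral_nutrition", 0.0, 30.0),
        ("a2", "parenteral_nutrition", 5.0, 20.0),
        ("a2", "corticosteroids", 0.0, 10.0),
    ]
    return make_cohort(stays, meas, rates, flags)


class TestCovariateVector:
    def test_hand_assembled_reference(self, rich_cohort):
        index = cov.index_cohort(rich_cohort)
        medians = cov.cohort_medians(rich_cohort)
        v = cov.covariate_vector(index["a1"], 6.0, medians)
        assert v.glucose_mgdl == 110.0          # carried from t=1
        assert v.lactate_mmoll == 2.4
        assert v.shock                          # MAP 58 carried
        assert v.insulin_max12_uh == 3.0
        assert v.dextrose_d10_mlh == 40.0       # 20 mL/h of D20
        assert v.pn is False and v.en is True and v.steroids is False
        # SOFA: resp 250->2, coag 80->2, hep 2.2->2, cns 12->2, renal 1.5->1; cardio MAP58->1
        assert v.sofa_no_cardio == 9
        assert v.sofa_total == 10

    def test_no_treatment_fields_zero(self, rich_cohort):
        index = cov.index_cohort(rich_cohort)
        medians = cov.cohort_medians(rich_cohort)
        v = cov.covariate_vector(index["a2"], 30.0, medians)
        assert v.insulin_max12_uh == 0.0
        assert v.dextrose_d10_mlh == 0.0
        assert v.steroids is False  # interval [0,10) no longer active

    def test_batch_equals_scalar_route(self, rich_cohort):
        """Dual-route check: vectorized table vs per-call scalar assembly."""
        index = cov.index_cohort(rich_cohort)
        medians = cov.cohort_medians(rich_cohort)
        queries = pd.DataFrame({
            "stay_id": ["a1"] * 5 + ["a2"] * 4,
            "time_h": [6.0, 12.0, 18.0, 24.0, 54.0, 6.0, 12.0, 18.0, 36.0],
        })
        table = cov.covariate_table(index, queries, medians)
        for i, row in table.iterrows():
            v = cov.covariate_vector(index[row["stay_id"]], row["time_h"], medians)
            assert row["glucose_mgdl"] == pytest.approx(v.glucose_mgdl)
            assert row["lactate_mmoll"] == pytest.approx(v.lactate_mmoll)
            assert bool(row["shock"]) == v.shock
            assert row["insulin_max12_uh"] == pytest.approx(v.insulin_max12_uh)
            assert row["dextrose_d10_mlh"] == pytest.approx(v.dextrose_d10_mlh)
            assert (bool(row["pn"]), bool(row["en"]), bool(row["steroids"])) == (v.pn, v.en, v.steroids)
            assert row["sofa_no_cardio"] == v.sofa_no_cardio
            assert row["sofa_total"] == v.sofa_total


class TestMissingness:
    def test_always_observed_zero(self):
        cohort = make_cohort(
            [{"stay_id": "s1", "los_icu_h": 48.0}],
            meas_rows=[("s1", "glucose_mgdl", 20.0, 100.0)])
        rep = cov.missingness_report(cohort, t=24.0)
        row = rep[(rep["variable"] == "glucose_mgdl")]
        assert (row["missing_fraction"] == 0.0).all()

    def test_never_observed_one(self):
        cohort = make_cohort(
            [{"stay_id": "s1", "los_icu_h": 48.0}],
            meas_rows=[("s1", "glucose_mgdl", 20.0, 100.0)])
        rep = cov.missingness_report(cohort, t=24.0)
        row = rep[(rep["variable"] == "lactate_mmoll")]
        assert (row["missing_fraction"] == 1.0).all()

    def test_half_missing(self):
        cohort = make_cohort(
            [{"stay_id": "s1", "los_icu_h": 48.0}, {"stay_id": "s2", "los_icu_h": 48.0}],
            meas_rows=[("s1", "lactate_mmoll", 10.0, 1.5),
                       ("s1", "glucose_mgdl", 10.0, 100.0),
                       ("s2", "glucose_mgdl", 10.0, 100.0)])
        rep = cov.missingness_report(cohort, t=24.0)
        row = rep[(rep["variable"] == "lactate_mmoll")]
        assert row["missing_fraction"].iloc[0] == 0.5
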