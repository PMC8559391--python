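import numpy as np
import pandas as pd
import pytest

from glyco import stats
from glyco import windows as win

from conftest import make_cohort


def make_design(records: pd.DataFrame, **kwargs) -> win.DesignTable:
    """Design table around explicit records, padding defaults for missing columns."""
    defaults = {
        "stay_id": [f"s{i}" for i in range(len(records))],
        "database": "site_a",
        "feature_time_h": 6.0,
        "bmi_group": win.REFERENTS["bmi_group"],
        "glucose_bin": win.REFERENTS["glucose_bin"],
        "insulin_bin": win.REFERENTS["insulin_bin"],
        "lactate_bin": win.REFERENTS["lactate_bin"],
        "dextrose_bin": win.REFERENTS["dextrose_bin"],
        "shock": False, "pn": False, "en": False, "steroids": False,
        "sofa_no_cardio": 0, "diabetes": None,
    }
    rec = records.copy()
    for col, val in defaults.items():
        if col not in rec.columns:
            rec[col] = val
    referents = dict(win.REFERENTS)
    referents["database"] = sorted(rec["database"].unique())[0]
    return win.DesignTable(records=rec[win.RECORD_COLUMNS], referents=referents, **kwargs)


def two_by_two_design(n_exp=100, k_exp=10, n_unexp=100, k_unexp=20):
    rec = pd.DataFrame({
        "shock": [True] * n_exp + [False] * n_unexp,
        "H": [1] * k_exp + [0] * (n_exp - k_exp) + [1] * k_unexp + [0] * (n_unexp - k_unexp),
    })
    return make_design(rec)


class TestPooledLogistic:
    def test_saturated_2x2_matches_cross_product_ratio(self):
        with pytest.warns(UserWarning):  # constant levels dropped
            fit = stats.fit_pooled_logistic(two_by_two_design())
        row = fit.or_table[fit.or_table["level"] == "shock"].iloc[0]
        expected = (10 * 80) / (90 * 20)
        assert row["or"] == pytest.approx(expected, abs=1e-6)
        assert row["ci_low"] < row["or"] < row["ci_high"]

    def test_null_predictor_ci_contains_one(self):
        rng = np.random.default_rng(0)
        n = 4000
        rec = pd.DataFrame({"shock": rng.random(n) < 0.5, "H": (rng.random(n) < 0.2).astype(int)})
        with pytest.warns(UserWarning):
            fit = stats.fit_pooled_logistic(make_design(rec))
        row = fit.or_table[fit.or_table["level"] == "shock"].iloc[0]
        assert row["ci_low"] < 1.0 < row["ci_high"]

    def test_deterministic(self):
        with pytest.warns(UserWarning):
            a = stats.fit_pooled_logistic(two_by_two_design())
        with pytest.warns(UserWarning):
            b = stats.fit_pooled_logistic(two_by_two_design())
        pd.testing.assert_series_equal(a.params, b.params)

    def test_no_events_rejected(self):
        rec = pd.DataFrame({"shock": [True, False], "H": [0, 0]})
        with pytest.raises(ValueError):
            stats.fit_pooled_logistic(make_design(rec))

    def test_separation_detected(self):
        rec = pd.DataFrame({"shock": [True] * 50 + [False] * 50,
                            "H": [1] * 50 + [0] * 50})
        with pytest.raises(stats.SeparationError):
            with pytest.warns(UserWarning):
                stats.fit_pooled_logistic(make_design(rec))

    def test_or_equals_exp_beta(self):
        with pytest.warns(UserWarning):
            fit = stats.fit_pooled_logistic(two_by_two_design())
        for _, r in fit.or_table.iterrows():
            assert r["or"] == pytest.approx(np.exp(r["beta"]))


class TestGvif:
    def test_orthogonal_predictors_unity(self):
        n = 64
        x1 = np.tile([1.0, -1.0], n // 2)
        x2 = np.repeat([1.0, -1.0], n // 2)
        X = pd.DataFrame({"a": x1, "b": x2})
        out = stats.gvif(X, {"a": ["a"], "b": ["b"]}).set_index("term")
        assert out.loc["a", "gvif"] == pytest.approx(1.0, abs=1e-6)
        assert out.loc["b", "gvif"] == pytest.approx(1.0, abs=1e-6)

    def test_two_predictor_closed_form(self):
        rng = np.random.default_rng(1)
        z1, z2 = rng.normal(size=(2, 500))
        # orthonormalize, then mix with exact correlation 0.9
        z1 = (z1 - z1.mean()) / z1.std()
        z2 = z2 - z2.mean()
        z2 -= z1 * (z1 @ z2) / (z1 @ z1)
        z2 /= z2.std()
        x2 = 0.9 * z1 + np.sqrt(1 - 0.81) * z2
        X = pd.DataFrame({"a": z1, "b": x2})
        out = stats.gvif(X, {"a": ["a"], "b": ["b"]}).set_index("term")
        assert out.loc["a", "gvif"] == pytest.approx(1.0 / (1.0 - 0.81), abs=1e-6)

    def test_single_predictor_unity(self):
        X = pd.DataFrame({"a": np.random.default_rng(2).normal(size=50)})
        out = stats.gvif(X, {"a": ["a"]})
        assert out["gvif"].iloc[0] == pytest.approx(1.0, abs=1e-9)

    def test_constant_column_raises(self):
        X = pd.DataFrame({"a": np.ones(10), "b": np.arange(10.0)})
        with pytest.raises(np.linalg.LinAlgError):
            stats.gvif(X, {"a": ["a"], "b": ["b"]})

    def test_multilevel_term_gvif_power(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(200, 3)), columns=["a1", "a2", "b"])
        out = stats.gvif(X, {"a": ["a1", "a2"], "b": ["b"]}).set_index("term")
        g = out.loc["a", "gvif"]
        assert out.loc["a", "gvif_1_2df"] == pytest.approx(g ** 0.25)


class TestCategoricalChi2:
    def test_null_when_term_absent_from_variation(self):
        # all records in the referent BMI group: term contributes nothing
        rng = np.random.default_rng(0)
        rec = pd.DataFrame({
            "shock": rng.random(500) < 0.5,
            "H": (rng.random(500) < 0.2).astype(int),
        })
        with pytest.warns(UserWarning):
            stat, df, p = stats.categorical_chi2(make_design(rec))
        assert stat == pytest.approx(0.0)
        assert df == 0

    def test_strong_effect_significant(self):
        rng = np.random.default_rng(1)
        n = 6000
        grp = rng.choice(["bmi[18.5-25]", "bmi[25-30]"], n)
        p = np.where(grp == "bmi[25-30]", 0.05, 0.20)
        rec = pd.DataFrame({"bmi_group": grp, "H": (rng.random(n) < p).astype(int)})
        with pytest.warns(UserWarning):
            stat, df, pval = stats.categorical_chi2(make_design(rec))
        assert df == 1
        assert pval < 1e-6


class TestBootstrap:
    def test_constant_data_zero_width(self):
        est, lo, hi = stats.bootstrap_mean_ci([5.0] * 20, seed=0)
        assert est == lo == hi == 5.0

    def test_default_b_is_500(self):
        import inspect
        assert inspect.signature(stats.bootstrap_mean_ci).parameters["B"].default == 500

    def test_deterministic_given_seed(self):
        x = np.random.default_rng(0).normal(size=50)
        assert stats.bootstrap_mean_ci(x, seed=42) == stats.bootstrap_mean_ci(x, seed=42)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            stats.bootstrap_mean_ci([])

    def test_affine_equivariance(self):
        x = np.random.default_rng(3).normal(size=80)
        est, lo, hi = stats.bootstrap_mean_ci(x, seed=9)
        est2, lo2, hi2 = stats.bootstrap_mean_ci(3.0 * x + 2.0, seed=9)
        assert est2 == pytest.approx(3 * est + 2, abs=1e-9)
        assert lo2 == pytest.approx(3 * lo + 2, abs=1e-9)
        assert hi2 == pytest.approx(3 * hi + 2, abs=1e-9)

    def test_interval_brackets_estimate(self):
        x = np.random.default_rng(4).normal(size=200)
        est, lo, hi = stats.bootstrap_mean_ci(x, seed=1)
        assert lo <= est <= hi


class TestCompareBmiHalves:
    def test_chi2_hand_computed(self):
        # 2x2: (30 of 100) vs (10 of 100); chi2 without continuity correction
        flags = [1] * 30 + [0] * 70 + [1] * 10 + [0] * 90
        groups = ["bmi[18.5-25]"] * 100 + ["bmi[25-30]"] * 100
        name, stat, p = stats.compare_bmi_halves(flags, groups)
        assert name == "chi2"
        assert stat == pytest.approx(12.5, abs=1e-9)  # n(ad-bc)^2 / row/col products

    def test_constant_equal_values_p_one(self):
        vals = [3.0] * 10
        groups = ["bmi[18.5-25]"] * 5 + ["bmi[30-35]"] * 5
        name, stat, p = stats.compare_bmi_halves(vals, groups)
        assert name == "mannwhitney"
        assert p == 1.0

    def test_empty_stratum_rejected(self):
        with pytest.raises(ValueError):
            stats.compare_bmi_halves([1.0, 2.0], ["bmi[18.5-25]", "bmi[0-18.5]"])

    def test_continuous_uses_mannwhitney(self):
        rng = np.random.default_rng(0)
        vals = np.concatenate([rng.normal(0, 1, 50), rng.normal(2, 1, 50)])
        groups = ["bmi[18.5-25]"] * 50 + ["bmi[30-35]"] * 50
        name, stat, p = stats.compare_bmi_halves(vals, groups)
        assert name == "mannwhitney"
        assert p < 1e-6


class TestGroupSummaries:
    @pytest.fixture
    def small_cohort(self):
        stays = []
        meas = []
        for i in range(8):
            sid = f"s{i}"
            weight = [55.0, 60.0, 80.0, 85.0, 95.0, 100.0, 110.0, 120.0][i]
            stays.append({"stay_id": sid, "weight_kg": weight, "height_m": 1.7,
                          "los_icu_h": 24.0,
                          "hospital_mortality": i == 0})
            meas.append((sid, "glucose_mgdl", 1.0, 100.0 + 5 * i))
            meas.append((sid, "glucose_mgdl", 10.0, 110.0 + 5 * i))
        return make_cohort(stays, meas)

    def test_mortality_rate_direct_proportion(self, small_cohort):
        from glyco import glycemia
        glyc = glycemia.glycemia_table(small_cohort)
        out = stats.group_summaries(small_cohort, glyc, B=100, seed=0)
        normal = out[(out["bmi_group"] == "bmi[18.5-25]") & (out["metric"] == "mortality")]
        assert normal["estimate"].iloc[0] == pytest.approx(0.5)  # 1 death of 2
        assert (out["ci_low"] <= out["estimate"]).all()
        assert (out["estimate"] <= out["ci_high"]).all()

    def test_unknown_stratum_rejected(self, small_cohort):
        from glyco import glycemia
        glyc = glycemia.glycemia_table(small_cohort)
        with pytest.raises(ValueError, match="stratum"):
            stats.group_summaries(small_cohort, glyc, strata=["nope"])

    def test_top_quartile_order_statistic(self):
        df = pd.DataFrame({
            "stay_id": [f"s{i}" for i in range(10)],
            "measurement_rate_per_h": [0.1, 0.9, 0.5, 0.9, 0.2, 0.3, 0.8, 0.4, 0.6, 0.7],
        })
        top = stats.top_quartile_monitoring(df)
        assert len(top) == int(np.ceil(10 / 4))
        # ties at 0.9 broken by stay_id
        assert list(top["stay_id"]) == ["s1", "s3", "s6"]


class TestTreatmentExposure:
    def test_no_treatments_all_zero(self):
        cohort = make_cohort([{"stay_id": "s1"}],
                             meas_rows=[("s1", "glucose_mgdl", 1.0, 100.0)])
        out = stats.treatment_exposure_summary(cohort)
        row = out.iloc[0]
        assert row["mean_max_insulin_uh"] == 0.0
        assert row["mean_dextrose_d10_mlh"] == 0.0
        assert row["mean_pn_duration_h"] == 0.0

    def test_weight_adjusted_insulin(self):
        cohort = make_cohort(
            [{"stay_id": "s1", "height_m": None, "weight_kg": 80.0, "bmi": 27.0}],
            meas_rows=[("s1", "glucose_mgdl", 1.0, 100.0)],
            rate_rows=[("s1", "insulin", 0.0, 20.0, 4.0, None, False)])
        out = stats.treatment_exposure_summary(cohort)
        assert out["mean_max_insulin_uh"].iloc[0] == pytest.approx(4.0)
        assert out["mean_max_insulin_uh_per_kg"].iloc[0] == pytest.approx(0.05)

    def test_duration_clipped_at_onset(self):
        cohort = make_cohort(
            [{"stay_id": "s1", "los_icu_h": 48.0}],
            meas_rows=[("s1", "glucose_mgdl", 10.0, 60.0)],  # onset at 10
            flag_rows=[("s1", "enteral_nutrition", 0.0, 20.0)])
        out = stats.treatment_exposure_summary(cohort)
        assert out["mean_en_duration_h"].iloc[0] == pytest.approx(10.0)
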