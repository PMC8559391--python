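"""Model fitting and statistical machinery.

Pooled logistic regression of the discrete-time hypoglycemia outcome with
Wald odds-ratio intervals, Fox–Monette generalized variance-inflation
factors, a likelihood-ratio χ² for the BMI term, percentile-bootstrap group
means, two-sample BMI<25 vs BMI≥25 comparisons, and the stratified
univariate summary tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from . import covariates as cov
from .data_model import BMI_GROUPS, assign_hba1c_group
from .windows import DesignTable, design_matrix

Z_95 = 1.959964

TWA_BIN_EDGES = (140.0, 180.0)
TWA_BINS = ("twa[70-140]", "twa[140-180]", "twa[>180]")
CV_BIN_EDGES = (10.0, 20.0, 30.0)
CV_BINS = ("cv[<10]", "cv[10-20]", "cv[20-30]", "cv[>30]")
EPISODE_BINS = ("episodes[0]", "episodes[1]", "episodes[>1]")

LOW_BMI_GROUPS = frozenset(BMI_GROUPS[:2])  # BMI < 25


class SeparationError(RuntimeError):
    """The likelihood is monotone in some coefficient (perfect separation)."""


@dataclass
class ModelFit:
    params: pd.Series
    cov_params: pd.DataFrame
    or_table: pd.DataFrame
    gvif_table: pd.DataFrame
    bmi_chi2: dict
    n_records: int
    n_events: int
    llf: float
    terms: dict[str, list[str]] = field(default_factory=dict)


def _glm_fit(X: pd.DataFrame, y: np.ndarray):
    model = sm.GLM(y, X, family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=100)
    big = res.params.abs() > 15
    if big.any():
        raise SeparationError(
            f"fit suggests separation in term(s): {list(res.params.index[big])}")
    return res


def _prepare_matrix(design: DesignTable):
    X, terms = design_matrix(design)
    y = design.records["H"].to_numpy(float)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("need at least one event and one non-event")
    dropped = []
    for c in list(X.columns):
        if c != "intercept" and X[c].nunique() <= 1:
            dropped.append(c)
            X = X.drop(columns=c)
    if dropped:
        warnings.warn(f"dropping empty covariate level(s): {dropped}")

    # quasi-separated indicator levels (outcome constant within the level)
    # are dropped, as common model software does; a level that perfectly
    # classifies the whole dataset is complete separation and errors.
    quasi = []
    for c in X.columns:
        col = X[c].to_numpy()
        if c == "intercept" or not set(np.unique(col)) <= {0.0, 1.0}:
            continue
        in_level = y[col == 1.0]
        if len(in_level) and in_level.min() == in_level.max():
            rest = y[col == 0.0]
            if len(rest) and rest.min() == rest.max() and rest[0] != in_level[0]:
                raise SeparationError(f"complete separation by term {c!r}")
            quasi.append(c)
    if quasi:
        warnings.warn(f"dropping quasi-separated covariate level(s): {quasi}")
        X = X.drop(columns=quasi)
        dropped += quasi

    if dropped:
        terms = {t: [c for c in cols if c not in dropped] for t, cols in terms.items()}
    return X, y, terms


def fit_pooled_logistic(design: DesignTable, cluster_se: bool = False,
                        compute_diagnostics: bool = True) -> ModelFit:
    """Maximum-likelihood pooled logistic fit of H on the binned covariates.

    Odds ratios carry Wald 95% CIs, ``exp(beta ± 1.96·SE)``. Covariate
    levels with no records are dropped with a warning; separation and
    singular designs raise. ``cluster_se=True`` switches to
    stay-clustered robust standard errors (not the default contract).
    """
    X, y, terms = _prepare_matrix(design)
    res = _glm_fit(X, y)
    if cluster_se:
        groups = design.records["stay_id"].to_numpy()
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit(
            cov_type="cluster", cov_kwds={"groups": groups}, maxiter=100)

    params = res.params
    se = res.bse
    rows = []
    for term, cols in terms.items():
        for c in cols:
            beta, s = params[c], se[c]
            rows.append({
                "term": term,
                "level": c,
                "beta": beta,
                "se": s,
                "or": float(np.exp(beta)),
                "ci_low": float(np.exp(beta - Z_95 * s)),
                "ci_high": float(np.exp(beta + Z_95 * s)),
                "p": float(2 * scipy.stats.norm.sf(abs(beta / s))),
            })
    or_table = pd.DataFrame(rows)

    if compute_diagnostics:
        gvif_table = gvif(X.drop(columns="intercept"), terms)
        chi2 = _lrt(design, X, y, res, terms, term="bmi_group")
    else:
        gvif_table = pd.DataFrame()
        chi2 = {}
    return ModelFit(
        params=params,
        cov_params=pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns),
        or_table=or_table,
        gvif_table=gvif_table,
        bmi_chi2=chi2,
        n_records=len(y),
        n_events=int(y.sum()),
        llf=float(res.llf),
        terms=terms,
    )


def _lrt(design, X, y, res_full, terms, term: str) -> dict:
    cols = terms.get(term, [])
    if not cols:
        return {"statistic": 0.0, "df": 0, "p": float("nan")}
    res_red = _glm_fit(X.drop(columns=cols), y)
    stat = 2.0 * (res_full.llf - res_red.llf)
    df = len(cols)
    return {"statistic": float(stat), "df": df, "p": float(scipy.stats.chi2.sf(stat, df))}


def categorical_chi2(design: DesignTable, term: str = "bmi_group") -> tuple[float, int, float]:
    """Likelihood-ratio χ² for a whole categorical term (full vs reduced fit)."""
    X, y, terms = _prepare_matrix(design)
    res_full = _glm_fit(X, y)
    out = _lrt(design, X, y, res_full, terms, term)
    return out["statistic"], out["df"], out["p"]


def gvif(X: pd.DataFrame, terms: dict[str, list[str]]) -> pd.DataFrame:
    """Fox–Monette generalized variance-inflation factors.

    For each term with columns J: ``GVIF = det(R_JJ)·det(R_-J-J)/det(R)``
    on the predictor correlation matrix R; also ``GVIF^(1/(2·df))``.
    Constant columns make R singular and raise.
    """
    cols = [c for c in X.columns if c != "intercept"]
    M = X[cols].to_numpy(float)
    sd = M.std(axis=0)
    if np.any(sd == 0):
        bad = [c for c, s in zip(cols, sd) if s == 0]
        raise np.linalg.LinAlgError(f"constant predictor column(s): {bad}")
    R = np.atleast_2d(np.corrcoef(M, rowvar=False))
    sign, logdet_R = np.linalg.slogdet(R)
    if sign <= 0:
        raise np.linalg.LinAlgError("predictor correlation matrix is singular")
    rows = []
    for term, tcols in terms.items():
        tcols = [c for c in tcols if c in cols]
        if not tcols:
            continue
        idx = [cols.index(c) for c in tcols]
        rest = [i for i in range(len(cols)) if i not in idx]
        s1, ld1 = np.linalg.slogdet(R[np.ix_(idx, idx)])
        s2, ld2 = np.linalg.slogdet(R[np.ix_(rest, rest)]) if rest else (1.0, 0.0)
        if s1 <= 0 or s2 <= 0:
            raise np.linalg.LinAlgError(f"singular sub-matrix for term {term!r}")
        g = float(np.exp(ld1 + ld2 - logdet_R))
        df = len(tcols)
        rows.append({"term": term, "df": df, "gvif": g, "gvif_1_2df": g ** (1.0 / (2 * df))})
    return pd.DataFrame(rows)


def bootstrap_mean_ci(values, B: int = 500, seed: int | np.random.Generator = 0) -> tuple[float, float, float]:
    """Percentile bootstrap 95% CI of the mean over ``B`` resamples."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n == 0:
        raise ValueError("cannot bootstrap an empty sample")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(B, n))
    means = values[idx].mean(axis=1)
    lo, hi = np.percentile(means, [2.5, 97.5])
    return float(values.mean()), float(lo), float(hi)


def compare_bmi_halves(values, bmi_groups, binary: bool | None = None) -> tuple[str, float, float]:
    """Two-sample test of BMI < 25 vs BMI >= 25.

    χ² on the 2×2 table (no continuity correction) for binary data,
    two-sided Mann–Whitney U otherwise; ``binary=None`` auto-detects.
    Returns ``(test_name, statistic, p)``.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(bmi_groups, dtype=object)
    low = np.isin(groups, list(LOW_BMI_GROUPS))
    a, b = values[low], values[~low]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both BMI strata must be nonempty")
    if binary is None:
        binary = set(np.unique(values)) <= {0.0, 1.0}
    if binary:
        table = np.array([[a.sum(), len(a) - a.sum()], [b.sum(), len(b) - b.sum()]])
        res = scipy.stats.chi2_contingency(table, correction=False)
        return "chi2", float(res.statistic), float(res.pvalue)
    if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
        return "mannwhitney", float(len(a) * len(b) / 2.0), 1.0
    res = scipy.stats.mannwhitneyu(a, b, alternative="two-sided")
    return "mannwhitney", float(res.statistic), float(res.pvalue)


def _stay_frame(cohort, glyc: pd.DataFrame) -> pd.DataFrame:
    """Per-stay analysis frame: statics joined with glycemic summaries plus
    derived stratum columns."""
    df = cohort.stays.merge(glyc, on="stay_id", how="left")
    df["mortality"] = df["hospital_mortality"].astype(float)
    df["hypo"] = df["any_hypo"].astype(float)
    twa = df["twa_glucose"].to_numpy(float)
    df["twa_bin"] = np.asarray(TWA_BINS, object)[np.searchsorted(TWA_BIN_EDGES, twa, side="right")]
    df.loc[~np.isfinite(twa), "twa_bin"] = np.nan
    cv = df["cv_glucose"].to_numpy(float)
    df["cv_bin"] = np.asarray(CV_BINS, object)[np.searchsorted(CV_BIN_EDGES, cv, side="right")]
    df.loc[~np.isfinite(cv), "cv_bin"] = np.nan
    ne = df["n_episodes"].to_numpy(float)
    df["episode_bin"] = np.asarray(EPISODE_BINS, object)[np.clip(ne, 0, 2).astype(int)]
    df["hba1c_group"] = df["hba1c_pct"].map(
        lambda x: assign_hba1c_group(x) if np.isfinite(x) else np.nan)
    return df


def top_quartile_monitoring(df: pd.DataFrame) -> pd.DataFrame:
    """Stays in the top quartile of glucose measurement frequency.

    Retains exactly ``ceil(n/4)`` stays ranked by per-hour measurement rate,
    ties broken by stay_id.
    """
    n = len(df)
    k = int(np.ceil(n / 4))
    ranked = df.sort_values(["measurement_rate_per_h", "stay_id"], ascending=[False, True], kind="mergesort")
    return ranked.head(k)


_DEFAULT_METRICS = {
    "twa_glucose": "mean",
    "cv_glucose": "mean",
    "mortality": "rate",
    "hypo": "rate",
    "measurement_rate_per_h": "mean",
    "mean_gap_h": "mean",
}


def group_summaries(
    cohort,
    glyc: pd.DataFrame,
    strata: list[str] | None = None,
    metrics: dict[str, str] | None = None,
    subset: str | None = None,
    B: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Stratified means/rates with percentile-bootstrap 95% CIs.

    ``strata`` extends the implicit BMI grouping (e.g. ``["admission_type"]``,
    ``["diabetes"]``, ``["hba1c_group"]``, ``["twa_bin"]``, ``["cv_bin"]``,
    ``["episode_bin"]``). ``subset`` may be ``hypo_only`` (patients who
    developed hypoglycemia; load/lowest switch to their whole-stay variants)
    or ``top_quartile`` (most frequently monitored quarter).
    """
    df = _stay_frame(cohort, glyc)
    metrics = dict(metrics or _DEFAULT_METRICS)
    if subset == "hypo_only":
        df = df[df["hypo"] == 1.0]
        metrics.setdefault("hypo_load_full", "mean")
        metrics.setdefault("lowest_glucose_full", "mean")
        metrics.setdefault("n_episodes", "mean")
    elif subset == "top_quartile":
        df = top_quartile_monitoring(df)
    elif subset is not None:
        raise ValueError(f"unknown subset {subset!r}")

    strata = list(strata or [])
    for s in strata:
        if s not in df.columns:
            raise ValueError(f"unknown stratum {s!r}")
    keys = ["bmi_group"] + [s for s in strata if s != "bmi_group"]

    rng = np.random.default_rng(seed)
    rows = []
    for key_vals, g in df.groupby(keys, dropna=True, observed=True):
        if not isinstance(key_vals, tuple):
            key_vals = (key_vals,)
        for metric in metrics:
            vals = g[metric].to_numpy(float)
            vals = vals[np.isfinite(vals)]
            if len(vals) == 0:
                continue
            est, lo, hi = bootstrap_mean_ci(vals, B=B, seed=rng)
            row = dict(zip(keys, key_vals))
            row.update({"metric": metric, "estimate": est, "ci_low": lo, "ci_high": hi, "n": len(vals)})
            rows.append(row)
    return pd.DataFrame(rows)


def treatment_exposure_summary(cohort, hypo_threshold: float = 70.0) -> pd.DataFrame:
    """Per-BMI-group treatment exposure, on pre-first-onset time only.

    Mean maximal insulin dose (u/h, and u/h/kg weight-adjusted), mean
    dextrose-10%-equivalent rate (time-averaged over the observation
    window), and mean durations (h) of parenteral/enteral nutrition and
    corticosteroid exposure clipped at first hypoglycemia onset.
    """
    from . import glycemia as gly

    onsets = gly.first_onsets(cohort, hypo_threshold)
    index = cov.index_cohort(cohort)
    rows = []
    for _, stay in cohort.stays.iterrows():
        sid = stay["stay_id"]
        sd = index[sid]
        onset = onsets.get(sid)
        end = sd.los_icu_h if onset is None else min(sd.los_icu_h, onset)
        if end <= 0:
            continue
        n_hours = max(1, int(np.ceil(end)))
        prof = cov._hourly_insulin_profile(sd.insulin, n_hours) if sd.insulin else np.zeros(1)
        max_ins = float(prof.max())
        dex_integral = 0.0
        for s, e, r, conc in sd.dextrose:
            if conc == 5:
                continue
            dex_integral += max(0.0, min(e, end) - max(s, 0.0)) * r * conc / 10.0
        durations = {}
        for name, key in (("pn", "parenteral_nutrition"), ("en", "enteral_nutrition"),
                          ("steroids", "corticosteroids")):
            durations[name] = sum(max(0.0, min(e, end) - max(s, 0.0)) for s, e in sd.flags[key])
        weight = stay["weight_kg"]
        rows.append({
            "stay_id": sid,
            "bmi_group": stay["bmi_group"],
            "max_insulin_uh": max_ins,
            "max_insulin_uh_per_kg": max_ins / weight if np.isfinite(weight) and weight > 0 else np.nan,
            "mean_dextrose_d10_mlh": dex_integral / end,
            "pn_duration_h": durations["pn"],
            "en_duration_h": durations["en"],
            "steroids_duration_h": durations["steroids"],
        })
    per_stay = pd.DataFrame(rows)
    if per_stay.empty:
        return per_stay
    return per_stay.groupby("bmi_group", observed=True).agg(
        n=("stay_id", "size"),
        mean_max_insulin_uh=("max_insulin_uh", "mean"),
        mean_max_insulin_uh_per_kg=("max_insulin_uh_per_kg", "mean"),
        mean_dextrose_d10_mlh=("mean_dextrose_d10_mlh", "mean"),
        mean_pn_duration_h=("pn_duration_h", "mean"),
        mean_en_duration_h=("en_duration_h", "mean"),
        mean_steroids_duration_h=("steroids_duration_h", "mean"),
    ).reset_index()
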