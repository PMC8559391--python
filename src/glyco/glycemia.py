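"""Glycemic statistics: hypoglycemia detection, episode construction,
time-weighted average, variability, load and monitoring-frequency metrics.

Hypoglycemia is blood glucose <= 70 mg/dL. An episode opens at a
hypoglycemic measurement and provisionally ends 6 h later; it is prolonged
by further hypoglycemic measurements, terminated early by a
non-hypoglycemic measurement, and truncated at discharge.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

HYPO_THRESHOLD_MGDL = 70.0
EPISODE_EXTENSION_H = 6.0


@dataclass(frozen=True)
class Episode:
    start_h: float
    end_h: float
    n_hypo_measurements: int


@dataclass(frozen=True)
class EpisodeSet:
    stay_id: str
    episodes: tuple[Episode, ...]

    @property
    def first_onset_h(self) -> float | None:
        return self.episodes[0].start_h if self.episodes else None

    @property
    def n_episodes(self) -> int:
        return len(self.episodes)

    @property
    def any_hypo(self) -> bool:
        return bool(self.episodes)


@dataclass(frozen=True)
class GlycemicSummary:
    stay_id: str
    twa_glucose: float
    cv_glucose: float
    n_measurements: int
    mean_gap_h: float
    measurement_rate_per_h: float
    hypo_load: float
    lowest_glucose: float
    n_episodes: int
    any_hypo: bool
    # whole-stay variants used for the hypoglycemic-cohort severity panels
    hypo_load_full: float = np.nan
    lowest_glucose_full: float = np.nan
    window_end_h: float = np.nan


def _check_sorted(times: np.ndarray) -> None:
    if len(times) > 1 and np.any(np.diff(times) < 0):
        raise ValueError("glucose series must be sorted by time")


def detect_hypo(times, values, threshold: float = HYPO_THRESHOLD_MGDL) -> np.ndarray:
    """Times of all measurements with value <= threshold (inclusive)."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    _check_sorted(times)
    return times[values <= threshold]


def build_episodes(
    stay_id,
    times,
    values,
    los_icu_h: float,
    threshold: float = HYPO_THRESHOLD_MGDL,
    extension_h: float = EPISODE_EXTENSION_H,
) -> EpisodeSet:
    """Left-to-right scan constructing maximal hypoglycemia episodes.

    A hypoglycemic measurement at ``t`` opens an episode with provisional end
    ``t + extension_h``, or prolongs an open one to that end. A
    non-hypoglycemic measurement at ``s`` while an episode is open (``s`` at
    or before the provisional end) closes it at ``s``. Episodes are truncated
    at discharge.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    _check_sorted(times)

    episodes: list[Episode] = []
    start = None  # opening hypo time of the open episode
    prov_end = None
    n_hypo = 0
    for t, v in zip(times, values):
        if v <= threshold:
            if start is not None and t <= prov_end:
                prov_end = t + extension_h
                n_hypo += 1
            else:
                if start is not None:
                    episodes.append(Episode(start, prov_end, n_hypo))
                start, prov_end, n_hypo = t, t + extension_h, 1
        else:
            if start is not None and t <= prov_end:
                episodes.append(Episode(start, t, n_hypo))
                start = None
    if start is not None:
        episodes.append(Episode(start, prov_end, n_hypo))

    truncated = tuple(
        Episode(e.start_h, min(e.end_h, los_icu_h), e.n_hypo_measurements)
        for e in episodes
        if e.start_h <= los_icu_h
    )
    return EpisodeSet(stay_id=str(stay_id), episodes=truncated)


def twa_glucose(times, values, window_end_h: float) -> float:
    """Time-weighted average via LOCF step integration.

    Integrates the last-observation-carried-forward step function from the
    first measurement to ``window_end_h`` and divides by the span; a single
    measurement (or zero-length span) yields that value. Measurements after
    ``window_end_h`` are ignored; returns NaN if none fall in the window.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    _check_sorted(times)
    keep = times <= window_end_h
    times, values = times[keep], values[keep]
    if len(times) == 0:
        return float("nan")
    span = window_end_h - times[0]
    if span <= 0:
        return float(values[-1])
    bounds = np.append(times, window_end_h)
    durations = np.diff(bounds)
    return float(np.sum(durations * values) / span)


def cv_glucose(times, values, window_end_h: float) -> float:
    """Coefficient of variation (%) of raw values in the window.

    Unweighted sample SD (ddof=1) over mean, of measurements taken at or
    before ``window_end_h``; NaN with fewer than two measurements.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    vals = values[times <= window_end_h]
    if len(vals) < 2:
        return float("nan")
    return float(100.0 * np.std(vals, ddof=1) / np.mean(vals))


def hypo_load(values, threshold: float = HYPO_THRESHOLD_MGDL) -> float:
    """Proportion of measurements at or below the threshold; NaN if empty."""
    values = np.asarray(values, dtype=float)
    if len(values) == 0:
        return float("nan")
    return float(np.mean(values <= threshold))


def monitoring_frequency(times, los_icu_h: float) -> tuple[float, float]:
    """Per-hour measurement rate and mean successive gap (NaN if < 2)."""
    if los_icu_h <= 0:
        raise ValueError("los_icu_h must be > 0")
    times = np.asarray(times, dtype=float)
    rate = len(times) / los_icu_h
    gap = float(np.mean(np.diff(times))) if len(times) >= 2 else float("nan")
    return rate, gap


def summarize_glycemia(
    stay_id,
    times,
    values,
    los_icu_h: float,
    threshold: float = HYPO_THRESHOLD_MGDL,
    cv_window: str = "pre_onset",
) -> GlycemicSummary:
    """Per-stay glycemic summary.

    TWA, CV, load, lowest and monitoring frequency are computed on the
    window ending at ``min(discharge, first episode onset)``; episode counts
    use the whole stay. ``cv_window='full'`` switches the CV (only) to the
    whole stay. Whole-stay load/lowest are additionally reported for the
    hypoglycemic-cohort severity analyses.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    episet = build_episodes(stay_id, times, values, los_icu_h, threshold)
    onset = episet.first_onset_h
    window_end = los_icu_h if onset is None else min(los_icu_h, onset)

    in_win = times <= window_end
    win_times, win_values = times[in_win], values[in_win]
    rate, gap = monitoring_frequency(win_times, max(window_end, 1e-12))

    return GlycemicSummary(
        stay_id=str(stay_id),
        twa_glucose=twa_glucose(times, values, window_end),
        cv_glucose=cv_glucose(times, values, window_end if cv_window == "pre_onset" else los_icu_h),
        n_measurements=int(len(win_times)),
        mean_gap_h=gap,
        measurement_rate_per_h=rate,
        hypo_load=hypo_load(win_values, threshold),
        lowest_glucose=float(np.min(win_values)) if len(win_values) else float("nan"),
        n_episodes=episet.n_episodes,
        any_hypo=episet.any_hypo,
        hypo_load_full=hypo_load(values, threshold),
        lowest_glucose_full=float(np.min(values)) if len(values) else float("nan"),
        window_end_h=window_end,
    )


def glycemia_table(cohort, threshold: float = HYPO_THRESHOLD_MGDL, cv_window: str = "pre_onset") -> pd.DataFrame:
    """Glycemic summary for every stay of a cohort, as a tidy table."""
    glu = cohort.measurements[cohort.measurements["variable"] == "glucose_mgdl"]
    grouped = {k: (g["time_h"].to_numpy(), g["value"].to_numpy()) for k, g in glu.groupby("stay_id")}
    rows = []
    for _, stay in cohort.stays.iterrows():
        sid = stay["stay_id"]
        t, v = grouped.get(sid, (np.array([]), np.array([])))
        s = summarize_glycemia(sid, t, v, float(stay["los_icu_h"]), threshold, cv_window)
        rows.append(dataclasses.asdict(s))
    cols = list(GlycemicSummary.__dataclass_fields__)
    return pd.DataFrame(rows, columns=cols)


def first_onsets(cohort, threshold: float = HYPO_THRESHOLD_MGDL) -> dict[str, float | None]:
    """First hypoglycemia onset per stay (None when none occurred).

    The first episode opens at the first hypoglycemic measurement, so the
    onset is simply the earliest glucose value at or below the threshold.
    """
    meas = cohort.measurements
    glu = meas[(meas["variable"] == "glucose_mgdl") & (meas["value"] <= threshold)]
    onset = glu.groupby("stay_id")["time_h"].min()
    out: dict[str, float | None] = {sid: None for sid in cohort.stays["stay_id"]}
    out.update(onset.to_dict())
    return out
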