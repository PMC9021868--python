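"""Estimators of the endodormancy-break (chilling-fulfilment) date.

Four routes are implemented, mirroring how the transition from
endodormancy (released by chill) to ecodormancy (released by heat) is
located in practice:

* :func:`forcing_break_date` — experimental: weekly shoot samples forced in
  a warm chamber; the break is the first sampling whose flower buds gain
  ≥ 30 % fresh weight in 8 chamber days.
* :func:`correlation_break` — statistical: the Pearson correlation between
  bloom date and 15-day windowed mean temperature flips sign around the
  break (warmth delays bloom while chill is being accumulated, advances it
  afterwards); the break is the midpoint between the last significantly
  positive and the first significantly negative day.
* :func:`pls_break` — statistical: PLS regression of bloom dates on daily
  chill (and heat) accumulation; the chilling phase is the run of days
  with negative model coefficients and VIP above 0.8, and its last day is
  the break date.
* :func:`biomarker_break_dates` — observational pass-through of externally
  determined break dates (e.g. male-meiosis onset).

The statistical estimators yield a single date per cultivar; the
experimental and biomarker routes yield one date per season plus the mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .chill_heat import compute_model
from .pls import PLSResult, nipals_pls
from .records_io import (
    BiomarkerDate,
    BloomRecord,
    BudWeightTrial,
    Season,
    TemperatureSeries,
    daily_mean,
    day_of_season_to_monthday,
    season_slice,
)

__all__ = [
    "critical_pcc",
    "CorrelationProfile",
    "CorrelationBreak",
    "season_day_matrix",
    "daily_accumulation_matrix",
    "bloom_day_series",
    "correlation_profile",
    "correlation_break_date",
    "correlation_break",
    "PLSDayProfile",
    "PLSPhases",
    "pls_day_profile",
    "pls_phase_delineation",
    "pls_break",
    "forcing_break_date",
    "BreakEstimate",
    "biomarker_break_dates",
    "mean_break_day",
]

#: days of the correlation design grid: 1 Oct (day 1) … 30 Apr (day 212)
CORRELATION_GRID = np.arange(1, 213)


def critical_pcc(n_years: int, alpha: float = 0.05) -> float:
    """Two-sided significance threshold for a Pearson correlation.

    ``r* = t / sqrt(t² + df)`` with ``df = n_years − 2`` and ``t`` the
    (1 − α/2) Student-t quantile; e.g. 13 years at α = 0.05 gives 0.553
    (reported to 3 decimals).
    """
    if n_years < 3:
        raise ValueError("need at least 3 years for a correlation threshold")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    df = n_years - 2
    t = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(t / np.sqrt(t**2 + df))


# ---------------------------------------------------------------------------
# season-aligned matrices


def season_day_matrix(
    weather_by_season: Mapping[str, TemperatureSeries],
    days: Sequence[int] = CORRELATION_GRID,
) -> pd.DataFrame:
    """Daily-mean temperature matrix: rows = seasons, columns = day-of-season.

    Day-of-season counts from 1 Oct = 1; indices ≤ 0 address September.
    Seasons are aligned on this index, so leap seasons contribute the date
    that falls on each index (29 Feb gets its own index).
    """
    days = np.asarray(list(days), dtype=int)
    rows = {}
    for label, series in sorted(weather_by_season.items()):
        season = Season.from_label(label)
        sliced = season_slice(series, season)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            means = daily_mean(sliced)
        dates = pd.DatetimeIndex([season.date_of_index(int(d)) for d in days])
        rows[label] = means.reindex(dates).to_numpy()
    out = pd.DataFrame.from_dict(rows, orient="index", columns=days)
    if out.isna().any().any():
        raise ValueError("weather does not cover the requested day grid")
    return out


def daily_accumulation_matrix(
    weather_by_season: Mapping[str, TemperatureSeries],
    model: str,
    days: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Daily model increments (CP/day, GDH/day, …): rows = seasons,
    columns = day-of-season (default −29 … 212, i.e. 1 Sep – 30 Apr)."""
    if days is None:
        days = np.arange(-29, 213)
    days = np.asarray(list(days), dtype=int)
    rows = {}
    for label, series in sorted(weather_by_season.items()):
        season = Season.from_label(label)
        acc = compute_model(season_slice(series, season), model)
        daily = acc.daily_increments()
        dates = pd.DatetimeIndex([season.date_of_index(int(d)) for d in days])
        rows[label] = daily.reindex(dates, fill_value=0.0).to_numpy()
    return pd.DataFrame.from_dict(rows, orient="index", columns=days)


def bloom_day_series(blooms: Sequence[BloomRecord], cultivar: str) -> pd.Series:
    """Bloom day-of-season (F50) per season for one cultivar."""
    data = {}
    for rec in blooms:
        if rec.cultivar != cultivar:
            continue
        season = Season.from_label(rec.season)
        data[season.label] = season.day_index(rec.f50_date)
    if not data:
        raise ValueError(f"no bloom records for cultivar {cultivar!r}")
    return pd.Series(data, dtype=float).sort_index()


# ---------------------------------------------------------------------------
# correlation sign-transition estimator


@dataclass
class CorrelationProfile:
    """Moving-window temperature/bloom correlation over the season grid."""

    day_index: np.ndarray
    pcc: np.ndarray
    crit_r: float
    n_seasons: int
    window_days: int
    constant_bloom: bool = False


@dataclass
class CorrelationBreak:
    """Sign-transition result: the endo→ecodormancy transition window and
    its midpoint.  ``break_day`` is None when undetermined."""

    last_positive_day: int | None
    first_negative_day: int | None
    break_day: int | None
    reason: str = ""

    @property
    def determined(self) -> bool:
        return self.break_day is not None

    @property
    def break_monthday(self) -> tuple[int, int] | None:
        if self.break_day is None:
            return None
        return day_of_season_to_monthday(self.break_day)


def correlation_profile(
    day_matrix: pd.DataFrame,
    bloom_days: pd.Series,
    window_days: int = 15,
    alpha: float = 0.05,
    crit_r: float | None = None,
) -> CorrelationProfile:
    """Pearson correlation, per day-of-season, between the mean temperature
    of the ``window_days`` window centred on that day and the bloom date
    across seasons.

    The window is truncated at the grid edges.  Seasons missing a bloom
    record are dropped with a warning.  A zero-variance bloom vector makes
    every correlation undefined; the profile is then all-zero and flagged.
    """
    if window_days < 1 or window_days % 2 == 0:
        raise ValueError("window_days must be odd and positive")
    common = day_matrix.index.intersection(bloom_days.index)
    dropped = set(day_matrix.index) - set(common)
    if dropped:
        warnings.warn(
            f"{len(dropped)} season(s) without bloom records dropped: "
            f"{sorted(dropped)}",
            stacklevel=2,
        )
    X = day_matrix.loc[common]
    y = bloom_days.loc[common].to_numpy()
    n = len(common)
    if n < 3:
        raise ValueError("need at least 3 seasons with weather and bloom data")
    if crit_r is None:
        crit_r = critical_pcc(n, alpha)

    half = window_days // 2
    windowed = (
        X.T.rolling(window=window_days, center=True, min_periods=half + 1)
        .mean()
        .T.to_numpy()
    )
    days = day_matrix.columns.to_numpy(dtype=int)

    yc = y - y.mean()
    sy = np.sqrt((yc**2).sum())
    if sy < 1e-12:
        return CorrelationProfile(
            days, np.zeros(len(days)), crit_r, n, window_days, constant_bloom=True
        )
    Xc = windowed - windowed.mean(axis=0)
    sx = np.sqrt((Xc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        pcc = (Xc * yc[:, None]).sum(axis=0) / (sx * sy)
    pcc = np.where(sx < 1e-12, 0.0, pcc)
    return CorrelationProfile(days, pcc, float(crit_r), n, window_days)


def correlation_break_date(profile: CorrelationProfile) -> CorrelationBreak:
    """Midpoint of the correlation sign-transition period.

    L = last day with PCC ≥ +r*, F = first later day with PCC ≤ −r*; the
    break day is round((L + F)/2), half-up.
    """
    if profile.constant_bloom:
        return CorrelationBreak(None, None, None, "bloom dates constant across seasons")
    pos = profile.day_index[profile.pcc >= profile.crit_r]
    if len(pos) == 0:
        return CorrelationBreak(None, None, None, "no significantly positive day")
    last_pos = int(pos[-1])
    after = (profile.day_index > last_pos) & (profile.pcc <= -profile.crit_r)
    neg = profile.day_index[after]
    if len(neg) == 0:
        return CorrelationBreak(
            last_pos, None, None, "no significantly negative day after the last positive"
        )
    first_neg = int(neg[0])
    mid = (last_pos + first_neg + 1) // 2  # round half-up
    return CorrelationBreak(last_pos, first_neg, mid)


def correlation_break(
    weather_by_season: Mapping[str, TemperatureSeries],
    blooms: Sequence[BloomRecord],
    cultivar: str,
    window_days: int = 15,
    alpha: float = 0.05,
) -> tuple[CorrelationProfile, CorrelationBreak]:
    """End-to-end correlation estimator from raw weather and bloom records."""
    matrix = season_day_matrix(weather_by_season)
    bloom_days = bloom_day_series(blooms, cultivar)
    profile = correlation_profile(matrix, bloom_days, window_days, alpha)
    return profile, correlation_break_date(profile)


# ---------------------------------------------------------------------------
# PLS phase-delineation estimator


@dataclass
class PLSDayProfile:
    """Per-day PLS model coefficients and VIP scores over the season grid."""

    day_index: np.ndarray
    coefficients: np.ndarray
    vip: np.ndarray
    model: PLSResult


@dataclass
class PLSPhases:
    """Chilling/forcing phases delineated from the PLS day profiles.

    The chilling phase ends at the break date; the forcing phase starts
    after an intervening transition of ``transition_days`` (≥ 0) days in
    which neither chill nor heat accumulation shows a significant signal.
    """

    chilling_phase: tuple[int, int] | None
    forcing_phase: tuple[int, int] | None
    transition_days: int | None
    break_day: int | None
    reason: str = ""

    @property
    def determined(self) -> bool:
        return self.break_day is not None

    @property
    def break_monthday(self) -> tuple[int, int] | None:
        if self.break_day is None:
            return None
        return day_of_season_to_monthday(self.break_day)


def pls_day_profile(
    acc_matrix: pd.DataFrame,
    bloom_days: pd.Series,
    n_components: int = 2,
    smooth_days: int = 11,
) -> PLSDayProfile:
    """Fit bloom dates on a seasons × days accumulation matrix.

    Daily increments are smoothed with a centred ``smooth_days`` running
    mean (0 disables) before the centred-and-scaled PLS fit, which damps
    the day-to-day weather noise that the phase signal rides on.
    """
    common = acc_matrix.index.intersection(bloom_days.index)
    if len(common) < 3:
        raise ValueError("need at least 3 seasons with accumulation and bloom data")
    X = acc_matrix.loc[common].to_numpy(dtype=float)
    y = bloom_days.loc[common].to_numpy(dtype=float)
    if smooth_days > 1:
        X = (
            pd.DataFrame(X.T)
            .rolling(window=smooth_days, center=True, min_periods=1)
            .mean()
            .to_numpy()
            .T
        )
    fit = nipals_pls(X, y, n_components=n_components)
    days = acc_matrix.columns.to_numpy(dtype=int)
    return PLSDayProfile(days, fit.coefficients, fit.vip, fit)


def _significant_runs(
    days: np.ndarray, qualifying: np.ndarray, gap_tolerance: int
) -> list[tuple[int, int]]:
    """Runs of qualifying days, merging runs separated by <= gap_tolerance
    non-qualifying days.  Returned as (start_day, end_day) inclusive."""
    qdays = days[qualifying]
    if len(qdays) == 0:
        return []
    runs = []
    start = prev = int(qdays[0])
    for d in qdays[1:]:
        d = int(d)
        if d - prev - 1 <= gap_tolerance:
            prev = d
        else:
            runs.append((start, prev))
            start = prev = d
    runs.append((start, prev))
    return runs


def pls_phase_delineation(
    chill_profile: PLSDayProfile,
    heat_profile: PLSDayProfile | None = None,
    vip_threshold: float = 0.8,
    gap_tolerance: int = 5,
    latest_day: int | None = None,
) -> PLSPhases:
    """Delineate the chilling and forcing phases from PLS day profiles.

    A day is *significant* when its model coefficient is negative (more
    accumulation on that day advances bloom) and its VIP exceeds
    ``vip_threshold``.  The chilling phase is the longest significant run
    in the chill profile (runs separated by at most ``gap_tolerance``
    non-significant days are merged — the observed phases are contiguous
    trends, not strict runs); its last day is the break date.  The forcing
    phase is the longest significant run in the heat profile starting
    after the break.

    ``latest_day`` (typically the earliest observed bloom day) truncates
    the candidate grid: days at or after bloom cannot belong to a dormancy
    phase, and chance significant runs there would otherwise be eligible.
    """
    chill_q = (chill_profile.coefficients < 0) & (chill_profile.vip > vip_threshold)
    if latest_day is not None:
        chill_q = chill_q & (chill_profile.day_index < latest_day)
    chill_runs = _significant_runs(chill_profile.day_index, chill_q, gap_tolerance)
    if not chill_runs:
        return PLSPhases(None, None, None, None, "no significant chilling run")
    chilling = max(chill_runs, key=lambda r: (r[1] - r[0], -r[0]))
    break_day = chilling[1]

    forcing = None
    transition = None
    if heat_profile is not None:
        heat_q = (heat_profile.coefficients < 0) & (heat_profile.vip > vip_threshold)
        heat_runs = [
            r
            for r in _significant_runs(heat_profile.day_index, heat_q, gap_tolerance)
            if r[0] > break_day
        ]
        if heat_runs:
            forcing = max(heat_runs, key=lambda r: (r[1] - r[0], -r[0]))
            transition = forcing[0] - break_day - 1
    return PLSPhases(chilling, forcing, transition, break_day)


def pls_break(
    weather_by_season: Mapping[str, TemperatureSeries],
    blooms: Sequence[BloomRecord],
    cultivar: str,
    n_components: int = 2,
    vip_threshold: float = 0.8,
    smooth_days: int = 11,
    gap_tolerance: int = 5,
) -> tuple[PLSDayProfile, PLSDayProfile, PLSPhases]:
    """End-to-end PLS estimator: chill (CP/day) and heat (GDH/day) profiles
    plus the delineated phases."""
    bloom_days = bloom_day_series(blooms, cultivar)
    chill_m = daily_accumulation_matrix(weather_by_season, "dynamic")
    heat_m = daily_accumulation_matrix(weather_by_season, "gdh")
    chill_p = pls_day_profile(chill_m, bloom_days, n_components, smooth_days)
    heat_p = pls_day_profile(heat_m, bloom_days, n_components, smooth_days)
    return chill_p, heat_p, pls_phase_delineation(
        chill_p,
        heat_p,
        vip_threshold,
        gap_tolerance,
        latest_day=int(bloom_days.min()),
    )


# ---------------------------------------------------------------------------
# experimental and biomarker routes


def forcing_break_date(
    trials: Sequence[BudWeightTrial], threshold: float = 0.30
) -> pd.Timestamp | None:
    """Break date from a season of weekly forcing trials.

    Returns the collection date of the first trial whose mean chamber bud
    weight is at least ``1 + threshold`` times the mean field weight
    (inclusive at the boundary), or None when the criterion is never met
    (endodormancy not released within the sampled window).
    """
    ordered = sorted(trials, key=lambda t: t.collection_date)
    for trial in ordered:
        if trial.weight_ratio >= 1.0 + threshold:
            return trial.collection_date
    return None


@dataclass
class BreakEstimate:
    """Per-cultivar break-date estimate for one method."""

    cultivar: str
    method: str
    per_season_days: dict[str, int]  # season label -> break day-of-season
    mean_day: int  # day-of-season, rounded half-up

    @property
    def mean_monthday(self) -> tuple[int, int]:
        return day_of_season_to_monthday(self.mean_day)

    @property
    def per_season_dates(self) -> dict[str, pd.Timestamp]:
        return {
            label: Season.from_label(label).date_of_index(day)
            for label, day in self.per_season_days.items()
        }


def mean_break_day(days: Sequence[int]) -> int:
    """Average day-of-season ordinals, rounding half-up."""
    return int(np.floor(np.mean(list(days)) + 0.5))


def biomarker_break_dates(
    records: Sequence[BiomarkerDate], cultivar: str | None = None
) -> BreakEstimate:
    """Pass-through of externally observed break dates (one per season)."""
    recs = [r for r in records if cultivar is None or r.cultivar == cultivar]
    if not recs:
        raise ValueError("no biomarker records")
    names = {r.cultivar for r in recs}
    if len(names) > 1:
        raise ValueError(f"records span multiple cultivars: {sorted(names)}")
    per_season = {
        r.season: Season.from_label(r.season).day_index(r.break_date) for r in recs
    }
    return BreakEstimate(
        cultivar=recs[0].cultivar,
        method="biomarker",
        per_season_days=per_season,
        mean_day=mean_break_day(list(per_season.values())),
    )
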