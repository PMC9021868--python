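"""Chilling and heat requirements from break dates plus weather.

The chilling requirement (CR) of a cultivar is the chill accumulated from
the model-specific start of accumulation to the endodormancy-break date;
the heat requirement (HR) is the growing-degree-hour total from the break
date to full bloom (F50).  Per-cultivar summaries use the sample standard
deviation and the coefficient of variation (cv = 100·SD/mean) as the
within-years quality indicator, and requirements are binned into the
standard high/medium/low classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .chill_heat import (
    compute_model,
    growing_degree_hours,
    utah_start_date,
)
from .records_io import Season, TemperatureSeries, season_slice

__all__ = [
    "ClassThresholds",
    "DEFAULT_THRESHOLDS",
    "Summary",
    "chilling_requirement",
    "heat_requirement",
    "summarize_cultivar",
    "classify_cr",
    "classify_hr",
    "monthday_in_season",
    "requirement_summary",
]


@dataclass(frozen=True)
class ClassThresholds:
    """Classification bands for chilling (CP) and heating (GDH) requirements.

    The printed integer bands leave real-valued gaps (e.g. medium chill
    56–65 vs high ≥ 66); bands are closed as half-open intervals at the
    upper printed bound, so e.g. medium chill is [56, 66) and the
    (3900, 3901) heat gap closes upward into medium.
    """

    cr_high: float = 66.0
    cr_medium: float = 56.0
    cr_low_medium: float = 50.0
    hr_high: float = 4101.0
    hr_low: float = 3900.0


DEFAULT_THRESHOLDS = ClassThresholds()


class Summary(NamedTuple):
    mean: float
    sd: float
    cv: float  # percent; NaN when the mean is zero


def chilling_requirement(
    weather: TemperatureSeries,
    season: Season,
    break_date,
    model: str,
) -> float:
    """Chill accumulated from the model's start rule to 24:00 of the break
    date.

    Start rules — dynamic: 1 Sep (season start); utah: restart at zero
    after the day of maximum negative effect; weinberger: the first
    sub-7.2 °C hour in autumn (hours before it contribute nothing, so no
    offset is needed).  A break date before the accumulation start returns
    0 with a warning.
    """
    break_date = pd.Timestamp(break_date).normalize()
    if not season.contains(break_date):
        raise ValueError(f"break date {break_date:%Y-%m-%d} outside {season.label}")
    sliced = season_slice(weather, season)
    acc = compute_model(sliced, model)
    value = acc.value_at_end_of_day(break_date)
    if model == "utah":
        restart = utah_start_date(acc)
        if break_date < restart:
            warnings.warn(
                f"break date {break_date:%Y-%m-%d} precedes the Utah "
                f"accumulation restart {restart:%Y-%m-%d}; returning 0",
                stacklevel=2,
            )
            return 0.0
        value -= acc.value_at_end_of_day(restart)
    if value < 0:
        warnings.warn("negative accumulation clamped to 0", stacklevel=2)
        return 0.0
    return float(value)


def heat_requirement(weather: TemperatureSeries, break_date, f50_date) -> float:
    """Growing degree hours over [break 00:00, F50 24:00)."""
    break_date = pd.Timestamp(break_date).normalize()
    f50_date = pd.Timestamp(f50_date).normalize()
    if f50_date < break_date:
        raise ValueError("F50 precedes the break date")
    window = weather.slice(break_date, f50_date + pd.Timedelta(hours=23))
    expected = int((f50_date - break_date).days + 1) * 24
    if len(window) != expected:
        raise ValueError("weather does not cover the break→bloom window")
    return growing_degree_hours(window).total


def summarize_cultivar(per_season_values: Sequence[float]) -> Summary:
    """Mean, sample SD (n − 1) and cv (%) of per-season values.

    A single season yields SD = 0 (flagged by cv = 0); a zero mean makes
    the cv undefined (NaN).
    """
    values = np.asarray(list(per_season_values), dtype=float)
    if len(values) == 0:
        raise ValueError("no values to summarize")
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if len(values) > 1 else 0.0
    cv = 100.0 * sd / mean if mean != 0 else float("nan")
    return Summary(mean, sd, cv)


def classify_cr(value: float, thresholds: ClassThresholds = DEFAULT_THRESHOLDS) -> str:
    """Chilling-requirement class (CP): high ≥ 66, medium [56, 66),
    low_medium [50, 56); values below 50 are flagged ``below_range``
    rather than silently binned."""
    if value < 0:
        raise ValueError("chilling requirement must be non-negative")
    if value >= thresholds.cr_high:
        return "high"
    if value >= thresholds.cr_medium:
        return "medium"
    if value >= thresholds.cr_low_medium:
        return "low_medium"
    return "below_range"


def classify_hr(value: float, thresholds: ClassThresholds = DEFAULT_THRESHOLDS) -> str:
    """Heating-requirement class (GDH): high ≥ 4101, medium (3900, 4101),
    low ≤ 3900."""
    if value < 0:
        raise ValueError("heating requirement must be non-negative")
    if value >= thresholds.hr_high:
        return "high"
    if value > thresholds.hr_low:
        return "medium"
    return "low"


def monthday_in_season(season: Season, monthday: tuple[int, int]) -> pd.Timestamp:
    """Place a (month, day) pair inside a season (Sep–Dec → first year,
    Jan–Apr → second year)."""
    month, day = monthday
    year = season.first_year if month >= 9 else season.first_year + 1
    return pd.Timestamp(year, month, day)


def requirement_summary(
    weather_by_season: Mapping[str, TemperatureSeries],
    break_by_season: Mapping[str, pd.Timestamp],
    f50_by_season: Mapping[str, pd.Timestamp],
    chill_models: Sequence[str] = ("dynamic", "utah", "weinberger"),
    thresholds: ClassThresholds = DEFAULT_THRESHOLDS,
) -> dict:
    """Per-cultivar CR (per chill model) and HR summaries.

    ``break_by_season`` holds one break date per season — for the
    statistical estimators (a single calendar date per cultivar) the same
    month-day is placed in every season, so the SD/cv reflect the
    between-season spread of accumulation to that fixed date.
    HR is computed only for seasons that also have an F50 record.
    """
    out: dict = {"cr": {}, "hr": None, "cr_class": {}, "hr_class": None}
    seasons = sorted(break_by_season)
    for model in chill_models:
        values = []
        for label in seasons:
            season = Season.from_label(label)
            values.append(
                chilling_requirement(
                    weather_by_season[label], season, break_by_season[label], model
                )
            )
        out["cr"][model] = summarize_cultivar(values)
    if "dynamic" in out["cr"]:
        out["cr_class"] = classify_cr(out["cr"]["dynamic"].mean, thresholds)
    hr_values = [
        heat_requirement(
            weather_by_season[label], break_by_season[label], f50_by_season[label]
        )
        for label in seasons
        if label in f50_by_season
    ]
    if hr_values:
        out["hr"] = summarize_cultivar(hr_values)
        out["hr_class"] = classify_hr(out["hr"].mean, thresholds)
    return out
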