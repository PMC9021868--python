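"""Reading, validation and calendar handling for weather and phenology records.

The record types here are the substrate of the whole pipeline:

* :class:`TemperatureSeries` — hourly air temperature from a weather station
  (or interpolated from daily minima/maxima);
* :class:`Season` — a dormancy season running from autumn (default 1 Sep) to
  spring (default 30 Apr), with the day-of-season index in which 1 Oct is
  day 1 and 30 Apr is day 212 (213 when the season contains 29 Feb);
* :class:`BloomRecord` — full bloom (F50, 50 % open flowers) per cultivar and
  season;
* :class:`BudWeightTrial` — paired field/forcing-chamber flower-bud weights
  from a weekly forcing test;
* :class:`BiomarkerDate` — an externally observed endodormancy-break date
  (e.g. onset of male meiosis detected as callose deposition).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TemperatureSeries",
    "Season",
    "BloomRecord",
    "BudWeightTrial",
    "BiomarkerDate",
    "read_temperature",
    "read_daily_temperature",
    "interpolate_hourly",
    "daily_mean",
    "season_slice",
    "read_blooms",
    "read_bud_weights",
    "read_biomarkers",
    "day_of_season_to_monthday",
]

TEMP_MIN_C = -50.0
TEMP_MAX_C = 60.0

_HOUR = pd.Timedelta(hours=1)


@dataclass
class TemperatureSeries:
    """Hourly air-temperature record.

    Timestamps are naive local standard time (no DST shifts) and must be
    strictly increasing.  Values are in °C and constrained to the
    physically plausible band [−50, 60].
    """

    timestamps: pd.DatetimeIndex
    temp_c: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        self.temp_c = np.asarray(self.temp_c, dtype=float)
        if len(self.timestamps) != len(self.temp_c):
            raise ValueError("timestamps and temp_c must have equal length")
        if len(self.timestamps) > 1 and not self.timestamps.is_monotonic_increasing:
            raise ValueError("timestamps must be increasing")
        if len(self.timestamps) != len(set(self.timestamps)):
            raise ValueError("duplicate timestamps")
        if np.any(np.isnan(self.temp_c)):
            raise ValueError("temp_c contains missing values")
        if np.any(self.temp_c < TEMP_MIN_C) or np.any(self.temp_c > TEMP_MAX_C):
            raise ValueError(
                f"temperature outside plausible band [{TEMP_MIN_C}, {TEMP_MAX_C}] °C"
            )

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def is_hourly(self) -> bool:
        """True when consecutive timestamps are exactly one hour apart."""
        if len(self) < 2:
            return True
        return bool((np.diff(self.timestamps.values) == np.timedelta64(1, "h")).all())

    def to_series(self) -> pd.Series:
        return pd.Series(self.temp_c, index=self.timestamps, name="temp_c")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"timestamp": self.timestamps, "temp_c": self.temp_c})

    def write_csv(self, path) -> None:
        """Write ``timestamp,temp_c`` CSV; values round-trip bit-exactly."""
        df = self.to_frame()
        df["timestamp"] = df["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
        df["temp_c"] = [repr(float(v)) for v in self.temp_c]
        df.to_csv(path, index=False)

    def slice(self, start: pd.Timestamp, end: pd.Timestamp) -> "TemperatureSeries":
        """Sub-series with start <= t <= end (end inclusive)."""
        mask = (self.timestamps >= start) & (self.timestamps <= end)
        return TemperatureSeries(self.timestamps[mask], self.temp_c[mask])


def read_temperature(path, fill_policy: str = "linear_fill_max6h") -> TemperatureSeries:
    """Read an hourly ``timestamp,temp_c`` CSV.

    Parameters
    ----------
    path
        CSV file with ISO-8601 hourly timestamps.
    fill_policy
        ``"error"`` — any missing hour raises; ``"linear_fill_max6h"`` —
        gaps of up to 6 consecutive missing hours are filled by linear
        interpolation, longer gaps raise.
    """
    if fill_policy not in ("error", "linear_fill_max6h"):
        raise ValueError(f"unknown fill policy: {fill_policy!r}")
    df = pd.read_csv(path, float_precision="round_trip")
    if not {"timestamp", "temp_c"} <= set(df.columns):
        raise ValueError("temperature CSV must have columns timestamp,temp_c")
    ts = pd.to_datetime(df["timestamp"], format="ISO8601")
    if not ts.is_monotonic_increasing or ts.duplicated().any():
        raise ValueError("timestamps must be strictly increasing")
    values = pd.to_numeric(df["temp_c"], errors="raise").to_numpy(dtype=float)
    s = pd.Series(values, index=pd.DatetimeIndex(ts)).dropna()
    if len(s) == 0:
        raise ValueError("empty temperature record")
    full = pd.date_range(s.index[0], s.index[-1], freq="h")
    if not s.index.isin(full).all():
        raise ValueError("timestamps must fall on whole hours")
    missing = full.difference(s.index)
    if len(missing) > 0:
        if fill_policy == "error":
            raise ValueError(f"{len(missing)} missing hourly values")
        # longest run of consecutive missing hours
        gap_run = _longest_missing_run(full.isin(s.index))
        if gap_run > 6:
            raise ValueError(
                f"gap of {gap_run} consecutive missing hours exceeds the "
                "6-hour linear-fill policy"
            )
        s = s.reindex(full).interpolate(method="time")
    return TemperatureSeries(s.index, s.to_numpy())


def _longest_missing_run(present: np.ndarray) -> int:
    run = best = 0
    for ok in present:
        run = 0 if ok else run + 1
        best = max(best, run)
    return best


def read_daily_temperature(path) -> pd.DataFrame:
    """Read a ``date,tmin_c,tmax_c`` daily CSV (for hourly interpolation)."""
    df = pd.read_csv(path)
    if not {"date", "tmin_c", "tmax_c"} <= set(df.columns):
        raise ValueError("daily CSV must have columns date,tmin_c,tmax_c")
    df["date"] = pd.to_datetime(df["date"])
    return df


def interpolate_hourly(
    dates,
    daily_min,
    daily_max,
    method: str = "sine_linear",
) -> TemperatureSeries:
    """Build an hourly series from daily minima and maxima.

    The ``sine_linear`` curve puts the daily minimum at 05:00 and the
    maximum at 14:00.  Between 05:00 and 14:00 the temperature follows a
    quarter-sine rise ``tmin + (tmax − tmin)·sin(π/2 · (h − 5)/9)``; from
    14:00 to 05:00 of the next day it decays linearly from today's maximum
    to tomorrow's minimum.  The first day's pre-dawn hours reuse the first
    day's own extremes, and the last day decays toward its own minimum.
    Each day's 24 values are clamped to [tmin, tmax] so the daily extremes
    of the output reproduce the inputs exactly.
    """
    if method != "sine_linear":
        raise ValueError(f"unknown interpolation method: {method!r}")
    tmin = np.asarray(daily_min, dtype=float)
    tmax = np.asarray(daily_max, dtype=float)
    dates = pd.DatetimeIndex(dates).normalize()
    if not (len(dates) == len(tmin) == len(tmax)):
        raise ValueError("dates, daily_min and daily_max must have equal length")
    if np.any(tmin > tmax):
        raise ValueError("daily minimum exceeds maximum")
    n = len(dates)
    prev_max = np.concatenate(([tmax[0]], tmax[:-1]))
    next_min = np.concatenate((tmin[1:], [tmin[-1]]))

    hours = np.arange(24)
    out = np.empty((n, 24))
    pre = hours < 5  # tail of the previous night's decay
    rise = (hours >= 5) & (hours <= 14)
    fall = hours > 14
    for i in range(n):
        out[i, pre] = prev_max[i] + (tmin[i] - prev_max[i]) * (hours[pre] + 10) / 15.0
        out[i, rise] = tmin[i] + (tmax[i] - tmin[i]) * np.sin(
            np.pi / 2.0 * (hours[rise] - 5) / 9.0
        )
        out[i, fall] = tmax[i] + (next_min[i] - tmax[i]) * (hours[fall] - 14) / 15.0
        np.clip(out[i], tmin[i], tmax[i], out=out[i])

    idx = pd.DatetimeIndex(
        np.repeat(dates.values, 24) + np.tile(hours, n) * np.timedelta64(1, "h")
    )
    return TemperatureSeries(idx, out.ravel())


def daily_mean(series: TemperatureSeries, strict: bool = False) -> pd.Series:
    """Mean temperature per calendar day (complete 24-hour days only).

    Partial days at the boundaries are dropped with a warning (or raise
    when ``strict``).
    """
    s = series.to_series()
    counts = s.groupby(s.index.normalize()).size()
    partial = counts[counts != 24]
    if len(partial) > 0:
        msg = f"{len(partial)} partial day(s) excluded from daily means"
        if strict:
            raise ValueError(msg)
        warnings.warn(msg, stacklevel=2)
    means = s.groupby(s.index.normalize()).mean()
    return means[counts == 24]


@dataclass(frozen=True)
class Season:
    """A dormancy season (default 1 Sep → 30 Apr of the following year).

    The day-of-season index counts from 1 Oct = day 1 to 30 Apr = day 212
    (213 when February of the second year has 29 days: the extra day gets
    its own index rather than being dropped).
    """

    label: str
    start: pd.Timestamp
    end: pd.Timestamp

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("season end must follow season start")

    @classmethod
    def from_label(
        cls,
        label: str,
        start_month: int = 9,
        start_day: int = 1,
        end_month: int = 4,
        end_day: int = 30,
    ) -> "Season":
        """Parse ``"2016-2017"`` (hyphen, en dash or slash separated)."""
        norm = label.replace("–", "-").replace("/", "-")
        parts = norm.split("-")
        if len(parts) != 2:
            raise ValueError(f"cannot parse season label {label!r}")
        y1, y2 = int(parts[0]), int(parts[1])
        if y2 < 100:  # "2016-17" shorthand
            y2 += y1 - y1 % 100
        if y2 != y1 + 1:
            raise ValueError(f"season {label!r} must span consecutive years")
        return cls(
            label=f"{y1}-{y2}",
            start=pd.Timestamp(y1, start_month, start_day),
            end=pd.Timestamp(y2, end_month, end_day),
        )

    @property
    def first_year(self) -> int:
        return self.start.year

    @property
    def index_origin(self) -> pd.Timestamp:
        """1 Oct of the first year — day-of-season 1."""
        return pd.Timestamp(self.first_year, 10, 1)

    @property
    def n_index_days(self) -> int:
        """212 in seasons with a 28-day February, 213 in leap seasons."""
        return self.day_index(self.end)

    def day_index(self, date) -> int:
        """Day-of-season index of ``date`` (1 Oct = 1 … 30 Apr = 212/213)."""
        return (pd.Timestamp(date).normalize() - self.index_origin).days + 1

    def date_of_index(self, day: int) -> pd.Timestamp:
        return self.index_origin + pd.Timedelta(days=day - 1)

    def contains(self, date) -> bool:
        d = pd.Timestamp(date).normalize()
        return self.start <= d <= self.end

    def hourly_range(self) -> pd.DatetimeIndex:
        """All hourly timestamps from start 00:00 through end 23:00."""
        return pd.date_range(self.start, self.end + pd.Timedelta(hours=23), freq="h")


def season_slice(series: TemperatureSeries, season: Season) -> TemperatureSeries:
    """Restrict an hourly series to one season (start 00:00 – end 23:00)."""
    last = season.end + pd.Timedelta(hours=23)
    if series.timestamps[0] > season.start or series.timestamps[-1] < last:
        raise ValueError(
            f"series does not cover season {season.label} "
            f"({season.start:%Y-%m-%d}..{season.end:%Y-%m-%d})"
        )
    return series.slice(season.start, last)


def day_of_season_to_monthday(day: int) -> tuple[int, int]:
    """Map a day-of-season index to (month, day) on the reference 28-day-
    February calendar (1 → 1 Oct, 212 → 30 Apr)."""
    if not 1 <= day <= 212:
        raise ValueError("day-of-season index must be in 1..212")
    d = pd.Timestamp(2001, 10, 1) + pd.Timedelta(days=day - 1)
    return d.month, d.day


@dataclass(frozen=True)
class BloomRecord:
    """Full bloom (F50, 50 % open flowers) of one cultivar in one season."""

    cultivar: str
    season: str
    f50_date: pd.Timestamp

    def __post_init__(self) -> None:
        object.__setattr__(self, "f50_date", pd.Timestamp(self.f50_date).normalize())
        season = Season.from_label(self.season)
        if not season.contains(self.f50_date):
            raise ValueError(
                f"F50 {self.f50_date:%Y-%m-%d} outside season {self.season}"
            )


def read_blooms(path) -> list[BloomRecord]:
    """Read a ``cultivar,season,f50_date`` CSV; one record per cultivar×season."""
    df = pd.read_csv(path)
    if not {"cultivar", "season", "f50_date"} <= set(df.columns):
        raise ValueError("bloom CSV must have columns cultivar,season,f50_date")
    if df.duplicated(["cultivar", "season"]).any():
        raise ValueError("duplicate cultivar × season bloom records")
    return [
        BloomRecord(r.cultivar, str(r.season), pd.Timestamp(r.f50_date))
        for r in df.itertuples()
    ]


@dataclass
class BudWeightTrial:
    """One weekly forcing-test sampling: bud weights in the field and after
    8 days in a warm growth chamber (n = 10 buds each)."""

    cultivar: str
    collection_date: pd.Timestamp
    field_weights: list[float] = field(default_factory=list)
    chamber_weights: list[float] = field(default_factory=list)
    chamber_days: int = 8

    def __post_init__(self) -> None:
        self.collection_date = pd.Timestamp(self.collection_date).normalize()
        if not self.field_weights or not self.chamber_weights:
            raise ValueError("both weight samples must be non-empty")
        if min(self.field_weights) <= 0 or min(self.chamber_weights) <= 0:
            raise ValueError("bud weights must be positive (mg)")

    @property
    def field_mean(self) -> float:
        return float(np.mean(self.field_weights))

    @property
    def chamber_mean(self) -> float:
        return float(np.mean(self.chamber_weights))

    @property
    def weight_ratio(self) -> float:
        """Mean chamber weight over mean field weight."""
        return self.chamber_mean / self.field_mean


def read_bud_weights(path) -> list[BudWeightTrial]:
    """Read a long-format ``cultivar,collection_date,context,weight_mg`` CSV
    (context is ``field`` or ``chamber``) into per-sampling trials."""
    df = pd.read_csv(path)
    need = {"cultivar", "collection_date", "context", "weight_mg"}
    if not need <= set(df.columns):
        raise ValueError(f"bud-weight CSV must have columns {sorted(need)}")
    bad = set(df["context"]) - {"field", "chamber"}
    if bad:
        raise ValueError(f"unknown context values: {sorted(bad)}")
    trials = []
    for (cultivar, date), grp in df.groupby(["cultivar", "collection_date"], sort=True):
        trials.append(
            BudWeightTrial(
                cultivar=cultivar,
                collection_date=pd.Timestamp(date),
                field_weights=grp.loc[grp.context == "field", "weight_mg"].tolist(),
                chamber_weights=grp.loc[grp.context == "chamber", "weight_mg"].tolist(),
            )
        )
    trials.sort(key=lambda t: (t.cultivar, t.collection_date))
    return trials


@dataclass(frozen=True)
class BiomarkerDate:
    """Externally observed endodormancy-break date for one cultivar ×
    season (e.g. first microscopic appearance of callose around the
    microspore mother cells at male-meiosis onset)."""

    cultivar: str
    season: str
    break_date: pd.Timestamp

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "break_date", pd.Timestamp(self.break_date).normalize()
        )
        if not Season.from_label(self.season).contains(self.break_date):
            raise ValueError(
                f"break date {self.break_date:%Y-%m-%d} outside season {self.season}"
            )


def read_biomarkers(path) -> list[BiomarkerDate]:
    """Read a ``cultivar,season,break_date`` CSV."""
    df = pd.read_csv(path)
    if not {"cultivar", "season", "break_date"} <= set(df.columns):
        raise ValueError("biomarker CSV must have columns cultivar,season,break_date")
    return [
        BiomarkerDate(r.cultivar, str(r.season), pd.Timestamp(r.break_date))
        for r in df.itertuples()
    ]
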