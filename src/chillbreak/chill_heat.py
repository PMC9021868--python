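"""Hourly chill and heat accumulation models.

Four accumulation models are implemented on hourly temperature series:

* **Dynamic model** (chill portions, CP) — a two-step process in which cold
  hours build an intermediate precursor that warm hours can degrade; once
  the precursor reaches a critical level it converts irreversibly into a
  chill portion, which can never be destroyed.
* **Utah model** (chill units, CU) — stepwise hourly weights, including
  negative weights for warm hours, so the running total can decrease.
* **Weinberger model** (chilling hours, CH) — one unit per hour strictly
  below 7.2 °C (45 °F).
* **Growing degree hours** (GDH) — capped linear heat accumulation above a
  4.5 °C base with a 25 °C optimum, used to time bloom after endodormancy
  release.

Each model also carries its own accumulation-start convention (see
:func:`utah_start_date` and :func:`weinberger_start_date`); the Dynamic
model starts on 1 Sep by convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import (
    DYNAMIC_PARAMS,
    GDH_BASE_C,
    GDH_CAP_C,
    UTAH_WEIGHTS,
    WEINBERGER_THRESHOLD_C,
    DynamicParams,
)
from .records_io import TemperatureSeries

__all__ = [
    "ChillSeries",
    "dynamic_chill_portions",
    "dynamic_portions_batch",
    "utah_chill_units",
    "utah_start_date",
    "weinberger_chill_hours",
    "weinberger_start_date",
    "growing_degree_hours",
    "MODELS",
]

#: model tag -> human unit
MODELS = {
    "dynamic": "CP",
    "utah": "CU",
    "weinberger": "CH",
    "gdh": "GDH",
}


@dataclass
class ChillSeries:
    """Cumulative chill (or heat) accumulation on an hourly grid."""

    model: str
    start_date: pd.Timestamp | None
    times: pd.DatetimeIndex
    contribution: np.ndarray
    cumulative: np.ndarray

    @property
    def total(self) -> float:
        return float(self.cumulative[-1]) if len(self.cumulative) else 0.0

    def value_at(self, when) -> float:
        """Accumulated value at the last hour <= ``when`` (0 before start)."""
        when = pd.Timestamp(when)
        pos = self.times.searchsorted(when, side="right") - 1
        return float(self.cumulative[pos]) if pos >= 0 else 0.0

    def value_at_end_of_day(self, date) -> float:
        """Accumulated value at 24:00 of ``date``."""
        day = pd.Timestamp(date).normalize()
        return self.value_at(day + pd.Timedelta(hours=23))

    def daily_increments(self) -> pd.Series:
        """Accumulation gained per calendar day (sum of hourly contributions)."""
        s = pd.Series(self.contribution, index=self.times)
        return s.groupby(s.index.normalize()).sum()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "timestamp": self.times,
                "contribution": self.contribution,
                "cumulative": self.cumulative,
            }
        )


def _require_hourly(series: TemperatureSeries) -> None:
    if not series.is_hourly:
        raise ValueError("accumulation models require contiguous hourly data")


def dynamic_portions_batch(
    temps_c: np.ndarray, params: DynamicParams = DYNAMIC_PARAMS
) -> np.ndarray:
    """Hourly chill-portion increments for a batch of temperature rows.

    ``temps_c`` has shape (n_series, n_hours); the recursion runs over
    hours, vectorised across rows.  Returns the per-hour portion
    increments (same shape).  The recursion: the precursor pool ``x``
    relaxes toward the temperature-dependent equilibrium ``xs`` with rate
    ``ak1``; whenever the relaxed pool reaches ``crit`` a fraction ``xi``
    (a sigmoid in temperature) converts to portions and leaves the pool.
    """
    temps_c = np.atleast_2d(np.asarray(temps_c, dtype=float))
    n_series, n_hours = temps_c.shape
    if n_hours == 0:
        return np.zeros((n_series, 0))
    tk = temps_c + params.kelvin_offset
    ftmprt = params.slp * params.tetmlt * (tk - params.tetmlt) / tk
    sr = np.exp(ftmprt)
    xi = sr / (1.0 + sr)
    xs = (params.a0 / params.a1) * np.exp((params.e1 - params.e0) / tk)
    ak1 = params.a1 * np.exp(-params.e1 / tk)
    decay = np.exp(-ak1)

    delta = np.zeros_like(temps_c)
    pool = np.zeros(n_series)
    for h in range(n_hours):
        inter_e = xs[:, h] - (xs[:, h] - pool) * decay[:, h]
        conv = np.where(inter_e >= params.crit, xi[:, h] * inter_e, 0.0)
        delta[:, h] = conv
        pool = inter_e - conv
    return delta


def dynamic_chill_portions(
    series: TemperatureSeries,
    params: DynamicParams = DYNAMIC_PARAMS,
    start_date: pd.Timestamp | None = None,
) -> ChillSeries:
    """Cumulative Dynamic-model chill portions over an hourly series.

    Portions are irreversible: the cumulative series is non-decreasing even
    though warm spells deplete the intermediate precursor pool.
    """
    _require_hourly(series)
    delta = dynamic_portions_batch(series.temp_c[np.newaxis, :], params)[0]
    start = series.timestamps[0] if len(series) else start_date
    return ChillSeries(
        model="dynamic",
        start_date=start,
        times=series.timestamps,
        contribution=delta,
        cumulative=np.cumsum(delta),
    )


def _utah_weight(temps_c: np.ndarray) -> np.ndarray:
    w = np.zeros_like(temps_c, dtype=float)
    for lo, hi, weight in UTAH_WEIGHTS:
        if weight != 0.0:
            w[(temps_c > lo) & (temps_c <= hi)] = weight
    return w


def utah_chill_units(series: TemperatureSeries) -> ChillSeries:
    """Cumulative Utah-model chill units (stepwise hourly weights).

    Full weight is earned between 2.4 and 9.1 °C, half weight on the
    1.4–2.4 and 9.1–12.4 °C shoulders, nothing between 12.4 and 15.9 °C,
    and warm hours above 15.9 °C subtract chill (−0.5, then −1 above
    18 °C), so the running total may decrease.
    """
    _require_hourly(series)
    w = _utah_weight(series.temp_c)
    start = series.timestamps[0] if len(series) else None
    return ChillSeries("utah", start, series.timestamps, w, np.cumsum(w))


def utah_start_date(series: ChillSeries) -> pd.Timestamp:
    """Utah accumulation start: the day of maximum negative effect.

    Scans the running cumulative CU at the end of each day and returns the
    day at which it attains its minimum (ties broken by the latest such
    day); accumulation toward the chilling requirement restarts from zero
    on the following hour.  If the running total never goes negative the
    series start day is returned.
    """
    if series.model != "utah":
        raise ValueError("utah_start_date expects a Utah chill-unit series")
    if len(series.times) == 0:
        raise ValueError("empty series")
    end_of_day = pd.Series(series.cumulative, index=series.times)
    daily = end_of_day.groupby(end_of_day.index.normalize()).last()
    if (series.cumulative >= 0).all():
        return series.times[0].normalize()
    minimum = daily.min()
    return daily.index[daily.to_numpy() == minimum][-1]


def weinberger_chill_hours(series: TemperatureSeries) -> ChillSeries:
    """Cumulative Weinberger chilling hours: +1 per hour strictly below
    7.2 °C (45 °F)."""
    _require_hourly(series)
    w = (series.temp_c < WEINBERGER_THRESHOLD_C).astype(float)
    start = series.timestamps[0] if len(series) else None
    return ChillSeries("weinberger", start, series.timestamps, w, np.cumsum(w))


def weinberger_start_date(series: ChillSeries) -> pd.Timestamp:
    """First qualifying (sub-7.2 °C) hour in autumn — the Weinberger
    accumulation start."""
    if series.model != "weinberger":
        raise ValueError("weinberger_start_date expects a chilling-hour series")
    idx = np.nonzero(series.contribution > 0)[0]
    if len(idx) == 0:
        raise ValueError("no hour below the chilling threshold in series")
    return series.times[idx[0]]


def growing_degree_hours(series: TemperatureSeries) -> ChillSeries:
    """Cumulative growing degree hours: max(0, min(T, 25) − 4.5) per hour."""
    _require_hourly(series)
    contrib = np.maximum(0.0, np.minimum(series.temp_c, GDH_CAP_C) - GDH_BASE_C)
    start = series.timestamps[0] if len(series) else None
    return ChillSeries("gdh", start, series.timestamps, contrib, np.cumsum(contrib))


def compute_model(series: TemperatureSeries, model: str) -> ChillSeries:
    """Dispatch on the model tag (``dynamic``/``utah``/``weinberger``/``gdh``)."""
    if model == "dynamic":
        return dynamic_chill_portions(series)
    if model == "utah":
        return utah_chill_units(series)
    if model == "weinberger":
        return weinberger_chill_hours(series)
    if model == "gdh":
        return growing_degree_hours(series)
    raise ValueError(f"unknown model {model!r} (expected one of {sorted(MODELS)})")
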