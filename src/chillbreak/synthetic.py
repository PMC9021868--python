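"""Synthetic multi-year weather and phenology with known ground truth.

Emulates the data layout of a long-term orchard/weather-station study:
hourly temperature per dormancy season (seasonal sinusoid + per-season
mean shift + diurnal cycle + AR(1) noise), full-bloom dates produced by a
sequential chill-then-heat model (Dynamic chill portions to a chilling
requirement CR*, then growing degree hours to a heat requirement HR*),
weekly forcing-test bud-weight trials, and jittered biomarker break dates.

Because the true break date of every season is known, every estimator in
the package can be scored against ground truth; see
:func:`recovery_experiment`.

All generators are seed-deterministic.  Random streams are derived from
``(seed, cultivar_index, season_index, stream)`` so that adding cultivars
or seasons never perturbs previously generated ones.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .break_estimators import (
    correlation_break_date,
    correlation_profile,
    pls_day_profile,
    pls_phase_delineation,
)
from .chill_heat import dynamic_portions_batch
from .constants import DYNAMIC_PARAMS, GDH_BASE_C, GDH_CAP_C
from .records_io import (
    BiomarkerDate,
    BloomRecord,
    BudWeightTrial,
    Season,
    TemperatureSeries,
)

__all__ = [
    "SyntheticConfig",
    "gen_weather",
    "gen_bloom_records",
    "gen_bud_weight_trials",
    "gen_biomarker_dates",
    "simulate_cultivar",
    "recovery_experiment",
    "recovery_rates",
]

# stream codes for derived RNGs
_W, _B, _F, _M = 0, 1, 2, 3


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings.

    The climate defaults emulate a mild-winter fruit-growing region
    (winter daily means ~8–12 °C, diurnal half-range 4 °C, AR(1)
    day-to-day anomalies) in which chill accumulation remains
    temperature-limited through the whole chilling phase — the regime the
    statistical break-detection methods assume — while still accumulating
    a seasonal total of ~100–115 chill portions so that chilling
    requirements up to ~85 CP are attainable.  The generator is a
    statistical emulator, not a physical weather model, and is
    deliberately not calibrated to any particular station record.  The
    phenology defaults (CR* = 55 chill portions, HR* = 4000 GDH) sit in
    the middle of the range reported for apricot.
    """

    n_seasons: int = 20
    seed: int = 0
    first_year: int = 2000
    annual_mean_c: float = 14.5
    annual_amplitude_c: float = 6.5
    coldest_monthday: tuple[int, int] = (1, 15)
    diurnal_amplitude_c: float = 4.0
    ar1_coef: float = 0.8
    ar1_innovation_sd_c: float = 1.5
    interannual_sd_c: float = 0.7
    cr_star: float = 55.0
    hr_star: float = 4000.0
    bloom_noise_days: float = 2.0
    biomarker_jitter_days: float = 2.0
    bud_weight_mg: float = 30.0
    bud_weight_sd_mg: float = 2.0
    ratio_dormant: float = 1.10
    ratio_released: float = 1.45
    ratio_noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if not 0 <= self.ar1_coef < 1:
            raise ValueError("AR(1) coefficient must be in [0, 1)")
        if min(self.annual_amplitude_c, self.diurnal_amplitude_c) < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.cr_star < 0 or self.hr_star < 0:
            raise ValueError("CR* and HR* must be non-negative")


def _rng(config: SyntheticConfig, cultivar_index: int, *keys: int):
    return np.random.default_rng([config.seed, cultivar_index, *keys])


def _season_labels(config: SyntheticConfig) -> list[str]:
    return [
        f"{config.first_year + s}-{config.first_year + s + 1}"
        for s in range(config.n_seasons)
    ]


def _gen_season_temps(
    config: SyntheticConfig, cultivar_index: int, season_index: int
) -> tuple[Season, pd.DatetimeIndex, np.ndarray]:
    season = Season.from_label(_season_labels(config)[season_index])
    times = season.hourly_range()
    rng = _rng(config, cultivar_index, season_index, _W)

    cold = pd.Timestamp(season.first_year + 1, *config.coldest_monthday)
    days_from_cold = ((times - cold) / pd.Timedelta(days=1)).to_numpy()
    seasonal = config.annual_mean_c - config.annual_amplitude_c * np.cos(
        2.0 * np.pi * days_from_cold / 365.25
    )
    diurnal = -config.diurnal_amplitude_c * np.cos(
        2.0 * np.pi * (times.hour.to_numpy() - 14) / 24.0
    )
    shift = rng.normal(0.0, config.interannual_sd_c)

    # synoptic variability: AR(1) daily-mean anomalies (day-to-day
    # persistence phi), held constant over each day's 24 hours
    phi, sd = config.ar1_coef, config.ar1_innovation_sd_c
    n_days = len(times) // 24
    if sd > 0:
        eta = rng.normal(0.0, sd, size=n_days)
        x0 = rng.normal(0.0, sd / np.sqrt(1.0 - phi**2))  # stationary start
        daily_anom, _ = lfilter([1.0], [1.0, -phi], eta, zi=np.array([phi * x0]))
        noise = np.repeat(daily_anom, 24)
    else:
        noise = np.zeros(len(times))
    temps = np.clip(seasonal + diurnal + shift + noise, -50.0, 60.0)
    return season, times, temps


def gen_weather(
    config: SyntheticConfig, cultivar_index: int = 0
) -> dict[str, TemperatureSeries]:
    """Hourly temperature per season (1 Sep 00:00 – 30 Apr 23:00)."""
    out = {}
    for s in range(config.n_seasons):
        season, times, temps = _gen_season_temps(config, cultivar_index, s)
        out[season.label] = TemperatureSeries(times, temps)
    return out


# ---------------------------------------------------------------------------
# ground-truth phenology


def _gdh_contrib(temps: np.ndarray) -> np.ndarray:
    return np.maximum(0.0, np.minimum(temps, GDH_CAP_C) - GDH_BASE_C)


def _cp_deltas(temp_arrays: Sequence[np.ndarray]) -> list[np.ndarray]:
    """Dynamic-model hourly portion increments, batched by series length."""
    out: list = [None] * len(temp_arrays)
    by_len: dict[int, list[int]] = {}
    for i, t in enumerate(temp_arrays):
        by_len.setdefault(len(t), []).append(i)
    for _, idxs in sorted(by_len.items()):
        batch = dynamic_portions_batch(
            np.stack([temp_arrays[i] for i in idxs]), DYNAMIC_PARAMS
        )
        for j, i in enumerate(idxs):
            out[i] = batch[j]
    return out


def _season_truth(
    cp_delta: np.ndarray, gdh: np.ndarray, cr_star: float, hr_star: float
) -> tuple[int, int] | None:
    """(break day, F50 day) as 0-based day offsets from season start, or
    None when CR*/HR* are not reached within the season."""
    cum_cp = np.cumsum(cp_delta)
    if len(cum_cp) == 0 or cum_cp[-1] < cr_star:
        return None
    break_hour = int(np.searchsorted(cum_cp, cr_star))
    break_day = break_hour // 24
    tail = gdh[break_day * 24 :]
    n_days = len(tail) // 24
    eod = np.cumsum(tail)[np.arange(n_days) * 24 + 23]
    if len(eod) == 0 or eod[-1] < hr_star:
        return None
    f50_day = break_day + int(np.searchsorted(eod, hr_star))
    return break_day, f50_day


def gen_bloom_records(
    weather_by_season: Mapping[str, TemperatureSeries],
    config: SyntheticConfig,
    cultivar: str = "SYN-001",
    cultivar_index: int = 0,
) -> tuple[list[BloomRecord], dict[str, dict]]:
    """Bloom records from the sequential chill-then-heat model.

    Per season: the true break date is the day the Dynamic chill-portion
    total (from 1 Sep) reaches CR*; F50 is the first day afterwards whose
    growing-degree-hour total from the break reaches HR*, plus rounded
    Gaussian observation noise.  Seasons in which CR* or HR* is never
    reached are flagged ``no_bloom`` in the returned truth and produce no
    record.
    """
    records: list[BloomRecord] = []
    truth: dict[str, dict] = {}
    for s, (label, series) in enumerate(sorted(weather_by_season.items())):
        season = Season.from_label(label)
        deltas = _cp_deltas([series.temp_c])[0]
        res = _season_truth(
            deltas, _gdh_contrib(series.temp_c), config.cr_star, config.hr_star
        )
        if res is None:
            truth[label] = {"no_bloom": True}
            continue
        break_day, f50_day = res
        rng = _rng(config, cultivar_index, s, _B)
        jitter = int(np.rint(rng.normal(0.0, config.bloom_noise_days)))
        obs_day = int(
            np.clip(f50_day + jitter, break_day, (season.end - season.start).days)
        )
        break_date = season.start + pd.Timedelta(days=break_day)
        truth[label] = {
            "no_bloom": False,
            "break_date": break_date,
            "f50_date": season.start + pd.Timedelta(days=f50_day),
        }
        records.append(
            BloomRecord(cultivar, label, season.start + pd.Timedelta(days=obs_day))
        )
    return records, truth


def gen_bud_weight_trials(
    truth_break: Mapping[str, pd.Timestamp],
    config: SyntheticConfig,
    cultivar: str = "SYN-001",
    cultivar_index: int = 0,
    n_buds: int = 10,
) -> dict[str, list[BudWeightTrial]]:
    """Weekly forcing-test trials per season (samplings 1 Nov – 31 Mar).

    The chamber/field weight ratio is drawn around ``ratio_dormant``
    before the true break and around ``ratio_released`` at or after it, so
    the forcing criterion (≥ 30 % gain) recovers the truth to within the
    weekly sampling resolution.
    """
    trials: dict[str, list[BudWeightTrial]] = {}
    for s, (label, break_date) in enumerate(sorted(truth_break.items())):
        season = Season.from_label(label)
        rng = _rng(config, cultivar_index, s, _F)
        season_trials = []
        date = pd.Timestamp(season.first_year, 11, 1)
        last = pd.Timestamp(season.first_year + 1, 3, 31)
        while date <= last:
            ratio_mu = (
                config.ratio_released
                if date >= break_date
                else config.ratio_dormant
            )
            ratio = ratio_mu + rng.normal(0.0, config.ratio_noise_sd)
            field = rng.normal(config.bud_weight_mg, config.bud_weight_sd_mg, n_buds)
            field = np.maximum(field, 0.1)
            chamber = np.maximum(field.mean() * ratio + rng.normal(
                0.0, config.bud_weight_sd_mg, n_buds
            ), 0.1)
            season_trials.append(
                BudWeightTrial(cultivar, date, field.tolist(), chamber.tolist())
            )
            date += pd.Timedelta(days=7)
        trials[label] = season_trials
    return trials


def gen_biomarker_dates(
    truth_break: Mapping[str, pd.Timestamp],
    config: SyntheticConfig,
    cultivar: str = "SYN-001",
    cultivar_index: int = 0,
) -> list[BiomarkerDate]:
    """Observed biomarker break dates: truth plus rounded Gaussian jitter."""
    out = []
    for s, (label, break_date) in enumerate(sorted(truth_break.items())):
        season = Season.from_label(label)
        rng = _rng(config, cultivar_index, s, _M)
        jitter = int(np.rint(rng.normal(0.0, config.biomarker_jitter_days)))
        date = break_date + pd.Timedelta(days=jitter)
        date = min(max(date, season.start), season.end)
        out.append(BiomarkerDate(cultivar, label, date))
    return out


def simulate_cultivar(
    config: SyntheticConfig, cultivar: str = "SYN-001", cultivar_index: int = 0
) -> dict:
    """Generate the full record set for one cultivar."""
    weather = gen_weather(config, cultivar_index)
    blooms, truth = gen_bloom_records(weather, config, cultivar, cultivar_index)
    breaks = {
        label: info["break_date"]
        for label, info in truth.items()
        if not info["no_bloom"]
    }
    return {
        "weather": weather,
        "blooms": blooms,
        "truth": truth,
        "bud_weight_trials": gen_bud_weight_trials(
            breaks, config, cultivar, cultivar_index
        ),
        "biomarkers": gen_biomarker_dates(breaks, config, cultivar, cultivar_index),
    }


# ---------------------------------------------------------------------------
# end-to-end parameter recovery


def recovery_experiment(
    n_cultivars: int = 100,
    n_seasons: int = 20,
    seed: int = 0,
    cr_range: tuple[float, float] = (45.0, 85.0),
    hr_range: tuple[float, float] = (3500.0, 5500.0),
    base_config: SyntheticConfig | None = None,
) -> pd.DataFrame:
    """Score the statistical break estimators against synthetic truth.

    For each simulated cultivar (CR* uniform in ``cr_range`` chill
    portions, HR* uniform in ``hr_range`` GDH), generates ``n_seasons`` of
    weather and bloom records, runs the correlation and PLS estimators,
    and reports the estimated break day-of-season and the implied chilling
    requirement (mean Dynamic-model accumulation to the estimated date)
    next to the truth.
    """
    cfg0 = base_config or SyntheticConfig(n_seasons=n_seasons, seed=seed)
    cfg0 = replace(cfg0, n_seasons=n_seasons, seed=seed)
    draw = np.random.default_rng([seed, 2**20])  # cultivar-level parameter draws
    rows = []
    for c in range(n_cultivars):
        cr_star = float(draw.uniform(*cr_range))
        hr_star = float(draw.uniform(*hr_range))
        cfg = replace(cfg0, cr_star=cr_star, hr_star=hr_star)

        labels, temp_arrays = [], []
        for s in range(cfg.n_seasons):
            season, _, temps = _gen_season_temps(cfg, c, s)
            labels.append(season.label)
            temp_arrays.append(temps)
        cp = _cp_deltas(temp_arrays)
        cp_cum = [np.cumsum(d) for d in cp]

        truth_days, bloom_days = {}, {}
        for s, label in enumerate(labels):
            res = _season_truth(cp[s], _gdh_contrib(temp_arrays[s]), cr_star, hr_star)
            if res is None:
                continue
            break_day, f50_day = res
            rng = _rng(cfg, c, s, _B)
            jitter = int(np.rint(rng.normal(0.0, cfg.bloom_noise_days)))
            n_days = len(temp_arrays[s]) // 24
            obs = int(np.clip(f50_day + jitter, break_day, n_days - 1))
            truth_days[label] = break_day - 29  # day-of-season (1 Oct = 1)
            bloom_days[label] = obs - 29
        if len(truth_days) < 3:
            continue
        y = pd.Series(bloom_days, dtype=float)
        truth_mean = float(np.mean(list(truth_days.values())))

        def mean_cr(day_of_season: int) -> float:
            hour = (day_of_season + 29) * 24 + 23
            return float(np.mean([cum[hour] for cum in cp_cum]))

        # correlation estimator: daily means on the 1..212 grid
        daily = {
            label: temp_arrays[s][: (len(temp_arrays[s]) // 24) * 24]
            .reshape(-1, 24)
            .mean(axis=1)[30:242]
            for s, label in enumerate(labels)
            if label in bloom_days
        }
        day_matrix = pd.DataFrame.from_dict(
            daily, orient="index", columns=np.arange(1, 213)
        )
        profile = correlation_profile(day_matrix, y)
        corr = correlation_break_date(profile)

        # PLS estimator: daily CP and GDH increments on the −29..212 grid
        grid = np.arange(-29, 213)
        chill_daily = {
            label: cp[s][: 242 * 24].reshape(-1, 24).sum(axis=1)
            for s, label in enumerate(labels)
            if label in bloom_days
        }
        heat_daily = {
            label: _gdh_contrib(temp_arrays[s][: 242 * 24])
            .reshape(-1, 24)
            .sum(axis=1)
            for s, label in enumerate(labels)
            if label in bloom_days
        }
        chill_p = pls_day_profile(
            pd.DataFrame.from_dict(chill_daily, orient="index", columns=grid), y
        )
        heat_p = pls_day_profile(
            pd.DataFrame.from_dict(heat_daily, orient="index", columns=grid), y
        )
        phases = pls_phase_delineation(chill_p, heat_p, latest_day=int(y.min()))

        rows.append(
            {
                "cultivar": f"SYN-{c:03d}",
                "cr_star": cr_star,
                "hr_star": hr_star,
                "n_bloom_seasons": len(bloom_days),
                "truth_mean_break_day": truth_mean,
                "corr_break_day": corr.break_day,
                "corr_cr": mean_cr(corr.break_day) if corr.determined else np.nan,
                "pls_break_day": phases.break_day,
                "pls_cr": mean_cr(phases.break_day) if phases.determined else np.nan,
            }
        )
    df = pd.DataFrame(rows)
    for m in ("corr", "pls"):
        df[f"{m}_day_err"] = df[f"{m}_break_day"] - df["truth_mean_break_day"]
        df[f"{m}_cr_err"] = df[f"{m}_cr"] - df["cr_star"]
    return df


def recovery_rates(
    df: pd.DataFrame, day_tol: float = 10.0, cr_tol: float = 8.0
) -> dict[str, float]:
    """Fraction of cultivars recovered within tolerance, per estimator."""
    out = {}
    for m in ("corr", "pls"):
        ok = (df[f"{m}_day_err"].abs() <= day_tol) & (
            df[f"{m}_cr_err"].abs() <= cr_tol
        )
        out[m] = float(ok.mean())
    return out
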