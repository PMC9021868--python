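import numpy as np
import pandas as pd
import pytest

from chillbreak.records_io import (
    BloomRecord,
    BudWeightTrial,
    Season,
    TemperatureSeries,
    daily_mean,
    day_of_season_to_monthday,
    interpolate_hourly,
    read_blooms,
    read_bud_weights,
    read_temperature,
    season_slice,
)

from conftest import constant_series, hourly


def _write_weather(path, index, values):
    pd.DataFrame(
        {"timestamp": index.strftime("%Y-%m-%dT%H:%M:%S"), "temp_c": values}
    ).to_csv(path, index=False)


class TestReadTemperature:
    def test_identity_read(self, tmp_path):
        idx = pd.date_range("2016-11-01", periods=3, freq="h")
        p = tmp_path / "w.csv"
        _write_weather(p, idx, [5.0, 6.0, 7.0])
        s = read_temperature(p)
        assert len(s) == 3
        assert list(s.temp_c) == [5.0, 6.0, 7.0]

    def test_two_hour_gap_filled_with_linear_midpoints(self, tmp_path):
        idx = pd.date_range("2016-11-01", periods=6, freq="h")
        keep = [0, 1, 4, 5]  # hours 2 and 3 missing
        p = tmp_path / "w.csv"
        _write_weather(p, idx[keep], [0.0, 3.0, 12.0, 9.0])
        s = read_temperature(p, fill_policy="linear_fill_max6h")
        assert len(s) == 6
        assert s.temp_c[2] == pytest.approx(6.0)
        assert s.temp_c[3] == pytest.approx(9.0)

    def test_long_gap_rejected(self, tmp_path):
        idx = pd.date_range("2016-11-01", periods=30, freq="h")
        keep = list(range(3)) + list(range(27, 30))  # 24-hour hole
        p = tmp_path / "w.csv"
        _write_weather(p, idx[keep], np.linspace(0, 5, 6))
        with pytest.raises(ValueError, match="gap"):
            read_temperature(p, fill_policy="linear_fill_max6h")
        with pytest.raises(ValueError):
            read_temperature(p, fill_policy="error")

    def test_non_monotone_timestamps_rejected(self, tmp_path):
        p = tmp_path / "w.csv"
        pd.DataFrame(
            {
                "timestamp": ["2016-11-01T02:00:00", "2016-11-01T01:00:00"],
                "temp_c": [5.0, 5.0],
            }
        ).to_csv(p, index=False)
        with pytest.raises(ValueError, match="increasing"):
            read_temperature(p)

    def test_round_trip_is_bit_exact(self, tmp_path):
        rng = np.random.default_rng(0)
        s = hourly(rng.uniform(-10, 30, 100))
        p = tmp_path / "w.csv"
        s.write_csv(p)
        back = read_temperature(p)
        assert np.array_equal(back.temp_c, s.temp_c)
        assert (back.timestamps == s.timestamps).all()

    def test_implausible_temperature_rejected(self):
        with pytest.raises(ValueError, match="plausible"):
            constant_series(80.0, 3)


class TestInterpolateHourly:
    def test_constant_day_is_constant(self):
        s = interpolate_hourly(["2016-11-01"], [10.0], [10.0])
        assert len(s) == 24
        assert np.allclose(s.temp_c, 10.0)

    def test_daily_extremes_preserved(self):
        rng = np.random.default_rng(1)
        n = 10
        tmin = rng.uniform(-5, 5, n)
        tmax = tmin + rng.uniform(0, 15, n)
        dates = pd.date_range("2016-11-01", periods=n, freq="D")
        s = interpolate_hourly(dates, tmin, tmax)
        by_day = s.to_series().groupby(s.timestamps.normalize())
        assert np.allclose(by_day.min().to_numpy(), tmin, atol=0.1)
        assert np.allclose(by_day.max().to_numpy(), tmax, atol=0.1)

    def test_documented_curve_on_two_day_ramp(self):
        # rise segment is a quarter sine between 05:00 and 14:00
        s = interpolate_hourly(
            pd.date_range("2016-11-01", periods=2, freq="D"), [0.0, 5.0], [10.0, 15.0]
        )
        for h in range(5, 15):
            expected = 0.0 + 10.0 * np.sin(np.pi / 2 * (h - 5) / 9)
            assert s.temp_c[h] == pytest.approx(expected)
        # decay segment: linear from day-1 max toward day-2 min
        for h in range(15, 24):
            expected = 10.0 + (5.0 - 10.0) * (h - 14) / 15.0
            assert s.temp_c[h] == pytest.approx(expected)

    def test_min_above_max_rejected(self):
        with pytest.raises(ValueError):
            interpolate_hourly(["2016-11-01"], [10.0], [5.0])

    def test_daily_mean_of_constant_interpolation(self):
        dates = pd.date_range("2016-11-01", periods=4, freq="D")
        s = interpolate_hourly(dates, [7.0] * 4, [7.0] * 4)
        assert np.allclose(daily_mean(s).to_numpy(), 7.0)


class TestDailyMean:
    def test_constant_and_split_days(self):
        s = constant_series(5.0, 24, start="2016-11-01 00:00")
        assert daily_mean(s).iloc[0] == 5.0
        s2 = hourly([0.0] * 12 + [10.0] * 12, start="2016-11-01 00:00")
        assert daily_mean(s2).iloc[0] == 5.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(2)
        vals = rng.uniform(-5, 25, 48)
        s = hourly(vals, start="2016-11-01 00:00")
        means = daily_mean(s)
        assert means.iloc[0] == pytest.approx(sum(vals[:24]) / 24)
        assert means.iloc[1] == pytest.approx(sum(vals[24:]) / 24)

    def test_partial_day_excluded_with_warning(self):
        s = hourly(np.arange(30.0), start="2016-11-01 00:00")  # 24 + 6 hours
        with pytest.warns(UserWarning, match="partial"):
            means = daily_mean(s)
        assert len(means) == 1


class TestSeason:
    def test_day_index_anchors(self):
        season = Season.from_label("2016-2017")
        assert season.day_index(pd.Timestamp("2016-10-01")) == 1
        assert season.day_index(pd.Timestamp("2017-04-30")) == 212
        assert season.n_index_days == 212

    def test_leap_february_gets_own_index(self):
        season = Season.from_label("2019-2020")
        assert season.day_index(pd.Timestamp("2020-04-30")) == 213
        assert season.day_index(pd.Timestamp("2020-02-29")) == 152

    def test_index_date_bijection(self):
        for label in ("2016-2017", "2019-2020"):
            season = Season.from_label(label)
            for d in range(1, season.n_index_days + 1):
                assert season.day_index(season.date_of_index(d)) == d

    @pytest.mark.parametrize("label", ["2016-2017", "2016–2017", "2016/2017", "2016-17"])
    def test_label_variants(self, label):
        assert Season.from_label(label).label == "2016-2017"

    def test_non_consecutive_years_rejected(self):
        with pytest.raises(ValueError):
            Season.from_label("2016-2019")

    def test_season_slice_and_coverage(self):
        idx = pd.date_range("2016-08-01", "2017-05-31 23:00", freq="h")
        s = TemperatureSeries(idx, np.zeros(len(idx)))
        season = Season.from_label("2016-2017")
        sliced = season_slice(s, season)
        assert sliced.timestamps[0] == pd.Timestamp("2016-09-01 00:00")
        assert sliced.timestamps[-1] == pd.Timestamp("2017-04-30 23:00")
        short = TemperatureSeries(idx[: 24 * 30], np.zeros(24 * 30))
        with pytest.raises(ValueError, match="cover"):
            season_slice(short, season)

    def test_monthday_mapping_endpoints(self):
        assert day_of_season_to_monthday(1) == (10, 1)
        assert day_of_season_to_monthday(212) == (4, 30)


class TestPhenologyRecords:
    def test_bloom_outside_season_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            BloomRecord("X", "2016-2017", pd.Timestamp("2017-06-10"))

    def test_read_blooms_rejects_duplicates(self, tmp_path):
        p = tmp_path / "b.csv"
        pd.DataFrame(
            {
                "cultivar": ["X", "X"],
                "season": ["2016-2017", "2016-2017"],
                "f50_date": ["2017-03-10", "2017-03-11"],
            }
        ).to_csv(p, index=False)
        with pytest.raises(ValueError, match="duplicate"):
            read_blooms(p)

    def test_bud_weight_long_format_grouping(self, tmp_path):
        rows = []
        for date in ("2016-12-05", "2016-12-12"):
            for ctx in ("field", "chamber"):
                for w in (10.0, 11.0, 12.0):
                    rows.append(
                        {"cultivar": "X", "collection_date": date,
                         "context": ctx, "weight_mg": w}
                    )
        p = tmp_path / "bw.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        trials = read_bud_weights(p)
        assert len(trials) == 2
        assert all(len(t.field_weights) == 3 for t in trials)
        assert trials[0].collection_date < trials[1].collection_date

    def test_bud_weights_must_be_positive(self):
        with pytest.raises(ValueError, match="positive"):
            BudWeightTrial("X", "2016-12-05", [10.0, -1.0], [12.0])
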