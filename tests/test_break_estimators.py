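import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chillbreak.break_estimators import (
    CorrelationProfile,
    PLSDayProfile,
    biomarker_break_dates,
    bloom_day_series,
    correlation_break_date,
    correlation_profile,
    critical_pcc,
    forcing_break_date,
    mean_break_day,
    pls_phase_delineation,
    season_day_matrix,
)
from chillbreak.records_io import BiomarkerDate, BloomRecord, BudWeightTrial

from _oracles import pearson_oracle


class TestCriticalPcc:
    def test_thirteen_years_threshold(self):
        assert round(critical_pcc(13, 0.05), 3) == 0.553

    def test_three_years_closed_form(self):
        t = 12.706204736432095  # t(0.975, df=1)
        assert critical_pcc(3, 0.05) == pytest.approx(t / np.sqrt(t**2 + 1))

    def test_threshold_vanishes_as_alpha_approaches_one(self):
        assert critical_pcc(13, 0.999) < 0.001

    def test_strictly_decreasing_in_years(self):
        values = [critical_pcc(n, 0.05) for n in range(3, 40)]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_matches_t_r_identity(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(3, 50))
            alpha = float(rng.uniform(0.001, 0.5))
            r = critical_pcc(n, alpha)
            df = n - 2
            t = np.sqrt(df * r**2 / (1 - r**2))
            assert t == pytest.approx(stats.t.ppf(1 - alpha / 2, df), rel=1e-9)

    def test_too_few_years_rejected(self):
        with pytest.raises(ValueError):
            critical_pcc(2)


def _random_day_matrix(rng, n_seasons=15, n_days=60):
    labels = [f"{2000 + i}-{2001 + i}" for i in range(n_seasons)]
    return pd.DataFrame(
        rng.normal(10, 3, (n_seasons, n_days)),
        index=labels,
        columns=np.arange(1, n_days + 1),
    )


class TestCorrelationProfile:
    def test_constant_bloom_flagged_with_zero_profile(self):
        rng = np.random.default_rng(1)
        X = _random_day_matrix(rng)
        y = pd.Series(150.0, index=X.index)
        prof = correlation_profile(X, y)
        assert prof.constant_bloom
        assert np.allclose(prof.pcc, 0.0)
        result = correlation_break_date(prof)
        assert not result.determined

    def test_perfect_linear_window_dependence(self):
        rng = np.random.default_rng(2)
        X = _random_day_matrix(rng, n_days=80)
        window_mean = X.loc[:, 33:47].mean(axis=1)  # window centred on day 40
        y = 100 + 2.0 * window_mean
        prof = correlation_profile(X, y)
        assert prof.pcc[39] == pytest.approx(1.0)

    def test_matches_sigma_formula_oracle(self):
        rng = np.random.default_rng(3)
        X = _random_day_matrix(rng, n_seasons=12, n_days=40)
        y = pd.Series(rng.normal(150, 8, 12), index=X.index)
        prof = correlation_profile(X, y, window_days=15)
        windowed = X.T.rolling(15, center=True, min_periods=8).mean().T
        for j, day in enumerate(X.columns):
            expected = pearson_oracle(windowed[day].tolist(), y.tolist())
            assert prof.pcc[j] == pytest.approx(expected, abs=1e-9)

    def test_invariant_to_bloom_shift_and_antisymmetric_to_negation(self):
        rng = np.random.default_rng(4)
        X = _random_day_matrix(rng)
        y = pd.Series(rng.normal(150, 8, len(X)), index=X.index)
        base = correlation_profile(X, y).pcc
        shifted = correlation_profile(X, y + 17).pcc
        negated = correlation_profile(X, -y).pcc
        assert np.allclose(base, shifted, atol=1e-12)
        assert np.allclose(base, -negated, atol=1e-12)

    def test_missing_bloom_seasons_dropped_with_warning(self):
        rng = np.random.default_rng(5)
        X = _random_day_matrix(rng)
        y = pd.Series(rng.normal(150, 8, len(X) - 2), index=X.index[:-2])
        with pytest.warns(UserWarning, match="dropped"):
            prof = correlation_profile(X, y)
        assert prof.n_seasons == len(X) - 2

    def test_even_window_rejected(self):
        rng = np.random.default_rng(6)
        X = _random_day_matrix(rng)
        y = pd.Series(rng.normal(150, 8, len(X)), index=X.index)
        with pytest.raises(ValueError, match="odd"):
            correlation_profile(X, y, window_days=14)


def _profile_from_pcc(pcc, crit=0.5):
    pcc = np.asarray(pcc, dtype=float)
    return CorrelationProfile(np.arange(1, len(pcc) + 1), pcc, crit, 13, 15)


class TestCorrelationBreakDate:
    def test_midpoint_of_transition(self):
        pcc = np.concatenate([np.full(40, 0.9), np.zeros(19), np.full(41, -0.9)])
        result = correlation_break_date(_profile_from_pcc(pcc))
        assert (result.last_positive_day, result.first_negative_day) == (40, 60)
        assert result.break_day == 50

    def test_half_day_midpoint_rounds_up(self):
        pcc = np.concatenate([np.full(40, 0.9), np.zeros(20), np.full(40, -0.9)])
        result = correlation_break_date(_profile_from_pcc(pcc))
        assert (result.last_positive_day, result.first_negative_day) == (40, 61)
        assert result.break_day == 51

    def test_no_positive_day_is_undetermined(self):
        result = correlation_break_date(_profile_from_pcc(np.full(100, -0.9)))
        assert not result.determined and "positive" in result.reason

    def test_no_negative_after_last_positive_is_undetermined(self):
        pcc = np.concatenate([np.full(50, -0.9), np.full(50, 0.9)])
        result = correlation_break_date(_profile_from_pcc(pcc))
        assert not result.determined and result.last_positive_day == 100


def _pls_profile(days, sig_days):
    days = np.asarray(days)
    coef = np.where(np.isin(days, sig_days), -1.0, 0.5)
    vip = np.where(np.isin(days, sig_days), 1.2, 0.2)
    return PLSDayProfile(days, coef, vip, model=None)


class TestPlsPhaseDelineation:
    def test_constructed_chilling_phase(self):
        days = np.arange(1, 213)
        chill = _pls_profile(days, np.arange(10, 101))
        phases = pls_phase_delineation(chill)
        assert phases.chilling_phase == (10, 100)
        assert phases.break_day == 100

    def test_transition_gap_arithmetic(self):
        days = np.arange(1, 213)
        chill = _pls_profile(days, np.arange(10, 101))
        heat = _pls_profile(days, np.arange(110, 161))
        phases = pls_phase_delineation(chill, heat)
        assert phases.forcing_phase == (110, 160)
        assert phases.transition_days == 9

    def test_small_gaps_merged_within_phase(self):
        days = np.arange(1, 213)
        sig = np.concatenate([np.arange(10, 41), np.arange(45, 91)])  # 4-day hole
        phases = pls_phase_delineation(_pls_profile(days, sig), gap_tolerance=5)
        assert phases.chilling_phase == (10, 90)
        phases_strict = pls_phase_delineation(_pls_profile(days, sig), gap_tolerance=2)
        assert phases_strict.chilling_phase == (45, 90)

    def test_no_qualifying_run_is_undetermined(self):
        days = np.arange(1, 213)
        phases = pls_phase_delineation(_pls_profile(days, []))
        assert not phases.determined

    def test_post_bloom_runs_excluded(self):
        days = np.arange(1, 213)
        sig = np.concatenate([np.arange(10, 61), np.arange(140, 213)])
        unrestricted = pls_phase_delineation(_pls_profile(days, sig))
        assert unrestricted.chilling_phase == (140, 212)
        phases = pls_phase_delineation(_pls_profile(days, sig), latest_day=130)
        assert phases.chilling_phase == (10, 60)


class TestForcingBreakDate:
    def _trial(self, date, field_mean, chamber_mean):
        return BudWeightTrial(
            "X", date, [field_mean] * 10, [chamber_mean] * 10
        )

    def test_thirty_percent_criterion(self):
        trials = [
            self._trial("2016-12-05", 10.0, 11.0),
            self._trial("2016-12-12", 10.0, 12.9),  # 29 % — not met
            self._trial("2016-12-19", 10.0, 13.1),  # 31 % — met
        ]
        assert forcing_break_date(trials) == pd.Timestamp("2016-12-19")

    def test_boundary_is_inclusive(self):
        trials = [self._trial("2016-12-05", 10.0, 13.0)]
        assert forcing_break_date(trials) == pd.Timestamp("2016-12-05")

    def test_never_released_returns_none(self):
        trials = [self._trial("2016-12-05", 10.0, 12.0)]
        assert forcing_break_date(trials) is None

    def test_trials_are_ordered_before_search(self):
        trials = [
            self._trial("2016-12-19", 10.0, 14.0),
            self._trial("2016-12-05", 10.0, 14.0),
        ]
        assert forcing_break_date(trials) == pd.Timestamp("2016-12-05")


class TestBiomarkerBreakDates:
    def test_single_season_pass_through(self):
        est = biomarker_break_dates(
            [BiomarkerDate("X", "2016-2017", "2017-01-20")]
        )
        assert est.per_season_dates["2016-2017"] == pd.Timestamp("2017-01-20")
        assert est.mean_monthday == (1, 20)

    def test_two_season_date_averaging(self):
        est = biomarker_break_dates(
            [
                BiomarkerDate("X", "2016-2017", "2017-01-12"),
                BiomarkerDate("X", "2017-2018", "2018-01-30"),
            ]
        )
        assert est.mean_monthday == (1, 21)

    def test_many_seasons_match_ordinal_mean(self):
        rng = np.random.default_rng(7)
        records = []
        days = []
        for i in range(8):
            label = f"{2010 + i}-{2011 + i}"
            day = int(rng.integers(90, 140))
            days.append(day)
            date = pd.Timestamp(f"{2010 + i}-10-01") + pd.Timedelta(days=day - 1)
            records.append(BiomarkerDate("X", label, date))
        est = biomarker_break_dates(records)
        assert est.mean_day == int(np.floor(np.mean(days) + 0.5))

    def test_mixed_cultivars_rejected(self):
        with pytest.raises(ValueError, match="multiple"):
            biomarker_break_dates(
                [
                    BiomarkerDate("X", "2016-2017", "2017-01-12"),
                    BiomarkerDate("Y", "2016-2017", "2017-01-30"),
                ]
            )

    def test_mean_break_day_rounds_half_up(self):
        assert mean_break_day([100, 101]) == 101
        assert mean_break_day([100, 102]) == 101


class TestSeasonAlignment:
    def test_day_matrix_and_bloom_days_from_synthetic(self, small_sim):
        cfg, sim = small_sim
        matrix = season_day_matrix(sim["weather"])
        assert matrix.shape[1] == 212
        assert not matrix.isna().any().any()
        blooms = bloom_day_series(sim["blooms"], sim["blooms"][0].cultivar)
        assert len(blooms) == len(sim["blooms"])
        assert (blooms > 100).all()  # F50 falls after early January
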