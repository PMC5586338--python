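import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from pollenlag import (GddSeries, attach_gdd_covariate, cumulative_gdd,
                       daily_average, gdd_anomaly, long_term_mean_gdd,
                       simulate_temperatures, TemperatureSimParams,
                       thermal_fit, time_lag, fit_clm)
from pollenlag.ordinal import ClmSpec
from pollenlag.survey import PhenologySurvey, day_from_may1


def _weather(tavgs, station="X", year=2015, start="-01-01"):
    dates = pd.date_range(f"{year}{start}", periods=len(tavgs), freq="D")
    t = np.asarray(tavgs, float)
    return pd.DataFrame({"station": station, "date": dates,
                         "tmax": t + 1.0, "tmin": t - 1.0, "tavg": t})


class TestDailyAverage:
    def test_midpoint(self):
        assert daily_average(10, 4) == 7.0

    def test_degenerate_equal(self):
        assert daily_average(5.5, 5.5) == 5.5

    def test_swapped_inputs_error_not_silent_fix(self):
        with pytest.raises(ValueError, match="swapped"):
            daily_average(4, 10)

    def test_vectorised(self):
        out = daily_average([10, 8], [4, 2])
        np.testing.assert_allclose(out, [7, 5])


class TestCumulativeGdd:
    def test_strict_exceedance_at_base(self):
        series = cumulative_gdd(_weather([3.0, 5.5, 5.0]))[0]
        assert series.values.iloc[-1] == 0.0

    def test_excess_convention_hand_computed(self):
        series = cumulative_gdd(_weather([6.5, 5.5, 10.5]))[0]
        np.testing.assert_allclose(series.values.to_numpy(), [1.0, 1.0, 6.0])

    def test_full_convention_hand_computed(self):
        series = cumulative_gdd(_weather([6.5, 5.5, 10.5]), convention="full")[0]
        np.testing.assert_allclose(series.values.to_numpy(), [6.5, 6.5, 17.0])

    def test_uniform_warming_adds_n_degree_days(self):
        t = np.full(30, 10.0)
        g0 = cumulative_gdd(_weather(t))[0].values.iloc[-1]
        g1 = cumulative_gdd(_weather(t + 1.0))[0].values.iloc[-1]
        assert g1 - g0 == pytest.approx(30.0)

    def test_nondecreasing_and_monotone_in_temperature(self):
        rng = np.random.default_rng(0)
        t = rng.normal(6.0, 4.0, 60)
        g = cumulative_gdd(_weather(t))[0].values.to_numpy()
        assert (np.diff(g) >= 0).all()
        warmer = cumulative_gdd(_weather(t + rng.uniform(0, 2, 60)))[0]
        assert (warmer.values.to_numpy() >= g).all()

    def test_gap_error_names_missing_dates(self):
        w = _weather(np.full(40, 8.0))
        w = w[w["date"] != "2015-02-05"]
        with pytest.raises(ValueError, match="2015-02-05"):
            cumulative_gdd(w)

    def test_must_start_january_first(self):
        w = _weather(np.full(10, 8.0), start="-02-01")
        with pytest.raises(ValueError, match="Jan 1"):
            cumulative_gdd(w)


class TestAnomaly:
    def test_self_anomaly_zero(self):
        s = cumulative_gdd(_weather(np.full(20, 9.0)))[0]
        assert (gdd_anomaly(s, s) == 0).all()

    def test_antisymmetry(self):
        a = cumulative_gdd(_weather(np.arange(20, dtype=float)))[0]
        b = cumulative_gdd(_weather(np.full(20, 9.0)))[0]
        np.testing.assert_allclose(gdd_anomaly(a, b).to_numpy(),
                                   -gdd_anomaly(b, a).to_numpy())

    def test_station_mismatch_rejected(self):
        a = cumulative_gdd(_weather(np.full(5, 9.0), station="A"))[0]
        b = cumulative_gdd(_weather(np.full(5, 9.0), station="B"))[0]
        with pytest.raises(ValueError, match="station"):
            gdd_anomaly(a, b)

    def test_warm_anomaly_year_positive_and_growing(self):
        params = TemperatureSimParams(stations=("X",), years=(2014, 2015),
                                      noise_sd=0.0,
                                      year_anomaly={("X", 2015): 2.0}, seed=0)
        series = cumulative_gdd(simulate_temperatures(params))
        ref = long_term_mean_gdd([s for s in series if s.year == 2014], "X")
        warm = [s for s in series if s.year == 2015][0]
        anom = gdd_anomaly(warm, ref)
        assert anom.iloc[-1] > 0
        assert (np.diff(anom.to_numpy()) >= -1e-9).all()


class TestAttachCovariate:
    @pytest.fixture()
    def survey3(self):
        dates = pd.to_datetime(["2015-05-10", "2015-05-20"])
        rows = []
        for site in ["A", "B", "C"]:
            for tree in [1, 2]:
                for d in dates:
                    rows.append({"site": site, "tree": tree, "year": 2015,
                                 "date": d, "replicate": 1, "score": 3})
        df = pd.DataFrame(rows)
        df["day"] = day_from_may1(df["date"], df["year"])
        return PhenologySurvey(df)

    @pytest.fixture()
    def gdd3(self):
        t = np.full(181, 10.0)
        w = pd.concat([_weather(t, station="SA"), _weather(t, station="SB")])
        return cumulative_gdd(w)

    def test_all_mapped_sites_gain_gdd(self, survey3, gdd3):
        out = attach_gdd_covariate(survey3, gdd3,
                                   {"A": "SA", "B": "SB", "C": "SA"})
        assert "gdd" in out.data.columns
        assert out.data["gdd"].notna().all()

    def test_excluded_site_absent_from_design(self, survey3, gdd3):
        out = attach_gdd_covariate(survey3, gdd3, {"A": "SA", "B": "SB"},
                                   exclude={"C"})
        assert "C" not in set(out.data["site"])

    def test_sites_sharing_station_share_gdd(self, survey3, gdd3):
        out = attach_gdd_covariate(survey3, gdd3,
                                   {"A": "SA", "B": "SA", "C": "SA"})
        by_date = out.data.groupby(["date", "site"])["gdd"].first().unstack()
        assert (by_date.nunique(axis=1) == 1).all()

    def test_unmapped_site_rejected(self, survey3, gdd3):
        with pytest.raises(KeyError, match="station mapping"):
            attach_gdd_covariate(survey3, gdd3, {"A": "SA"})


def test_thermal_model_reverses_calendar_lags_under_shared_gdd_requirement():
    """If development at every site is triggered by the same thermal-time
    requirement and sites differ only in temperature, calendar-day lags are
    large but GDD-scale lags vanish."""
    rng = np.random.default_rng(99)
    temps = TemperatureSimParams(stations=("W", "C"), years=(2015,),
                                 noise_sd=0.0,
                                 station_offsets={"W": 2.5, "C": 0.0}, seed=1)
    weather = simulate_temperatures(temps)
    gdd = cumulative_gdd(weather)
    lookup = {s.station: s for s in gdd}

    # stage crossings at these cumulative GDD values (same at both sites)
    crossings = np.array([240.0, 280.0, 315.0, 345.0, 380.0, 420.0])
    beta_g = 0.05  # logit units per degree-day
    theta = beta_g * crossings
    rows = []
    for site, station in [("W", "W"), ("C", "C")]:
        g = lookup[station]
        for tree in range(1, 16):
            for day in range(1, 62, 10):
                date = pd.Timestamp(2015, 5, 1) + pd.Timedelta(days=day - 1)
                eta = beta_g * g.at(date)
                cum = expit(theta - eta)
                for rep in range(1, 6):
                    u = rng.random()
                    score = 1 + int((u > cum).sum())
                    rows.append({"site": site, "tree": tree, "year": 2015,
                                 "date": date, "day": day, "replicate": rep,
                                 "score": score})
    survey = PhenologySurvey(pd.DataFrame(rows))

    res_day = fit_clm(survey, ClmSpec(time_term="day"))
    lag_day = time_lag(res_day, "C", "W")
    res_gdd = thermal_fit(survey, gdd, {"W": "W", "C": "C"})
    beta_gdd_hat = res_gdd.beta_time
    lag_gdd_units = (res_gdd.factor_coef("site", "W")
                     - res_gdd.factor_coef("site", "C")) / beta_gdd_hat
    # warmer site is many days ahead on the calendar ...
    assert abs(lag_day) > 5
    # ... but on the thermal-time scale the sites nearly coincide
    # (tolerance in degree-days; ~40 GDD corresponds to a couple of days)
    assert abs(lag_gdd_units) < 15
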