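"""Generator tests: calendar, weather process, advisories, storms, effort."""

from dataclasses import asdict, replace

import numpy as np
import pandas as pd
import pytest

import creelweather as cw
from creelweather.synth import (CATEGORY_MIX, WeatherProcessParams,
                                derive_advisory_counts, derive_storm_warnings,
                                make_calendar, sample_storm_catalog,
                                simulate_daily_weather, simulate_effort,
                                split_weekly_effort, week_month_label)


class TestCalendar:
    def test_seven_study_years_give_364_weeks(self):
        cal = make_calendar(2015, 2021)
        assert len(cal) == 364
        assert (cal.groupby("year").size() == 52).all()

    def test_single_year_weeks_are_monday_start_seven_day_spans(self):
        cal = make_calendar(2015, 2015)
        assert len(cal) == 52
        assert (cal["monday"].dt.weekday == 0).all()
        deltas = cal["monday"].diff().dropna().dt.days
        assert (deltas == 7).all()

    def test_month_label_follows_majority_of_days(self):
        # Mon 2021-03-29 spans Mar 29-31 (3 days) and Apr 1-4 (4 days) -> April
        assert week_month_label(pd.Timestamp("2021-03-29").date()) == 4
        # fully interior week
        assert week_month_label(pd.Timestamp("2021-06-07").date()) == 6

    def test_invalid_year_range_rejected(self):
        with pytest.raises(ValueError):
            make_calendar(2021, 2015)


class TestDailyWeather:
    def test_noise_free_limit_is_exact_sinusoid(self):
        p = WeatherProcessParams(temp_noise_sd=0.0, temp_ar1=0.0)
        daily = simulate_daily_weather(p, "west", (2018, 2018), seed=0)
        doy = pd.to_datetime(daily["date"]).dt.dayofyear.to_numpy(dtype=float)
        expected = p.temp_mean_annual + p.temp_amplitude * np.cos(
            2 * np.pi * (doy - p.temp_peak_doy) / 365.25)
        np.testing.assert_allclose(daily["tmax"], expected, atol=1e-10)

    def test_zero_wet_probability_gives_dry_series(self):
        p = WeatherProcessParams(precip_wet_prob={
            "winter": 0.0, "spring": 0.0, "summer": 0.0, "fall": 0.0})
        daily = simulate_daily_weather(p, "east", (2018, 2018), seed=1)
        assert (daily["precip_total"] == 0).all()

    def test_fixed_seed_reproduces_bit_identical_tables(self):
        a = simulate_daily_weather(WeatherProcessParams(), "east", (2015, 2016), 9)
        b = simulate_daily_weather(WeatherProcessParams(), "east", (2015, 2016), 9)
        pd.testing.assert_frame_equal(a, b)

    def test_winter_weekly_temperature_variability_calibration(self):
        # Long simulation: January effort-weighted weekly tmax SD near 3.3 degC,
        # with summer variability roughly a third of that.
        p = WeatherProcessParams()
        daily = simulate_daily_weather(p, "west", (1980, 2039), seed=3)
        cal = make_calendar(1980, 2039)
        wx = cw.weekly_weather(daily, cal, cw.EffortWeights())
        jan = wx[wx["month"] == 1]["ew_tmax"].std(ddof=1)
        jun = wx[wx["month"] == 6]["ew_tmax"].std(ddof=1)
        assert jan == pytest.approx(3.3, abs=0.5)
        assert jun < 0.55 * jan

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            WeatherProcessParams(temp_ar1=1.0)
        with pytest.raises(ValueError):
            WeatherProcessParams(precip_gamma_scale=-1.0)


class TestAdvisories:
    @staticmethod
    def _daily(winds):
        dates = pd.date_range("2021-03-01", periods=7)  # a Monday-start week
        return pd.DataFrame({"date": dates, "region": "east",
                             "tmax": 20.0, "precip_total": 0.0,
                             "wind_max": winds})

    def test_calm_week_has_zero_count(self):
        out = derive_advisory_counts(self._daily([5.0] * 7), wind_threshold=10.8,
                                     zones_per_region=4)
        assert out["sca_count"].sum() == 0

    def test_three_exceedance_days_four_zones_gives_twelve(self):
        winds = [12.0, 3.0, 15.0, 3.0, 11.0, 3.0, 3.0]
        out = derive_advisory_counts(self._daily(winds), wind_threshold=10.8,
                                     zones_per_region=4)
        assert out["sca_count"].tolist() == [12]

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            derive_advisory_counts(self._daily([5.0] * 7), wind_threshold=0.0)

    def test_east_region_totals_on_the_order_of_thousands(self, dataset):
        east = dataset.advisories[dataset.advisories["region"] == "east"]
        assert 1000 <= east["sca_count"].sum() <= 10_000


class TestStormCatalog:
    def test_category_mix_matches_study(self):
        storms = sample_storm_catalog(seed=0)
        assert sorted(s.category for s in storms) == sorted(CATEGORY_MIX)
        assert len(storms) == 12

    def test_landfalls_sorted_in_season_and_spaced(self):
        storms = sample_storm_catalog(seed=1)
        dates = [s.landfall_date for s in storms]
        assert all(a < b for a, b in zip(dates, dates[1:]))
        assert all(6 <= d.month <= 11 for d in dates)
        assert all((b - a).days >= 42 for a, b in zip(dates, dates[1:]))

    def test_seeds_share_category_multiset_but_not_dates(self):
        a = sample_storm_catalog(seed=2)
        b = sample_storm_catalog(seed=3)
        assert sorted(s.category for s in a) == sorted(s.category for s in b)
        assert [s.landfall_date for s in a] != [s.landfall_date for s in b]


class TestSimulateEffort:
    @staticmethod
    def _zeroed_truth(**overrides):
        t = cw.TruthBundle.default()
        fields = asdict(t)
        fields["beta"] = np.zeros((12, 4))
        fields["sigma_resid"] = 0.0
        fields["pandemic_mult"] = np.ones(12)
        fields.update(overrides)
        return cw.TruthBundle(**fields)

    def test_deterministic_limit_is_constant_within_month(self):
        truth = self._zeroed_truth()
        ds = cw.simulate_dataset(11, truth=truth, storms=[])
        eff = ds.effort[ds.effort["region"] == "east"]
        for month, grp in eff.groupby("month"):
            np.testing.assert_allclose(grp["effort"],
                                       np.exp(truth.alpha[month - 1]), rtol=1e-9)

    def test_pandemic_multiplier_lifts_march_2020_by_75_percent(self):
        mult = np.ones(12)
        mult[2] = 1.75
        truth = self._zeroed_truth(pandemic_mult=mult)
        ds = cw.simulate_dataset(11, truth=truth, storms=[])
        eff = ds.effort[(ds.effort["region"] == "east") & (ds.effort["month"] == 3)]
        ratio = (eff[eff["year"] == 2020]["effort"].mean()
                 / eff[eff["year"] == 2019]["effort"].mean())
        assert ratio == pytest.approx(1.75, rel=1e-9)

    def test_storm_dip_recovers_monotonically(self):
        # With sigma_resid = 0 the log-effort difference between a run with the
        # storm and one without is exactly the disturbance: increasing in week.
        storms = [cw.StormEvent("TC01", "Alpha", pd.Timestamp("2017-08-17"),
                                category=4, impacted_region="east")]
        truth = self._zeroed_truth()
        fields = asdict(truth)
        fields["storm_dip"], fields["storm_recovery_per_cat"] = 0.35, 0.10
        truth = cw.TruthBundle(**fields)
        with_storm = cw.simulate_dataset(13, truth=truth, storms=storms)
        without = cw.simulate_dataset(13, truth=truth, storms=[])
        delta = (np.log(with_storm.effort.sort_values(["region", "monday"])["effort"].to_numpy())
                 - np.log(without.effort.sort_values(["region", "monday"])["effort"].to_numpy()))
        hit = np.flatnonzero(delta < -1e-12)
        assert len(hit) in (4, 5)  # last week may already be fully recovered
        assert np.all(np.diff(delta[hit]) > 0)
        assert delta[hit[0]] == pytest.approx(-0.35 * 5)

    def test_weekend_share_of_daily_split_is_weight_mass(self, dataset):
        daily = split_weekly_effort(dataset.effort.head(10), cw.EffortWeights())
        weekend = daily[daily["dow"] >= 4]["effort"].sum()
        assert weekend / daily["effort"].sum() == pytest.approx(0.70, abs=1e-12)

    def test_full_dataset_is_seed_deterministic(self):
        a = cw.simulate_dataset(5)
        b = cw.simulate_dataset(5)
        pd.testing.assert_frame_equal(a.effort, b.effort)
        pd.testing.assert_frame_equal(a.advisories, b.advisories)

    def test_misaligned_weather_rejected(self, dataset):
        with pytest.raises(ValueError):
            simulate_effort(dataset.calendar, dataset.weekly_weather.iloc[:-5],
                            dataset.advisories, [], dataset.truth)


class TestTruthBundle:
    def test_invalid_parameters_rejected(self):
        t = cw.TruthBundle.default()
        fields = asdict(t)
        fields["Sigma"] = -np.eye(4)
        with pytest.raises(ValueError):
            cw.TruthBundle(**fields)
        fields = asdict(t)
        fields["pandemic_mult"] = np.zeros(12)
        with pytest.raises(ValueError):
            cw.TruthBundle(**fields)

    def test_yaml_round_trip(self, tmp_path):
        t = cw.TruthBundle.default()
        t.to_yaml(tmp_path / "truth.yaml")
        back = cw.TruthBundle.from_yaml(tmp_path / "truth.yaml")
        np.testing.assert_allclose(back.beta, t.beta)
        assert back.gamma1 == t.gamma1


def test_storm_warnings_follow_edge_rule():
    # Landfall on a Tuesday -> the 36-hour lead puts warnings in the prior week.
    cal = make_calendar(2017, 2017)
    storm = cw.StormEvent("TC01", "Alpha", pd.Timestamp("2017-06-20"), 1, "east")
    assert storm.landfall_date.weekday() == 1
    warn = derive_storm_warnings(cal, [storm], seed=0)
    prior = storm.landfall_monday - pd.Timedelta(days=7)
    row = warn[(warn["region"] == "east") & (warn["monday"] == prior)].iloc[0]
    assert row["ts_warn_count"] > 0 and row["hu_warn_count"] > 0
    same = warn[(warn["region"] == "east")
                & (warn["monday"] == storm.landfall_monday)].iloc[0]
    assert same["ts_warn_count"] == 0
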