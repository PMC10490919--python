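"""Preparation-stage tests: summarization, weighting, filtering, standardization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import creelweather as cw
from creelweather import prep
from creelweather.synth import make_calendar


class TestDailyFromHourly:
    @staticmethod
    def _hourly(temps=None, precips=None, winds=None, hours=24):
        n = hours
        return pd.DataFrame({
            "hour": pd.date_range("2019-05-06", periods=n, freq="h"),
            "region": "east",
            "temp": temps if temps is not None else [20.0] * n,
            "precip": precips if precips is not None else [0.0] * n,
            "wind": winds if winds is not None else [0.0] * n,
        })

    def test_constant_day_summaries(self):
        out = prep.daily_from_hourly(self._hourly())
        assert out["tmax"].iloc[0] == 20.0

    def test_precip_totals_sum_hourly_values(self):
        out = prep.daily_from_hourly(self._hourly(precips=[0.5] * 24))
        assert out["precip_total"].iloc[0] == pytest.approx(12.0)

    def test_wind_max_picks_peak_hour(self):
        winds = [0.0] * 24
        winds[2], winds[9], winds[15] = 3.0, 9.0, 5.0
        out = prep.daily_from_hourly(self._hourly(winds=winds))
        assert out["wind_max"].iloc[0] == 9.0

    def test_partial_day_error_names_the_date(self):
        with pytest.raises(ValueError, match="2019-05-06"):
            prep.daily_from_hourly(self._hourly(hours=23))


class TestAggregateRegions:
    @staticmethod
    def _table(rows):
        return pd.DataFrame(rows, columns=["year", "week_index", "area", "effort"])

    def test_east_areas_sum(self):
        df = self._table([(2019, 1, "Pontchartrain", 10.0),
                          (2019, 1, "Barataria", 20.0),
                          (2019, 1, "Terrebonne/Timbalier", 30.0)])
        out = prep.aggregate_regions(df)
        assert out[out["region"] == "east"]["effort"].iloc[0] == 60.0

    def test_west_areas_sum(self):
        df = self._table([(2019, 1, "Vermilion/Teche", 5.0),
                          (2019, 1, "Calcasieu", 7.0)])
        out = prep.aggregate_regions(df)
        assert out[out["region"] == "west"]["effort"].iloc[0] == 12.0

    def test_offshore_rows_are_dropped(self):
        df = self._table([(2019, 1, "offshore", 99.0)])
        assert len(prep.aggregate_regions(df)) == 0

    def test_charter_rows_are_dropped(self):
        df = self._table([(2019, 1, "Calcasieu", 7.0),
                          (2019, 1, "Calcasieu", 3.0)])
        df["mode"] = ["private", "charter"]
        out = prep.aggregate_regions(df)
        assert out["effort"].iloc[0] == 7.0

    def test_unmapped_area_is_an_error(self):
        with pytest.raises(ValueError, match="Atchafalaya"):
            prep.aggregate_regions(self._table([(2019, 1, "Atchafalaya", 1.0)]))


class TestEffortWeightedWeek:
    def test_uniform_weights_reduce_to_mean(self):
        w = prep.EffortWeights(*([1 / 7] * 7))
        assert prep.effort_weighted_week([1, 2, 3, 4, 5, 6, 7], w) == pytest.approx(4.0)

    def test_point_mass_on_saturday(self):
        w = prep.EffortWeights(0, 0, 0, 0, 0, 1.0, 0)
        assert prep.effort_weighted_week([1, 2, 3, 4, 5, 6, 7], w) == 6.0

    def test_cold_saturday_outweighs_cold_tuesday(self):
        w = prep.EffortWeights()
        warm = [20.0] * 7
        cold_sat = warm.copy(); cold_sat[5] = 5.0
        cold_tue = warm.copy(); cold_tue[1] = 5.0
        assert (prep.effort_weighted_week(cold_sat, w)
                < prep.effort_weighted_week(cold_tue, w))

    def test_missing_day_is_an_error(self):
        with pytest.raises(ValueError):
            prep.effort_weighted_week([1, 2, 3], prep.EffortWeights())

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-50, 50), min_size=7, max_size=7))
    def test_uniform_weight_identity_property(self, values):
        w = prep.EffortWeights(*([1 / 7] * 7))
        assert prep.effort_weighted_week(values, w) == pytest.approx(
            np.mean(values), abs=1e-9)

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError):
            prep.EffortWeights(0.5, 0, 0, 0, 0, 0, 0)


class TestRealignWarningWeeks:
    @staticmethod
    def _advisories(cal, region="east"):
        adv = cal[["year", "week_index", "monday"]].copy()
        adv["region"] = region
        adv["sca_count"] = 0
        adv["ts_warn_count"] = 0
        adv["hu_warn_count"] = 0
        return adv

    def test_lead_week_warning_moves_to_landfall_week(self):
        cal = make_calendar(2018, 2018)
        storm = cw.StormEvent("TC01", "Alpha", pd.Timestamp("2018-07-17"), 0, "east")
        adv = self._advisories(cal)
        prior = storm.landfall_monday - pd.Timedelta(days=7)
        adv.loc[adv["monday"] == prior, "ts_warn_count"] = 9
        out = prep.realign_warning_weeks(adv, [storm])
        assert out[out["monday"] == prior]["ts_warn_count"].iloc[0] == 0
        assert out[out["monday"] == storm.landfall_monday]["ts_warn_count"].iloc[0] == 9

    def test_same_week_warning_unchanged(self):
        cal = make_calendar(2018, 2018)
        storm = cw.StormEvent("TC01", "Alpha", pd.Timestamp("2018-07-17"), 0, "east")
        adv = self._advisories(cal)
        adv.loc[adv["monday"] == storm.landfall_monday, "ts_warn_count"] = 4
        out = prep.realign_warning_weeks(adv, [storm])
        assert out[out["monday"] == storm.landfall_monday]["ts_warn_count"].iloc[0] == 4

    def test_no_storms_leaves_table_unchanged(self):
        cal = make_calendar(2018, 2018)
        adv = self._advisories(cal)
        adv.loc[10, "ts_warn_count"] = 3
        out = prep.realign_warning_weeks(adv, [])
        pd.testing.assert_frame_equal(
            out.reset_index(drop=True), adv.reset_index(drop=True))


class TestExclusionFilter:
    @staticmethod
    def _records(rows):
        df = pd.DataFrame(rows, columns=["region", "year", "week_index", "monday",
                                         "ts_warn_count", "hu_warn_count"])
        df["monday"] = pd.to_datetime(df["monday"])
        return df

    def test_holiday_warning_and_pandemic_weeks_removed(self):
        rows = [
            ("east", 2019, 27, "2019-07-01", 0, 0),   # contains July 4
            ("east", 2019, 40, "2019-09-30", 0, 0),   # plain week
            ("east", 2019, 33, "2019-08-12", 2, 0),   # warning week
            ("east", 2020, 10, "2020-03-02", 0, 0),   # pandemic year
        ]
        retained, audit = prep.exclusion_filter(self._records(rows))
        assert retained["week_index"].tolist() == [40]
        reasons = dict(zip(audit["week_index"], audit["reason"]))
        assert reasons[27] == "holiday_week"
        assert reasons[33] == "storm_warning"
        assert reasons[10] == "pandemic_year"

    def test_memorial_and_labor_day_rules(self):
        # 2015: Memorial Day = May 25 (last Monday of May), Labor Day = Sep 7
        assert prep.is_holiday_week(pd.Timestamp("2015-05-25"))
        assert prep.is_holiday_week(pd.Timestamp("2015-09-07"))
        assert not prep.is_holiday_week(pd.Timestamp("2015-05-18"))

    def test_filtering_only_removes_rows(self, weekly_records, retained_records):
        assert len(retained_records) < len(weekly_records)
        merged = retained_records.merge(
            weekly_records[["region", "year", "week_index"]],
            on=["region", "year", "week_index"], how="left", indicator=True)
        assert (merged["_merge"] == "both").all()


class TestStandardize:
    @staticmethod
    def _records(**cols):
        n = len(next(iter(cols.values())))
        base = {"effort": np.full(n, 100.0), "month": np.arange(n) % 12 + 1,
                "ew_precip": np.arange(n, dtype=float),
                "ew_tmax": np.arange(n, dtype=float) * 2,
                "ew_windmax": np.arange(n, dtype=float) + 5,
                "sca_count": np.arange(n) % 7}
        base.update(cols)
        return pd.DataFrame(base)

    def test_three_point_column_standardizes_to_unit_steps(self):
        rec = self._records(ew_precip=np.array([1.0, 2.0, 3.0]))
        design = prep.standardize(rec)
        np.testing.assert_allclose(design.frame["z_precip"], [-1, 0, 1])
        assert design.sds["ew_precip"] == pytest.approx(1.0)  # sample SD, ddof=1

    def test_idempotence_on_z_columns(self):
        rec = self._records(ew_precip=np.random.default_rng(0).normal(size=30))
        once = prep.standardize(rec)
        again_rec = rec.copy()
        for raw, z in zip(prep.PREDICTORS, prep.Z_COLUMNS):
            again_rec[raw] = once.frame[z]
        twice = prep.standardize(again_rec)
        np.testing.assert_allclose(twice.frame[list(prep.Z_COLUMNS)],
                                   once.frame[list(prep.Z_COLUMNS)], atol=1e-9)

    def test_constant_column_error_names_it(self):
        rec = self._records(ew_windmax=np.full(10, 3.0))
        with pytest.raises(ValueError, match="ew_windmax"):
            prep.standardize(rec)

    def test_z_columns_have_zero_mean_unit_sd(self, retained_records):
        design = prep.standardize(
            retained_records[retained_records["region"] == "west"], region="west")
        z = design.frame[list(prep.Z_COLUMNS)]
        np.testing.assert_allclose(z.mean(), 0.0, atol=1e-9)
        np.testing.assert_allclose(z.std(ddof=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(
            design.frame["log_effort"],
            np.log(retained_records[retained_records["region"] == "west"]
                   ["effort"]).to_numpy())


class TestCorrelationScreen:
    def test_known_correlations(self):
        n = 40
        rng = np.random.default_rng(1)
        x = rng.normal(size=n)
        rec = pd.DataFrame({"ew_precip": x, "ew_tmax": -x,
                            "ew_windmax": rng.normal(size=n),
                            "sca_count": rng.normal(size=n)})
        corr, max_abs, pair = prep.correlation_screen(rec)
        assert corr.loc["ew_precip", "ew_precip"] == pytest.approx(1.0)
        assert corr.loc["ew_precip", "ew_tmax"] == pytest.approx(-1.0)
        assert max_abs == pytest.approx(-1.0)
        assert set(pair) == {"ew_precip", "ew_tmax"}

    def test_exactly_linear_pair(self):
        rec = pd.DataFrame({"ew_precip": [1, 2, 3, 4, 5],
                            "ew_tmax": [2, 4, 6, 8, 10],
                            "ew_windmax": [3, 1, 4, 1, 5],
                            "sca_count": [0, 2, 1, 4, 3]})
        corr, _, _ = prep.correlation_screen(rec)
        assert corr.loc["ew_precip", "ew_tmax"] == pytest.approx(1.0)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            prep.correlation_screen(pd.DataFrame(
                {c: [1.0, 2.0] for c in prep.PREDICTORS}))


class TestDescriptives:
    def test_identical_values_have_zero_sd(self):
        rec = pd.DataFrame({"month": [1] * 5, "ew_tmax": [12.0] * 5})
        assert prep.monthly_sd(rec, "ew_tmax", 1) == 0.0

    def test_perfectly_linear_pair_has_unit_r2(self):
        rec = pd.DataFrame({"ew_tmax": [25.0, 26, 27, 28], "ew_windmax": [1.0, 2, 3, 4]})
        assert prep.conditional_r2(rec, "ew_tmax", "ew_windmax", "ew_tmax", 25.0) \
            == pytest.approx(1.0)

    def test_hand_computed_r2(self):
        rec = pd.DataFrame({"ew_tmax": [1.0, 2, 3], "ew_windmax": [2.0, 1, 3]})
        assert prep.conditional_r2(rec, "ew_tmax", "ew_windmax", "ew_tmax", 0.0) \
            == pytest.approx(0.25)

    def test_empty_subset_rejected(self):
        rec = pd.DataFrame({"ew_tmax": [1.0, 2, 3], "ew_windmax": [2.0, 1, 3]})
        with pytest.raises(ValueError):
            prep.conditional_r2(rec, "ew_tmax", "ew_windmax", "ew_tmax", 99.0)


def test_full_synthetic_prep_has_364_weeks_per_region(weekly_records):
    assert (weekly_records.groupby("region").size() == 364).all()
    assert not weekly_records.duplicated(["region", "year", "week_index"]).any()
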