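"""Range QC, midday/cloud filters, aggregation, gap reporting."""

from datetime import time

import numpy as np
import pandas as pd
import pytest

from phenosense import series_ops, synth
from phenosense.series_ops import FilterConfig, SensorSpec
from phenosense.types import PhenosenseError, empty_series_table, make_series_table

from conftest import series_equal


def one_day(channel="air_temp", node="n1", values=None, interval=15):
    times = pd.date_range("2021-05-01", periods=1440 // interval, freq=f"{interval}min")
    if values is None:
        values = np.full(len(times), 20.0)
    return make_series_table(times, node, channel, values)


class TestRangeCheck:
    def test_values_outside_datasheet_range_flagged(self):
        t = one_day("rel_hum", values=np.r_[np.full(95, 50.0), 120.0])
        res = series_ops.range_check(t)
        assert res.n_flagged == {"rel_hum": 1}
        flagged = res.table[res.table["flag"] == "out_of_range"]
        assert flagged["value"].tolist() == [120.0]

    def test_in_range_values_untouched(self):
        t = one_day("par_in", values=np.full(96, 2000.0))  # within 0-2500
        res = series_ops.range_check(t)
        assert res.n_flagged == {}
        assert (res.table["flag"] == "ok").all()
        assert res.table["value"].equals(t["value"])  # values never mutated

    def test_empty_table_passes_through(self):
        res = series_ops.range_check(empty_series_table())
        assert res.table.empty and res.n_flagged == {}

    def test_unknown_channel_skipped_with_warning(self):
        t = one_day("air_temp")
        with pytest.warns(UserWarning, match="air_temp"):
            series_ops.range_check(t, specs={"rel_hum": SensorSpec("rel_hum", 0, 100)})

    def test_bad_spec_rejected(self):
        with pytest.raises(PhenosenseError):
            SensorSpec("air_temp", 10.0, 10.0)


class TestWindowFilter:
    def test_midday_window_keeps_16_of_96(self):
        out = series_ops.window_filter(one_day())
        assert len(out) == 16  # 4 h of 15-min slots, half-open [10:00, 14:00)
        tod = out["timestamp"].dt.time
        assert tod.min() >= time(10, 0) and tod.max() < time(14, 0)

    def test_full_day_window_is_identity(self):
        t = one_day()
        cfg = FilterConfig(time_of_day_window=(time(0, 0), time(23, 59, 59)))
        assert len(series_ops.window_filter(t, cfg)) == len(t)

    def test_night_only_table_empties(self):
        times = pd.date_range("2021-05-01 00:00", periods=8, freq="15min")
        t = make_series_table(times, "n1", "air_temp", 15.0)
        assert series_ops.window_filter(t).empty


class TestCloudFilter:
    @staticmethod
    def paired(par_values):
        times = pd.date_range("2021-05-01 11:00", periods=len(par_values), freq="15min")
        par = make_series_table(times, "t00", "par_in", par_values)
        temp = make_series_table(times, "t00", "air_temp", 25.0)
        return pd.concat([par, temp], ignore_index=True)

    def test_exactly_900_is_dropped_strict_inequality(self):
        t = self.paired([900.0, 900.0001, 1200.0])
        out = series_ops.cloud_filter(t)
        kept_par = out[out["channel"] == "par_in"]["value"].tolist()
        assert kept_par == [900.0001, 1200.0]

    def test_records_without_par_partner_dropped_and_counted(self):
        t = self.paired([1000.0, 1000.0])
        orphan = make_series_table(["2021-05-01 23:00"], ["t00"], ["air_temp"], [18.0])
        counts = {}
        out = series_ops.cloud_filter(pd.concat([t, orphan], ignore_index=True),
                                      counts=counts)
        assert counts["dropped_no_partner"] == 1
        assert len(out) == 4

    def test_missing_par_channel_is_an_error(self):
        with pytest.raises(PhenosenseError, match="par_in"):
            series_ops.cloud_filter(one_day("air_temp"))

    def test_clear_synthetic_midday_retained_overcast_day_emptied(self, small_geom):
        cfg = synth.SynthConfig(random_seed=1, n_days=1)
        clear, _ = synth.make_deployment_series(small_geom, cfg)
        clear = series_ops.window_filter(clear)
        assert not series_ops.cloud_filter(clear).empty
        cfg2 = synth.SynthConfig(random_seed=1, n_days=1, cloudy_day_probability=1.0)
        overcast, _ = synth.make_deployment_series(small_geom, cfg2)
        overcast = series_ops.window_filter(overcast)
        assert series_ops.cloud_filter(overcast).empty

    def test_commutes_with_window_filter(self, clean_table):
        a = series_ops.cloud_filter(series_ops.window_filter(clean_table))
        b = series_ops.window_filter(series_ops.cloud_filter(clean_table))
        assert series_equal(a, b)


class TestAggregate:
    def test_constant_series_aggregates_to_constant(self):
        t = one_day(values=np.full(96, 21.5))
        for period in ("hourly", "daily"):
            out = series_ops.aggregate(t, period, "mean", 15)
            assert (out["value"] == 21.5).all()
            assert (out["flag"] == "ok").all()

    def test_daily_mean_of_sinusoid_matches_analytic_mean(self):
        # T(t) = 20 + 6 cos(2 pi (h - 15) / 24) integrates to 20 over a day,
        # and the 96-point uniform sample mean of a whole number of periods
        # of a cosine is exactly its analytic mean
        times = pd.date_range("2021-05-01", periods=96, freq="15min")
        h = times.hour + times.minute / 60
        t = make_series_table(times, "n1", "air_temp",
                              20 + 6 * np.cos(2 * np.pi * (h - 15) / 24))
        out = series_ops.aggregate(t, "daily", "mean", 15)
        assert out["value"].iloc[0] == pytest.approx(20.0, abs=1e-12)

    def test_undercovered_bucket_emitted_as_gap(self):
        t = one_day().head(48)  # half a day of samples
        out = series_ops.aggregate(t, "daily", "mean", 15, min_coverage=0.75)
        assert len(out) == 1
        assert out["flag"].iloc[0] == "gap" and np.isnan(out["value"].iloc[0])

    def test_bucket_counts_conserve_retained_records(self, clean_table):
        retained = clean_table[clean_table["value"].notna()]
        out = series_ops.aggregate(clean_table, "hourly", "count", 15,
                                   min_coverage=0.01)
        assert int(out["value"].sum()) == len(retained)

    def test_buckets_labeled_by_start(self):
        t = one_day()
        out = series_ops.aggregate(t, "hourly", "max", 15)
        assert (out["timestamp"].dt.minute == 0).all()
        assert out["timestamp"].iloc[0] == pd.Timestamp("2021-05-01 00:00")

    def test_monthly_coverage_uses_calendar_length(self):
        # a full 15-min May (2976 samples) just meets min_coverage=1.0
        times = pd.date_range("2021-05-01", "2021-05-31 23:45", freq="15min")
        t = make_series_table(times, "n1", "air_temp", 20.0)
        out = series_ops.aggregate(t, "monthly", "mean", 15, min_coverage=1.0)
        assert out["flag"].iloc[0] == "ok"


class TestGapReport:
    def test_complete_table_has_no_gaps(self):
        rep = series_ops.gap_report(one_day(), 15)
        assert rep.gaps.empty and rep.downtime.empty

    def test_injected_failure_window_reported_exactly(self, small_geom):
        window = ("t01", "air_temp", "2021-05-02 06:00", "2021-05-02 18:00")
        cfg = synth.SynthConfig(random_seed=8, n_days=3)
        table, _ = synth.make_deployment_series(
            small_geom, cfg, synth.DefectSpec(failure_windows=[window])
        )
        rep = series_ops.gap_report(table, 15)
        assert len(rep.gaps) == 1
        g = rep.gaps.iloc[0]
        assert (g["node_id"], g["channel"]) == ("t01", "air_temp")
        assert g["gap_start"] == pd.Timestamp(window[2])
        assert g["gap_end"] == pd.Timestamp(window[3])
        assert rep.downtime["t01"] == pd.Timedelta(hours=12)

    def test_adjacent_missing_samples_coalesce_into_one_gap(self):
        t = one_day()
        t = t[~t["timestamp"].isin(
            pd.to_datetime(["2021-05-01 08:00", "2021-05-01 08:15"])
        )]
        rep = series_ops.gap_report(t, 15)
        assert len(rep.gaps) == 1
        g = rep.gaps.iloc[0]
        assert g["gap_start"] == pd.Timestamp("2021-05-01 08:00")
        assert g["gap_end"] == pd.Timestamp("2021-05-01 08:30")


def test_filters_never_mutate_values(clean_table):
    before = clean_table.copy()
    series_ops.window_filter(clean_table)
    series_ops.cloud_filter(clean_table)
    series_ops.range_check(clean_table)
    assert clean_table.equals(before)
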