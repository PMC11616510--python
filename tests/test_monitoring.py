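"""Monitoring CSV parsing, HRT regimes and descriptive statistics."""

import datetime as dt
import textwrap

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mnztreat import (HRTRegime, HRTSchedule, Station, StationSeries,
                      molar_ratio, read_monitoring_csv, read_schedule_csv,
                      removal_efficiency, summarise_station)
from mnztreat.exceptions import (InsufficientDataError, SchemaError,
                                 ValidationError)

HEADER = "date,station,mn_mg_l,zn_mg_l,ph,do_mg_l,ec_us_cm,orp_mv,temp_c\n"


def write(tmp_path, body, name="mon.csv"):
    p = tmp_path / name
    p.write_text(HEADER + textwrap.dedent(body))
    return p


@pytest.fixture
def schedule():
    return HRTSchedule.from_day_offsets(
        dt.date(2022, 6, 1), [(16, 2.0, 6.0), (97, 0.5, 1.5), (39, 0.3, 1.0)])


class TestReadMonitoringCsv:
    def test_empty_data_section_gives_empty_list(self, tmp_path):
        assert read_monitoring_csv(write(tmp_path, "")) == []

    def test_row_parses_all_fields(self, tmp_path):
        recs = read_monitoring_csv(
            write(tmp_path, "2022-07-01,A1,0.30,1.59,7.1,9.3,,,\n"))
        (r,) = recs
        assert r.station is Station.A1
        assert r.date == dt.date(2022, 7, 1)
        assert r.mn == pytest.approx(0.30)
        assert r.zn == pytest.approx(1.59)
        assert r.ph == pytest.approx(7.1)
        assert r.ec is None and r.orp is None and r.temp is None

    def test_unknown_station_names_the_row(self, tmp_path):
        p = write(tmp_path, "2022-07-01,B9,0.3,1.5,,,,,\n")
        with pytest.raises(ValidationError, match="line 2.*B9"):
            read_monitoring_csv(p)

    def test_missing_mandatory_column_is_schema_error(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("date,station,mn_mg_l\n2022-07-01,A1,0.3\n")
        with pytest.raises(SchemaError, match="zn_mg_l"):
            read_monitoring_csv(p)

    def test_unparseable_numeric_becomes_missing_not_zero(self, tmp_path):
        (r,) = read_monitoring_csv(
            write(tmp_path, "2022-07-01,A1,oops,1.5,,,,,\n"))
        assert r.mn is None

    def test_negative_concentration_rejected(self, tmp_path):
        with pytest.raises(ValidationError, match="line 2"):
            read_monitoring_csv(write(tmp_path, "2022-07-01,A1,-1.0,1.5,,,,,\n"))


class TestHRTSchedule:
    def test_half_open_regime_membership(self, schedule):
        assert schedule.label_for(dt.date(2022, 6, 1)) == "HRT2"
        # day 16 boundary belongs to the second regime, not the first
        assert schedule.label_for(dt.date(2022, 6, 17)) == "HRT0.5"
        assert schedule.label_for(dt.date(2023, 1, 1)) is None

    def test_overlapping_regimes_rejected(self):
        r1 = HRTRegime(dt.date(2022, 6, 1), dt.date(2022, 6, 20), 2.0, 6.0)
        r2 = HRTRegime(dt.date(2022, 6, 15), dt.date(2022, 7, 1), 0.5, 1.5)
        with pytest.raises(ValidationError):
            HRTSchedule([r1, r2])

    def test_csv_round_trip(self, schedule, tmp_path):
        p = tmp_path / "sched.csv"
        schedule.to_csv(p)
        back = read_schedule_csv(p)
        assert back.labels == schedule.labels
        assert back.start == schedule.start and back.end == schedule.end


def series(station, start, values_mn, values_zn=None):
    n = len(values_mn)
    dates = [start + dt.timedelta(days=i) for i in range(n)]
    zn = values_zn if values_zn is not None else values_mn
    return StationSeries(station=station, dates=dates,
                         mn=np.asarray(values_mn, float),
                         zn=np.asarray(zn, float))


class TestRemovalEfficiency:
    def test_hand_computed_example(self, schedule):
        start = dt.date(2022, 6, 2)
        inlet = series(Station.A0, start, [19.0] * 5)
        outlet = series(Station.A1, start, [0.5] * 5)
        eff = removal_efficiency(inlet, outlet, schedule, "HRT2", "mn")
        assert eff == pytest.approx(100 * (19 - 0.5) / 19)  # 97.37 %

    def test_identical_series_gives_zero(self, schedule):
        start = dt.date(2022, 6, 2)
        s = series(Station.A0, start, [3.0, 4.0, 5.0])
        assert removal_efficiency(s, s, schedule, "HRT2", "mn") == pytest.approx(0.0)

    def test_no_data_in_regime_raises(self, schedule):
        start = dt.date(2022, 6, 2)
        s = series(Station.A0, start, [3.0])
        with pytest.raises(InsufficientDataError):
            removal_efficiency(s, s, schedule, "HRT0.3", "mn")

    def test_paired_mode_matches_mean_mode_on_aligned_dates(self, schedule):
        start = dt.date(2022, 6, 2)
        inlet = series(Station.A0, start, [20.0, 18.0, 19.0])
        outlet = series(Station.A1, start, [1.0, 0.6, 0.8])
        e_mean = removal_efficiency(inlet, outlet, schedule, "HRT2", "mn")
        e_pair = removal_efficiency(inlet, outlet, schedule, "HRT2", "mn",
                                    mode="paired")
        assert e_mean == pytest.approx(e_pair)

    @given(scale=st.floats(0.1, 100.0))
    @settings(max_examples=25, deadline=None)
    def test_invariant_under_uniform_rescaling(self, scale):
        schedule = HRTSchedule.from_day_offsets(dt.date(2022, 6, 1),
                                                [(30, 2.0, 6.0)])
        start = dt.date(2022, 6, 2)
        inlet = series(Station.A0, start, [19.0, 21.0, 20.0])
        outlet = series(Station.A1, start, [0.5, 0.8, 0.2])
        base = removal_efficiency(inlet, outlet, schedule, "HRT2", "mn")
        inlet2 = series(Station.A0, start, [scale * v for v in [19.0, 21.0, 20.0]])
        outlet2 = series(Station.A1, start, [scale * v for v in [0.5, 0.8, 0.2]])
        scaled = removal_efficiency(inlet2, outlet2, schedule, "HRT2", "mn")
        assert scaled == pytest.approx(base, rel=1e-9)
        assert scaled <= 100.0


class TestMolarRatio:
    @pytest.mark.parametrize("mn, zn, expected", [
        (20.0, 9.5, (20 / 54.938) / (9.5 / 65.38)),  # ~2.51
        (0.0, 8.0, 0.0),
        (54.938, 65.38, 1.0),
    ])
    def test_values(self, mn, zn, expected):
        assert molar_ratio(mn, zn) == pytest.approx(expected)

    def test_zero_zn_raises(self):
        with pytest.raises(ZeroDivisionError):
            molar_ratio(1.0, 0.0)

    @given(a=st.floats(1e-3, 1e3))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance(self, a):
        assert molar_ratio(a * 20, a * 9.5) == pytest.approx(
            molar_ratio(20, 9.5), rel=1e-12)


class TestSummariseStation:
    def test_basic_statistics(self):
        s = series(Station.A1, dt.date(2022, 6, 2), [1.0, 2.0, 3.0])
        table = summarise_station(s)
        row = table[(table.analyte == "mn")].iloc[0]
        assert (row["mean"], row["min"], row["max"]) == (2.0, 1.0, 3.0)
        assert row["n"] == 3 and row["n_missing"] == 0

    def test_singleton_mean_is_the_value(self):
        s = series(Station.A1, dt.date(2022, 6, 2), [4.2])
        assert summarise_station(s).iloc[0]["mean"] == pytest.approx(4.2)

    def test_missing_values_excluded_and_counted(self):
        s = series(Station.A1, dt.date(2022, 6, 2), [1.0, np.nan, 3.0])
        row = summarise_station(s).iloc[0]
        assert row["mean"] == pytest.approx(2.0)
        assert row["n"] == 2 and row["n_missing"] == 1

    def test_empty_series_raises(self):
        s = StationSeries(station=Station.A1, dates=[], mn=[], zn=[])
        with pytest.raises(InsufficientDataError):
            summarise_station(s)

    def test_per_regime_grouping(self, schedule):
        camp_start = dt.date(2022, 6, 2)
        dates = [camp_start + dt.timedelta(days=d) for d in (1, 20, 40, 120)]
        s = StationSeries(station=Station.A1, dates=dates,
                          mn=[1.0, 2.0, 3.0, 4.0], zn=[1.0, 2.0, 3.0, 4.0])
        table = summarise_station(s, schedule)
        assert set(table.regime) == {"HRT2", "HRT0.5", "HRT0.3"}
        mid = table[(table.regime == "HRT0.5") & (table.analyte == "mn")].iloc[0]
        assert mid["mean"] == pytest.approx(2.5)
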