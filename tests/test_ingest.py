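import datetime as dt

import pytest
from hypothesis import given, settings, strategies as st

from dielact.ingest import (
    FilterConfig,
    assign_season,
    bin_and_window,
    read_and_filter,
    season_center,
    solar_hour,
    to_solar,
)
from .oracles import noaa_solar


class TestSolarHour:
    def test_longitude_shift_is_exactly_one_hour_per_15_degrees(self, utc):
        ts = utc(2021, 7, 3, 14)
        for lon in (-120.0, -30.0, 0.0, 44.0):
            delta = (solar_hour(ts, lon + 15.0) - solar_hour(ts, lon)) % 24.0
            assert delta == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize(
        "lon,utc_hour", [(0.0, 12), (-75.0, 17), (30.0, 10)],
        ids=["greenwich", "us-east", "east30"],
    )
    def test_solar_noon_near_zero_equation_of_time(self, utc, lon, utc_hour):
        # mid-April: equation of time passes through zero
        ts = utc(2021, 4, 15, utc_hour)
        assert solar_hour(ts, lon) == pytest.approx(12.0, abs=0.02)

    def test_agrees_with_noaa_equation_of_time_across_the_year(self, utc):
        # Spencer series vs the NOAA (Meeus) series: within ~1.5 min,
        # far below the 1-hour binning resolution
        for month in range(1, 13):
            date = dt.date(2021, month, 10)
            got = solar_hour(utc(2021, month, 10, 12), 0.0)
            want = 12.0 + noaa_solar(date, 40.0)["eqtime_min"] / 60.0
            assert got == pytest.approx(want, abs=1.5 / 60.0)

    def test_naive_timestamp_is_rejected(self):
        with pytest.raises(ValueError, match="UTC offset"):
            solar_hour(dt.datetime(2021, 4, 15, 12, 0), 0.0)


class TestBinAndWindow:
    @pytest.mark.parametrize(
        "raw,expected",
        [(13.6, 14), (7.49, None), (7.5, 8), (20.4, 20), (20.5, None), (12.0, 12), (8.0, 8), (20.0, 20)],
    )
    def test_rounding_and_window(self, raw, expected):
        assert bin_and_window(raw) == expected

    @given(st.integers(min_value=8, max_value=20))
    @settings(derandomize=True, max_examples=13)
    def test_idempotent_on_in_window_integers(self, h):
        assert bin_and_window(float(h)) == h


class TestSeasons:
    @pytest.mark.parametrize(
        "date,season,year",
        [
            ("2020-12-21", "winter", 2020),
            ("2020-06-21", "summer", 2020),
            ("2021-02-04", "winter", 2020),
            ("2021-02-05", "spring", 2021),
            ("2021-01-10", "winter", 2020),
            ("2020-09-19", "fall", 2020),
        ],
    )
    def test_known_dates(self, date, season, year):
        assert assign_season(dt.date.fromisoformat(date)) == (season, year)

    def test_centers_are_91_days_apart(self):
        centers = [season_center(s, 2020) for s in ("spring", "summer", "fall")]
        prev = season_center("winter", 2019)
        for c in centers:
            assert (c - prev).days == 91
            prev = c
        assert season_center("winter", 2020) == dt.date(2020, 12, 21)
        assert (season_center("summer", 2020) - dt.date(2019, 12, 21)).days == 182

    @given(st.dates(min_value=dt.date(2016, 1, 1), max_value=dt.date(2024, 12, 31)))
    @settings(derandomize=True, max_examples=300)
    def test_every_date_maps_to_exactly_one_season(self, date):
        season, year = assign_season(date)
        assert season in ("winter", "spring", "summer", "fall")
        # the date lies within 46 days of its season center, and no other
        # center is strictly closer
        own = abs((date - season_center(season, year)).days)
        assert own <= 46
        for s in ("winter", "spring", "summer", "fall"):
            for y in (year - 1, year, year + 1):
                assert abs((date - season_center(s, y)).days) >= own


class TestReadAndFilter:
    def test_rule_order_and_accounting(self, occurrence_csv):
        path = occurrence_csv(
            [
                {"id": "keep"},
                {"id": "nots", "eventDateTime": ""},
                {"id": "badts", "eventDateTime": "not-a-time"},
                {"id": "old", "eventDateTime": "2014-06-15T18:00:00+00:00"},
                {"id": "ocean", "decimalLongitude": -150.0},
                {"id": "badcoord", "decimalLatitude": "oops"},
                {"id": "larva", "lifeStage": "larva"},
                {"id": "monarch", "species": "Danaus plexippus"},
                {"id": "cater", "project": "Caterpillars of Eastern North America"},
            ]
        )
        records, report = read_and_filter(path)
        assert [r.record_id for r in records] == ["keep"]
        assert report.no_timestamp == 2
        assert report.outside_region == 2  # ocean point + malformed coordinate
        assert report.year_cutoff == 1
        assert report.life_stage == 1
        assert report.species_excluded == 1
        assert report.project_excluded == 1
        assert report.retained == 1
        assert report.removed + report.retained == report.n_input == 9

    def test_first_matching_rule_wins(self, occurrence_csv):
        # a 2014 monarch is counted under the year rule, not the species rule
        path = occurrence_csv(
            [{"species": "Danaus plexippus", "eventDateTime": "2014-06-15T18:00:00+00:00"}]
        )
        _, report = read_and_filter(path)
        assert report.year_cutoff == 1
        assert report.species_excluded == 0

    def test_year_cutoff_is_configurable(self, occurrence_csv):
        path = occurrence_csv([{"eventDateTime": "2015-06-15T18:00:00+00:00"}])
        _, r2016 = read_and_filter(path, FilterConfig(min_year=2016))
        _, r2015 = read_and_filter(path, FilterConfig(min_year=2015))
        assert r2016.year_cutoff == 1 and r2015.retained == 1

    def test_unreadable_file_is_fatal(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_and_filter(str(tmp_path / "missing.csv"))

    def test_missing_required_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("foo,bar\n1,2\n")
        with pytest.raises(ValueError, match="required column"):
            read_and_filter(str(path))


class TestToSolar:
    def test_window_removals_update_report(self, occurrence_csv):
        # solar hour at lon -90 for 09:00 UTC is ~3am: outside the window
        path = occurrence_csv(
            [
                {"id": "day", "eventDateTime": "2020-06-15T18:00:00+00:00"},
                {"id": "night", "eventDateTime": "2020-06-15T09:00:00+00:00"},
            ]
        )
        records, report = read_and_filter(path)
        solar = to_solar(records, report)
        assert [o.record_id for o in solar] == ["day"]
        assert report.outside_hour_window == 1
        assert report.removed + report.retained == report.n_input

    def test_solar_fields_consistent(self, occurrence_csv):
        path = occurrence_csv([{"eventDateTime": "2020-06-15T18:30:00+00:00"}])
        records, report = read_and_filter(path)
        (obs,) = to_solar(records, report)
        assert obs.solar_hour == bin_and_window(obs.solar_hour_raw)
        assert 8 <= obs.solar_hour <= 20
        assert (obs.season, obs.season_year) == assign_season(obs.date)
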