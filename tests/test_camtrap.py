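"""Photo logs, event collapsing, detection histories, naive occurrence."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dielocc.camtrap import (
    PhotoRecord,
    build_history,
    collapse_events,
    naive_occurrence,
    read_photo_log,
    trap_days,
    write_photo_log,
)
from tests.conftest import TZ, make_sites


def photo(site, hours, species="Kodkod", base=dt.datetime(2012, 1, 6, 0, 0, tzinfo=TZ)):
    return PhotoRecord(site, species, base + dt.timedelta(hours=hours))


class TestCollapseEvents:
    def test_photos_within_a_day_form_one_event(self):
        events = collapse_events([photo("T0", h) for h in (0, 1, 2)])
        assert len(events) == 1 and len(events[0]) == 3

    def test_gap_beyond_24h_starts_new_event(self):
        events = collapse_events([photo("T0", 0), photo("T0", 25)])
        assert len(events) == 2

    def test_exactly_24h_starts_new_event(self):
        events = collapse_events([photo("T0", 0), photo("T0", 24)])
        assert len(events) == 2

    def test_anchor_is_first_photo_of_event(self):
        # 0h, 23h, 30h: the 30h photo is 30h after the anchor -> new event,
        # even though it is only 7h after the previous photo
        events = collapse_events([photo("T0", 0), photo("T0", 23), photo("T0", 30)])
        assert [len(e) for e in events] == [2, 1]

    def test_empty_and_unsorted(self):
        assert collapse_events([]) == []
        with pytest.raises(ValueError, match="sorted"):
            collapse_events([photo("T0", 5), photo("T0", 0)])

    @given(st.lists(st.floats(0, 400, allow_nan=False), min_size=1, max_size=40),
           st.floats(1, 48), st.floats(0.1, 48))
    @settings(max_examples=100, deadline=None)
    def test_wider_window_never_increases_event_count(self, hours, w1, extra):
        photos = [photo("T0", h) for h in sorted(hours)]
        narrow = collapse_events(photos, dt.timedelta(hours=w1))
        wide = collapse_events(photos, dt.timedelta(hours=w1 + extra))
        assert len(wide) <= len(narrow)
        assert sum(len(e) for e in narrow) == len(photos)  # events cover all


class TestBuildHistory:
    def test_day_detections_counted_per_distinct_day(self, solar):
        sites = make_sites(1, k=10)
        photos = [
            PhotoRecord("T0", "Kodkod", dt.datetime(2012, 1, 5 + d, 12, 0, tzinfo=TZ))
            for d in (0, 2, 4)
        ]
        hist = build_history(photos, sites, solar)
        row = hist.set_index(["species", "period"])
        assert row.loc[("Kodkod", "day"), "y"].item() == 3
        assert row.loc[("Kodkod", "day"), "k"].item() == 10
        assert row.loc[("Kodkod", "night"), "y"].item() == 0
        assert row.loc[("Kodkod", "night"), "k"].item() == 10

    def test_photo_just_before_sunrise_is_a_day_occasion(self, solar):
        sites = make_sites(1, k=5)
        sr, _ = solar.times(dt.date(2012, 1, 6))
        photos = [PhotoRecord("T0", "Kodkod", sr - dt.timedelta(minutes=30))]
        hist = build_history(photos, sites, solar).set_index(["species", "period"])
        assert hist.loc[("Kodkod", "day"), "y"].item() == 1

    def test_same_night_photos_are_one_occasion(self, solar):
        sites = make_sites(1, k=5)
        base = dt.datetime(2012, 1, 6, 1, 0, tzinfo=TZ)
        photos = [
            PhotoRecord("T0", "Kodkod", base),
            PhotoRecord("T0", "Kodkod", base + dt.timedelta(minutes=45)),
        ]
        hist = build_history(photos, sites, solar).set_index(["species", "period"])
        assert hist.loc[("Kodkod", "night"), "y"].item() == 1

    def test_photo_outside_deployment_rejected_with_record(self, solar):
        sites = make_sites(1, k=5)
        photos = [PhotoRecord("T0", "Kodkod", dt.datetime(2012, 3, 1, 12, 0, tzinfo=TZ))]
        with pytest.raises(ValueError, match="T0/Kodkod"):
            build_history(photos, sites, solar)

    def test_occasion_conservation(self, solar):
        # sum of k over sites equals total camera-days, per period
        sites = make_sites(6, k=9)
        hist = build_history([], sites, solar, species=["Kodkod"])
        per_period = hist.groupby("period")["k"].sum()
        assert (per_period == 6 * 9).all()

    def test_rebuild_is_bit_identical(self, solar):
        sites = make_sites(3, k=8)
        photos = [photo("T1", h) for h in (1, 30, 77)]
        h1 = build_history(photos, sites, solar)
        h2 = build_history(photos, sites, solar)
        pd.testing.assert_frame_equal(h1, h2)

    def test_partial_day_counts_as_whole_trap_day(self):
        sites = make_sites(1, k=1)  # deploy_start == deploy_end
        assert trap_days(sites).iloc[0] == 1


class TestNaiveOccurrence:
    def test_fraction_of_sites_with_detection(self, solar):
        sites = make_sites(4, k=5)
        photos = [photo("T0", 12), photo("T1", 12)]
        hist = build_history(photos, sites, solar)
        naive = naive_occurrence(hist).set_index(["species", "period"])
        assert naive.loc[("Kodkod", "day"), "naive_occurrence"].item() == 0.5
        assert naive.loc[("Kodkod", "night"), "naive_occurrence"].item() == 0.0

    def test_zero_sites_error(self):
        with pytest.raises(ValueError):
            naive_occurrence(pd.DataFrame(columns=["site_id", "species", "period", "y", "k"]))


class TestPhotoLogIO:
    def test_round_trip(self, tmp_path):
        records = [photo("T0", 3), photo("T1", 40, species="Cougar")]
        path = tmp_path / "log.csv"
        write_photo_log(records, path)
        back = read_photo_log(path)
        assert back == records

    def test_naive_timestamp_rejected_with_line_number(self, tmp_path):
        path = tmp_path / "log.csv"
        path.write_text("site_id,species,timestamp\nT0,Kodkod,2012-01-06T12:00:00\n")
        with pytest.raises(ValueError, match="line 2"):
            read_photo_log(path)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "log.csv"
        path.write_text("site_id,when\nT0,2012-01-06\n")
        with pytest.raises(ValueError, match="missing"):
            read_photo_log(path)


def test_naive_timestamp_photo_record_rejected():
    with pytest.raises(ValueError, match="offset"):
        PhotoRecord("T0", "Kodkod", dt.datetime(2012, 1, 6, 1, 0))
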