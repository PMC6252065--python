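"""Detection-table IO, independence filtering and co-occurrence restriction."""

from datetime import timedelta

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from camtrapdiel import records_io
from camtrapdiel.records_io import (
    DetectionRecord,
    RowError,
    SchemaError,
    filter_independent,
    read_detections,
    restrict_to_cooccurrence,
    write_detections,
)


class TestReadDetections:
    def test_well_formed_csv_reads_in_timestamp_order(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text(
            "species,site_id,camera_id,timestamp,latitude,longitude\n"
            "fox,A,C1,2015-04-17T22:10,54.6,-5.9\n"
            "fox,A,C1,2015-04-17T10:00,54.6,-5.9\n"
            "hare,A,C1,2015-04-17T05:30,54.6,-5.9\n"
        )
        df = read_detections(p)
        assert len(df) == 3
        fox = df[df["species"] == "fox"]
        assert list(fox["timestamp"].dt.hour) == [10, 22]
        assert (df["group_size"] == 1).all()

    def test_out_of_range_latitude_names_the_row(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text(
            "species,site_id,camera_id,timestamp,latitude,longitude\n"
            "fox,A,C1,2015-04-17T22:10,95,-5.9\n"
        )
        with pytest.raises(RowError, match="row 1.*latitude"):
            read_detections(p)

    def test_unparseable_timestamps_collected_then_raised(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text(
            "species,site_id,camera_id,timestamp,latitude,longitude\n"
            "fox,A,C1,not-a-time,54.6,-5.9\n"
            "fox,A,C1,also bad,54.6,-5.9\n"
        )
        with pytest.raises(RowError, match="2 invalid row"):
            read_detections(p)

    def test_missing_column_is_schema_error(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text("species,timestamp\nfox,2015-04-17T22:10\n")
        with pytest.raises(SchemaError, match="site_id"):
            read_detections(p)

    def test_column_mapping_and_ddmmyyyy_dialect(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text(
            "Species,Station,Cam,DateTime,Lat,Lon\n"
            "fox,A,C1,17/04/2015 22:10,54.6,-5.9\n"
        )
        schema = {
            "species": "Species",
            "site_id": "Station",
            "camera_id": "Cam",
            "timestamp": "DateTime",
            "latitude": "Lat",
            "longitude": "Lon",
        }
        df = read_detections(p, schema)
        assert df.loc[0, "timestamp"] == pd.Timestamp("2015-04-17 22:10")

    def test_write_then_read_roundtrip(self, tmp_path, detections_factory):
        df = detections_factory(
            [
                ("fox", "A", "C1", "2015-04-17T22:10"),
                ("hare", "B", "C2", "2015-07-01T05:31"),
            ]
        )
        p = tmp_path / "rt.csv"
        write_detections(df, p)
        back = read_detections(p)
        pd.testing.assert_frame_equal(back, df)


class TestDetectionRecord:
    def test_bounds_enforced(self):
        with pytest.raises(ValueError, match="latitude"):
            DetectionRecord("fox", "A", "C1", pd.Timestamp("2015-01-01"), 95.0, 0.0)
        with pytest.raises(ValueError, match="group_size"):
            DetectionRecord("fox", "A", "C1", pd.Timestamp("2015-01-01"), 54.0, 0.0, 0)


def brute_force_independent(times, interval):
    """Reference greedy scan over an already-sorted list of timestamps."""
    kept = []
    for t in times:
        if not kept or t - kept[-1] >= interval:
            kept.append(t)
    return kept


class TestFilterIndependent:
    def test_worked_example_one_hour(self, detections_factory):
        df = detections_factory(
            [
                ("fox", "A", "C1", "2015-04-17T10:00"),
                ("fox", "A", "C1", "2015-04-17T10:30"),
                ("fox", "A", "C1", "2015-04-17T11:30"),
            ]
        )
        out = filter_independent(df, timedelta(hours=1))
        assert list(out.records["timestamp"].dt.strftime("%H:%M")) == ["10:00", "11:30"]
        assert out.n_removed == 1

    def test_single_record_unchanged(self, detections_factory):
        df = detections_factory([("fox", "A", "C1", "2015-04-17T10:00")])
        out = filter_independent(df)
        assert len(out.records) == 1

    def test_independence_is_per_camera(self, detections_factory):
        df = detections_factory(
            [
                ("fox", "A", "C1", "2015-04-17T10:00"),
                ("fox", "A", "C2", "2015-04-17T10:00"),
            ]
        )
        assert len(filter_independent(df).records) == 2

    def test_same_minute_burst_collapses(self, detections_factory):
        df = detections_factory(
            [
                ("fox", "A", "C1", "2015-04-17T10:00"),
                ("fox", "A", "C1", "2015-04-17T10:00"),
            ]
        )
        assert len(filter_independent(df, timedelta(0)).records) == 1

    def test_negative_interval_rejected(self, detections_factory):
        df = detections_factory([("fox", "A", "C1", "2015-04-17T10:00")])
        with pytest.raises(ValueError):
            filter_independent(df, timedelta(hours=-1))

    @given(
        minutes=st.lists(st.integers(0, 60 * 24 * 3), min_size=1, max_size=40),
        interval_min=st.integers(0, 180),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_brute_force_greedy_scan(self, minutes, interval_min):
        base = pd.Timestamp("2015-04-17")
        times = sorted({base + pd.Timedelta(minutes=m) for m in minutes})
        df = pd.DataFrame(
            {
                "species": "fox",
                "site_id": "A",
                "camera_id": "C1",
                "timestamp": times,
                "latitude": 54.6,
                "longitude": -5.9,
                "group_size": 1,
            }
        )
        interval = timedelta(minutes=interval_min)
        got = list(filter_independent(df, interval).records["timestamp"])
        assert got == brute_force_independent(times, interval)

    @given(
        minutes=st.lists(st.integers(0, 60 * 24), min_size=1, max_size=30, unique=True),
        interval_min=st.integers(0, 120),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_idempotent_and_zero_interval_identity(self, minutes, interval_min):
        base = pd.Timestamp("2015-04-17")
        df = pd.DataFrame(
            {
                "species": "fox",
                "site_id": "A",
                "camera_id": "C1",
                "timestamp": sorted(base + pd.Timedelta(minutes=m) for m in minutes),
                "latitude": 54.6,
                "longitude": -5.9,
                "group_size": 1,
            }
        )
        interval = timedelta(minutes=interval_min)
        once = filter_independent(df, interval).records
        twice = filter_independent(once, interval).records
        pd.testing.assert_frame_equal(once, twice)
        zero = filter_independent(df, timedelta(0)).records
        assert len(zero) == len(df)

    def test_event_count_non_increasing_in_interval(self, rng):
        base = pd.Timestamp("2015-04-17")
        df = pd.DataFrame(
            {
                "species": "fox",
                "site_id": "A",
                "camera_id": "C1",
                "timestamp": sorted(
                    base + pd.Timedelta(minutes=int(m))
                    for m in rng.integers(0, 2880, size=60)
                ),
                "latitude": 54.6,
                "longitude": -5.9,
                "group_size": 1,
            }
        )
        counts = [
            len(filter_independent(df, timedelta(minutes=m)).records)
            for m in [0, 15, 30, 60, 120, 240]
        ]
        assert counts == sorted(counts, reverse=True)


class TestCooccurrence:
    def test_shared_sites_only(self, detections_factory):
        df = detections_factory(
            [
                ("fox", "A", "C1", "2015-04-17T10:00"),
                ("fox", "B", "C2", "2015-04-17T10:00"),
                ("hare", "B", "C3", "2015-04-17T11:00"),
                ("hare", "C", "C4", "2015-04-17T12:00"),
            ]
        )
        out, shared = restrict_to_cooccurrence(df, "fox", "hare")
        assert shared == {"B"}
        assert set(out["site_id"]) == {"B"}
        assert len(out) == 2

    def test_no_shared_location_gives_empty_result(self, detections_factory):
        df = detections_factory(
            [
                ("fox", "A", "C1", "2015-04-17T10:00"),
                ("hare", "B", "C2", "2015-04-17T11:00"),
            ]
        )
        out, shared = restrict_to_cooccurrence(df, "fox", "hare")
        assert shared == set() and len(out) == 0

    def test_unknown_species_rejected(self, detections_factory):
        df = detections_factory([("fox", "A", "C1", "2015-04-17T10:00")])
        with pytest.raises(ValueError, match="badger"):
            restrict_to_cooccurrence(df, "fox", "badger")

    def test_random_assignments_match_set_intersection(self, rng):
        sites = [f"S{i}" for i in range(8)]
        rows = []
        for i in range(200):
            rows.append(
                {
                    "species": rng.choice(["fox", "hare", "badger"]),
                    "site_id": rng.choice(sites),
                    "camera_id": "C1",
                    "timestamp": pd.Timestamp("2015-04-17") + pd.Timedelta(minutes=i),
                    "latitude": 54.6,
                    "longitude": -5.9,
                    "group_size": 1,
                }
            )
        df = pd.DataFrame(rows)
        out, shared = restrict_to_cooccurrence(df, "fox", "hare")
        expect = set(df[df.species == "fox"].site_id) & set(df[df.species == "hare"].site_id)
        assert shared == expect
        assert set(out["species"]) <= {"fox", "hare"}
        assert set(out["site_id"]) <= expect


def test_camera_days_counts_distinct_camera_dates(detections_factory):
    df = detections_factory(
        [
            ("fox", "A", "C1", "2015-04-17T10:00"),
            ("fox", "A", "C1", "2015-04-17T22:00"),
            ("fox", "A", "C1", "2015-04-18T10:00"),
            ("hare", "A", "C2", "2015-04-17T10:00"),
        ]
    )
    assert records_io.camera_days(df) == 3
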