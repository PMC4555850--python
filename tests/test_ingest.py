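"""Event reading, filters and displacement diagnostics."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon

import geomob
from geomob import ingest
from geomob.synthetic import write_events_csv, write_events_jsonl

from _oracles import haversine_km_oracle, point_in_polygon_oracle

CSV_HEADER = "user_id,lon,lat,timestamp\n"


def _write(tmp_path, body, name="events.csv"):
    p = tmp_path / name
    p.write_text(CSV_HEADER + body)
    return p


class TestReadEvents:
    def test_well_formed_rows(self, tmp_path):
        p = _write(tmp_path, "a,0.1,51.5,2010-01-01T10:00:00Z\n"
                             "a,0.2,51.6,2010-01-02T10:00:00Z\n"
                             "b,-3.1,55.9,2010-02-01T09:00:00Z\n")
        events = ingest.read_events(p)
        assert len(events) == 3
        assert list(events.columns) == ["user_id", "lon", "lat", "timestamp"]

    def test_invalid_latitude_row_rejected_others_kept(self, tmp_path):
        p = _write(tmp_path, "a,0.1,95.0,2010-01-01T10:00:00Z\n"
                             "a,0.2,51.6,2010-01-02T10:00:00Z\n")
        events = ingest.read_events(p)
        assert len(events) == 1
        assert events.loc[0, "lat"] == 51.6

    def test_zero_valid_rows_raises(self, tmp_path):
        p = _write(tmp_path, "a,999,95.0,not-a-time\n")
        with pytest.raises(ValueError):
            ingest.read_events(p)

    def test_unknown_format_raises(self, tmp_path):
        p = _write(tmp_path, "a,0.1,51.5,2010-01-01T10:00:00Z\n")
        with pytest.raises(ValueError):
            ingest.read_events(p, fmt="parquet")

    @pytest.mark.parametrize("writer,fmt", [(write_events_csv, "csv"),
                                            (write_events_jsonl, "jsonl")])
    def test_synthetic_population_round_trip(self, tmp_path, world10, writer, fmt):
        events, _ = geomob.simulate_population(world10, 5, seed=21)
        p = tmp_path / f"pop.{fmt}"
        writer(events, p)
        back = ingest.read_events(p, fmt=fmt)
        assert len(back) == len(events)
        np.testing.assert_allclose(back["lon"], events["lon"], atol=1e-9)
        np.testing.assert_allclose(back["lat"], events["lat"], atol=1e-9)
        assert (back["timestamp"].dt.floor("s").to_numpy()
                == events["timestamp"].dt.floor("s").to_numpy()).all()


def _events(rows):
    df = pd.DataFrame(rows, columns=["user_id", "lon", "lat", "timestamp"])
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
    return df


UNIT_SQUARE = {"type": "Polygon",
               "coordinates": [[[0, 0], [1, 0], [1, 1], [0, 1], [0, 0]]]}


class TestRegionFilter:
    def test_interior_point_kept_exterior_removed(self):
        ev = _events([("a", 0.5, 0.5, "2010-01-01"), ("a", 2.0, 2.0, "2010-01-02")])
        out = ingest.filter_by_region(ev, UNIT_SQUARE)
        assert len(out) == 1 and out.loc[0, "lon"] == 0.5

    def test_boundary_point_kept(self):
        ev = _events([("a", 0.0, 0.5, "2010-01-01")])
        assert len(ingest.filter_by_region(ev, UNIT_SQUARE)) == 1

    def test_invalid_polygon_raises(self):
        bowtie = Polygon([(0, 0), (1, 1), (1, 0), (0, 1)])
        ev = _events([("a", 0.5, 0.5, "2010-01-01")])
        with pytest.raises(ValueError):
            ingest.filter_by_region(ev, bowtie)

    def test_membership_matches_ray_casting_oracle(self, rng):
        # random simple (star-shaped) 12-gon around the origin
        angles = np.sort(rng.uniform(0, 2 * np.pi, 12))
        radii = rng.uniform(0.5, 2.0, 12)
        verts = [(r * np.cos(a), r * np.sin(a)) for r, a in zip(radii, angles)]
        poly = Polygon(verts)
        pts = rng.uniform(-2.5, 2.5, size=(1000, 2))
        ev = _events([(f"u{i}", x, y, "2010-01-01") for i, (x, y) in enumerate(pts)])
        kept = set(ingest.filter_by_region(ev, poly)["user_id"])
        expected = {f"u{i}" for i, (x, y) in enumerate(pts)
                    if point_in_polygon_oracle(x, y, verts)}
        assert kept == expected


class TestSingleDayFilter:
    def test_single_day_user_removed(self):
        ev = _events([("a", 0, 50, f"2010-03-01T{h:02d}:00:00") for h in range(10)])
        assert len(ingest.filter_single_day_users(ev)) == 0

    def test_multi_day_user_kept(self):
        ev = _events([("a", 0, 50, "2010-03-01"), ("a", 0, 50, "2010-03-02")])
        assert len(ingest.filter_single_day_users(ev)) == 2

    def test_matches_brute_force_date_set_check(self, world10):
        events, _ = geomob.simulate_population(world10, 30, photo_log_mean=1.0,
                                               photo_log_sd=1.0, seed=31)
        survivors = set(ingest.filter_single_day_users(events)["user_id"])
        expected = set()
        for uid, grp in events.groupby("user_id"):
            days = {ts.strftime("%Y-%m-%d") for ts in grp["timestamp"]}
            if len(days) > 1:
                expected.add(uid)
        assert survivors == expected

    def test_filters_idempotent_and_commutative(self):
        ev = _events([("a", 0.5, 0.5, "2010-03-01"), ("a", 0.6, 0.6, "2010-03-02"),
                      ("b", 0.5, 0.5, "2010-03-01"), ("b", 2.0, 2.0, "2010-03-02"),
                      ("c", 2.0, 2.0, "2010-03-01"), ("c", 2.1, 2.1, "2010-03-05")])
        f_day = ingest.filter_single_day_users
        f_reg = lambda e: ingest.filter_by_region(e, UNIT_SQUARE)
        once = f_day(f_reg(ev))
        pd.testing.assert_frame_equal(f_day(once), once)
        pd.testing.assert_frame_equal(f_reg(once), once)
        pd.testing.assert_frame_equal(f_day(f_reg(ev)), f_reg(f_day(f_reg(ev))))
        # user b becomes single-day after the region filter and must vanish
        assert "b" not in set(once["user_id"])


class TestSplitTrajectories:
    def test_two_interleaved_users(self):
        ev = _events([("a", 0, 50, "2010-01-02"), ("b", 1, 51, "2010-01-01"),
                      ("a", 0, 50, "2010-01-01"), ("b", 1, 51, "2010-01-03")])
        trajs = {t.user_id: t for t in ingest.split_trajectories(ev)}
        assert set(trajs) == {"a", "b"}
        for t in trajs.values():
            assert np.all(np.diff(t.timestamps.astype("int64")) >= 0)

    def test_duplicate_timestamps_keep_input_order(self):
        ev = _events([("a", 1, 50, "2010-01-01T10:00:00"),
                      ("a", 2, 50, "2010-01-01T10:00:00"),
                      ("a", 3, 50, "2010-01-01T10:00:00")])
        t = ingest.split_trajectories(ev)[0]
        np.testing.assert_array_equal(t.lons, [1, 2, 3])

    def test_events_conserved_as_multiset(self, world10):
        events, _ = geomob.simulate_population(world10, 10, seed=41)
        shuffled = events.sample(frac=1.0, random_state=7).reset_index(drop=True)
        trajs = ingest.split_trajectories(shuffled)
        rebuilt = pd.concat([
            pd.DataFrame({"user_id": t.user_id, "lon": t.lons, "lat": t.lats,
                          "timestamp": t.timestamps}) for t in trajs])
        key = ["user_id", "timestamp", "lon", "lat"]
        a = rebuilt.sort_values(key).reset_index(drop=True)
        b = events.assign(timestamp=events["timestamp"].dt.tz_localize(None)
                          ).sort_values(key).reset_index(drop=True)
        np.testing.assert_allclose(a[["lon", "lat"]], b[["lon", "lat"]])
        assert (a["user_id"].to_numpy() == b["user_id"].to_numpy()).all()


class TestDisplacements:
    def test_identical_points_and_single_event(self):
        t = ingest.Trajectory("u", np.array([0.0, 0.0]), np.array([50.0, 50.0]),
                              np.array(["2010-01-01", "2010-01-02"],
                                       dtype="datetime64[ns]"))
        np.testing.assert_allclose(ingest.displacement_lengths(t), [0.0])
        t1 = ingest.Trajectory("u", np.array([0.0]), np.array([50.0]),
                               np.array(["2010-01-01"], dtype="datetime64[ns]"))
        assert ingest.displacement_lengths(t1).size == 0

    def test_london_edinburgh_against_independent_haversine(self):
        t = ingest.Trajectory("u", np.array([-0.1276, -3.1883]),
                              np.array([51.5072, 55.9533]),
                              np.array(["2010-01-01", "2010-01-02"],
                                       dtype="datetime64[ns]"))
        d = ingest.displacement_lengths(t)[0]
        expected = haversine_km_oracle(-0.1276, 51.5072, -3.1883, 55.9533)
        assert abs(d - expected) / expected < 1e-3

    def test_invariant_under_reversal(self, world10):
        events, _ = geomob.simulate_user(world10, 3, 100, seed=51)
        t = ingest.split_trajectories(events)[0]
        rev = ingest.Trajectory("u", t.lons[::-1].copy(), t.lats[::-1].copy(),
                                t.timestamps.copy())
        np.testing.assert_allclose(ingest.displacement_lengths(t),
                                   ingest.displacement_lengths(rev)[::-1])
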