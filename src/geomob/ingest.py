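"""Reading, filtering and splitting geo-tagged event streams.

The two data filters mirror standard practice for photo-sharing mobility
data: drop events outside the study region polygon (e.g. points at sea),
then drop users whose entire record falls on one calendar day (they carry
no movement information).  "One day" means one UTC calendar date.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import shape as shapely_shape
from shapely.geometry.base import BaseGeometry

from .geo import haversine_km

logger = logging.getLogger(__name__)

EVENT_COLUMNS = ["user_id", "lon", "lat", "timestamp"]


@dataclass
class Trajectory:
    """One user's time-ordered geo-tagged events."""

    user_id: str
    lons: np.ndarray
    lats: np.ndarray
    timestamps: np.ndarray  # datetime64[ns], non-decreasing

    def __post_init__(self):
        if len(self.lons) < 1:
            raise ValueError("trajectory must contain at least one event")
        if np.any(np.diff(self.timestamps.astype("datetime64[ns]").astype(np.int64)) < 0):
            raise ValueError("timestamps must be non-decreasing")

    def __len__(self) -> int:
        return len(self.lons)

    @property
    def coords(self) -> np.ndarray:
        """(T, 2) array of (lon, lat)."""
        return np.column_stack([self.lons, self.lats])


def _validate_events(df: pd.DataFrame, origin: str):
    """Coerce raw rows to the event schema, dropping invalid rows with a reason."""
    reasons = pd.Series("", index=df.index, dtype=object)
    lon = pd.to_numeric(df["lon"], errors="coerce")
    lat = pd.to_numeric(df["lat"], errors="coerce")
    ts = pd.to_datetime(df["timestamp"], errors="coerce", utc=True, format="ISO8601")
    bad_lon = lon.isna() | (lon < -180) | (lon > 180)
    bad_lat = lat.isna() | (lat < -90) | (lat > 90)
    bad_ts = ts.isna()
    bad_uid = df["user_id"].isna() | (df["user_id"].astype(str).str.len() == 0)
    reasons[bad_lon] = "invalid longitude"
    reasons[bad_lat] = "invalid latitude"
    reasons[bad_ts] = "unparseable timestamp"
    reasons[bad_uid] = "missing user_id"
    bad = bad_lon | bad_lat | bad_ts | bad_uid
    for i, reason in reasons[bad].items():
        logger.warning("%s: rejected row %s: %s", origin, i, reason)
    out = pd.DataFrame({
        "user_id": df["user_id"].astype(str),
        "lon": lon, "lat": lat, "timestamp": ts,
    })[~bad.values].reset_index(drop=True)
    logger.info("%s: accepted %d rows, rejected %d", origin, len(out), int(bad.sum()))
    return out


def read_events(path, fmt: str = None) -> pd.DataFrame:
    """Read an event table from CSV or JSON-lines.

    Schema: ``user_id, lon, lat, timestamp`` (ISO-8601 UTC).  Malformed
    rows are rejected with a logged per-row reason; raises if the file is
    unreadable, the format unknown, or no row survives validation.
    """
    path = Path(path)
    if fmt is None:
        fmt = "jsonl" if path.suffix in {".jsonl", ".ndjson", ".json"} else "csv"
    if fmt == "csv":
        raw = pd.read_csv(path, dtype={"user_id": str})
    elif fmt == "jsonl":
        records = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line:
                    records.append(json.loads(line))
        raw = pd.DataFrame.from_records(records)
    else:
        raise ValueError(f"unknown format: {fmt!r}")
    missing = set(EVENT_COLUMNS) - set(raw.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = _validate_events(raw, str(path))
    if len(out) == 0:
        raise ValueError(f"{path}: no valid rows")
    return out


def load_region(polygon) -> BaseGeometry:
    """Accept a shapely geometry, a GeoJSON mapping, or a GeoJSON file path."""
    if isinstance(polygon, BaseGeometry):
        geom = polygon
    else:
        if isinstance(polygon, (str, Path)):
            with open(polygon) as fh:
                polygon = json.load(fh)
        if polygon.get("type") == "FeatureCollection":
            geoms = [shapely_shape(f["geometry"]) for f in polygon["features"]]
            geom = shapely.unary_union(geoms)
        elif polygon.get("type") == "Feature":
            geom = shapely_shape(polygon["geometry"])
        else:
            geom = shapely_shape(polygon)
    if not geom.is_valid:
        raise ValueError("invalid region polygon")
    return geom


def filter_by_region(events: pd.DataFrame, polygon) -> pd.DataFrame:
    """Keep only events inside or on the boundary of the region polygon."""
    geom = load_region(polygon)
    keep = shapely.intersects_xy(geom, events["lon"].to_numpy(),
                                 events["lat"].to_numpy())
    logger.info("region filter: kept %d of %d events", int(keep.sum()), len(events))
    return events[keep].reset_index(drop=True)


def filter_single_day_users(events: pd.DataFrame) -> pd.DataFrame:
    """Drop users whose events all fall on a single UTC calendar date."""
    dates = pd.to_datetime(events["timestamp"], utc=True).dt.floor("D")
    n_dates = dates.groupby(events["user_id"]).transform("nunique")
    keep = n_dates > 1
    logger.info("single-day filter: kept %d of %d events (%d users dropped)",
                int(keep.sum()), len(events),
                events.loc[~keep, "user_id"].nunique())
    return events[keep].reset_index(drop=True)


def split_trajectories(events: pd.DataFrame) -> list:
    """One time-sorted Trajectory per user; ties keep input order (stable)."""
    trajectories = []
    for uid, grp in events.groupby("user_id", sort=True):
        grp = grp.sort_values("timestamp", kind="stable")
        trajectories.append(Trajectory(
            user_id=uid,
            lons=grp["lon"].to_numpy(dtype=float),
            lats=grp["lat"].to_numpy(dtype=float),
            timestamps=pd.to_datetime(grp["timestamp"], utc=True)
                         .to_numpy(dtype="datetime64[ns]"),
        ))
    return trajectories


def displacement_lengths(trajectory: Trajectory) -> np.ndarray:
    """Great-circle lengths (km) of the T-1 consecutive displacements."""
    if len(trajectory) < 2:
        return np.empty(0)
    return haversine_km(trajectory.lons[:-1], trajectory.lats[:-1],
                        trajectory.lons[1:], trajectory.lats[1:])


def population_displacements(trajectories) -> np.ndarray:
    """Concatenated displacement lengths over a list of trajectories."""
    parts = [displacement_lengths(t) for t in trajectories]
    return np.concatenate(parts) if parts else np.empty(0)


def write_displacements(displacements: np.ndarray, path) -> None:
    """One-column CSV of displacement lengths in km."""
    pd.DataFrame({"displacement_km": displacements}).to_csv(path, index=False)
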