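"""Assign timestamped frames to geo-anchored trees and aggregate per tree.

The vehicle's GPS tracker and the cameras log independently, so each frame
first receives a position by linear time-interpolation between the
bracketing track points, then is assigned to the nearest tree anchor within
a maximum matching distance (great-circle, haversine).  Frames farther than
the cap from every anchor stay unassigned; frames timestamped outside the
track span are flagged.  Per tree and survey date, indices are aggregated
(mean by default) over contributing frames.
"""

from __future__ import annotations

import logging
import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TreeAnchor",
    "TrackPoint",
    "TreeObservation",
    "haversine_m",
    "interpolate_track",
    "match_frames_to_trees",
    "aggregate_observations",
    "read_anchors_csv",
    "read_track",
]

logger = logging.getLogger(__name__)

EARTH_RADIUS_M = 6_371_000.0

#: observation fields averaged per tree
INDEX_COLUMNS = ["laie", "lai", "omega0", "twsi", "ig", "td", "t_canopy"]


@dataclass(frozen=True)
class TreeAnchor:
    tree_id: str
    lat: float
    lon: float

    def __post_init__(self) -> None:
        if abs(self.lat) > 90 or abs(self.lon) > 180:
            raise ValueError(f"anchor {self.tree_id}: invalid coordinates "
                             f"({self.lat}, {self.lon})")


@dataclass(frozen=True)
class TrackPoint:
    timestamp: datetime
    lat: float
    lon: float


@dataclass
class TreeObservation:
    """Per-tree, per-survey-date aggregate: the output table's row type."""

    tree_id: str
    survey_date: str
    laie: float
    lai: float
    omega0: float
    twsi: float
    ig: float
    td: float
    t_canopy: float
    n_frames: int
    match_distance_m: float
    lat: float = math.nan
    lon: float = math.nan


def haversine_m(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Great-circle distance in metres (Earth radius 6371 km)."""
    lat1, lon1, lat2, lon2 = map(math.radians, (*a, *b))
    dlat, dlon = lat2 - lat1, lon2 - lon1
    h = math.sin(dlat / 2) ** 2 + math.cos(lat1) * math.cos(lat2) * math.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_M * math.asin(math.sqrt(h))


def _haversine_matrix(lats1, lons1, lats2, lons2) -> np.ndarray:
    """Pairwise great-circle distances, metres; shape (len(1), len(2))."""
    la1 = np.radians(np.asarray(lats1, float))[:, None]
    lo1 = np.radians(np.asarray(lons1, float))[:, None]
    la2 = np.radians(np.asarray(lats2, float))[None, :]
    lo2 = np.radians(np.asarray(lons2, float))[None, :]
    h = (np.sin((la2 - la1) / 2) ** 2
         + np.cos(la1) * np.cos(la2) * np.sin((lo2 - lo1) / 2) ** 2)
    return 2 * EARTH_RADIUS_M * np.arcsin(np.sqrt(h))


def _epoch(ts: datetime) -> float:
    if ts.tzinfo is None:
        ts = ts.replace(tzinfo=timezone.utc)
    return ts.timestamp()


def interpolate_track(
    track: list[TrackPoint], timestamps: list[datetime]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Linear-in-time positions along the track for each timestamp.

    Returns (lats, lons, in_span) where ``in_span`` is False for
    timestamps outside [first, last] track time (those positions are NaN).
    Track timestamps must be strictly increasing.
    """
    if len(track) < 2:
        raise ValueError("track needs at least two points for interpolation")
    t = np.array([_epoch(p.timestamp) for p in track])
    if not np.all(np.diff(t) > 0):
        raise ValueError("track timestamps must be strictly increasing")
    lats = np.array([p.lat for p in track])
    lons = np.array([p.lon for p in track])
    q = np.array([_epoch(ts) for ts in timestamps])
    in_span = (q >= t[0]) & (q <= t[-1])
    out_lat = np.interp(q, t, lats)
    out_lon = np.interp(q, t, lons)
    out_lat[~in_span] = np.nan
    out_lon[~in_span] = np.nan
    return out_lat, out_lon, in_span


def match_frames_to_trees(
    track: list[TrackPoint],
    frames: list[tuple[str, datetime]],
    anchors: list[TreeAnchor],
    max_distance_m: float = 25.0,
) -> pd.DataFrame:
    """Nearest-anchor assignment of frames positioned on the GPS track.

    Each frame is assigned to its nearest anchor iff the distance is within
    ``max_distance_m`` (default 25 m, about half a street-tree spacing, to
    prevent cross-street mis-assignment).  Exact distance ties break toward
    the lexicographically lower tree_id.

    Returns a DataFrame with columns frame_id, timestamp, lat, lon,
    tree_id (None when unassigned), distance_m, out_of_track.
    """
    if not track or not frames or not anchors:
        raise ValueError("track, frames and anchors must all be nonempty")
    ids = [a.tree_id for a in anchors]
    if len(set(ids)) != len(ids):
        raise ValueError("anchor tree_ids must be unique within a survey")

    frame_ids = [f[0] for f in frames]
    lats, lons, in_span = interpolate_track(track, [f[1] for f in frames])

    # stable anchor order by tree_id so argmin's first-hit IS the tie-break
    order = sorted(range(len(anchors)), key=lambda i: anchors[i].tree_id)
    a_ids = [anchors[i].tree_id for i in order]
    a_lat = [anchors[i].lat for i in order]
    a_lon = [anchors[i].lon for i in order]

    assigned: list[str | None] = []
    dists: list[float] = []
    valid = np.flatnonzero(in_span)
    if valid.size:
        dmat = _haversine_matrix(lats[valid], lons[valid], a_lat, a_lon)
    row = 0
    for i in range(len(frames)):
        if not in_span[i]:
            assigned.append(None)
            dists.append(math.nan)
            continue
        d = dmat[row]
        row += 1
        j = int(np.argmin(d))  # first minimum = lowest tree_id on ties
        if d[j] <= max_distance_m:
            assigned.append(a_ids[j])
            dists.append(float(d[j]))
        else:
            assigned.append(None)
            dists.append(float(d[j]))
    return pd.DataFrame({
        "frame_id": frame_ids,
        "timestamp": [f[1] for f in frames],
        "lat": lats,
        "lon": lons,
        "tree_id": assigned,
        "distance_m": dists,
        "out_of_track": ~in_span,
    })


def aggregate_observations(
    assignments: pd.DataFrame,
    frame_results: dict[str, dict[str, float]],
    anchors: list[TreeAnchor],
    survey_date: str,
    statistic: str = "mean",
) -> list[TreeObservation]:
    """Roll assigned, non-degenerate frame results up to one row per tree.

    ``frame_results`` maps frame_id to a dict of index values (keys from
    ``INDEX_COLUMNS``; a ``degenerate`` key of True drops the frame).
    Trees with zero valid frames are omitted with a logged warning.
    """
    if statistic not in ("mean", "median"):
        raise ValueError(f"unknown aggregation statistic {statistic!r}")
    by_tree: dict[str, list[tuple[dict[str, float], float]]] = {}
    for rec in assignments.itertuples(index=False):
        if rec.tree_id is None:
            continue
        res = frame_results.get(rec.frame_id)
        if res is None or res.get("degenerate"):
            continue
        by_tree.setdefault(rec.tree_id, []).append((res, rec.distance_m))

    anchor_pos = {a.tree_id: (a.lat, a.lon) for a in anchors}
    agg = np.mean if statistic == "mean" else np.median
    out: list[TreeObservation] = []
    for tree_id in sorted(anchor_pos):
        contrib = by_tree.get(tree_id)
        if not contrib:
            logger.warning("tree %s: no valid frames on %s; omitted",
                           tree_id, survey_date)
            continue
        values = {}
        for col in INDEX_COLUMNS:
            vals = [r[col] for r, _ in contrib
                    if col in r and not math.isnan(r[col])]
            values[col] = float(agg(vals)) if vals else math.nan
        lat, lon = anchor_pos[tree_id]
        out.append(TreeObservation(
            tree_id=tree_id, survey_date=survey_date,
            n_frames=len(contrib),
            match_distance_m=float(np.mean([d for _, d in contrib])),
            lat=lat, lon=lon, **values,
        ))
    return out


def observations_to_frame(observations: list[TreeObservation]) -> pd.DataFrame:
    """Tabulate observations, one row per tree per survey date."""
    cols = ["tree_id", "survey_date", *INDEX_COLUMNS,
            "n_frames", "match_distance_m", "lat", "lon"]
    return pd.DataFrame([{c: getattr(o, c) for c in cols} for o in observations],
                        columns=cols)


# ---------------------------------------------------------------------------
# input readers

def read_anchors_csv(path: str | Path) -> list[TreeAnchor]:
    """Anchor table: CSV with columns tree_id, lat, lon."""
    df = pd.read_csv(path, dtype={"tree_id": str})
    missing = {"tree_id", "lat", "lon"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing anchor columns {sorted(missing)}")
    return [TreeAnchor(r.tree_id, float(r.lat), float(r.lon))
            for r in df.itertuples(index=False)]


def read_track(path: str | Path) -> list[TrackPoint]:
    """GPS track from CSV (timestamp, lat, lon) or a GPX 1.1 file."""
    path = Path(path)
    if path.suffix.lower() == ".gpx":
        return _read_gpx(path)
    df = pd.read_csv(path)
    missing = {"timestamp", "lat", "lon"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing track columns {sorted(missing)}")
    ts = pd.to_datetime(df["timestamp"], utc=True)
    return [TrackPoint(t.to_pydatetime(), float(la), float(lo))
            for t, la, lo in zip(ts, df["lat"], df["lon"])]


def _read_gpx(path: Path) -> list[TrackPoint]:
    ns = {"gpx": "http://www.topografix.com/GPX/1/1"}
    root = ET.parse(path).getroot()
    points = []
    for pt in root.iterfind(".//gpx:trkpt", ns):
        time_el = pt.find("gpx:time", ns)
        if time_el is None or time_el.text is None:
            raise ValueError(f"{path}: trackpoint without <time>")
        ts = datetime.fromisoformat(time_el.text.replace("Z", "+00:00"))
        points.append(TrackPoint(ts, float(pt.attrib["lat"]), float(pt.attrib["lon"])))
    if not points:
        raise ValueError(f"{path}: no trackpoints found")
    return points
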