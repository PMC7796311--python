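"""Synthetic survey scenes with known ground truth.

The field data behind this kind of survey are rarely shareable, so every
pipeline stage is exercised against generated inputs whose truth is known
in closed form.

Visible frames come from a Poisson Boolean disc model: foliage discs of
fixed radius placed by a homogeneous Poisson process whose intensity is set
so the expected gap fraction equals ``exp(-k * LAI)`` — the Beer-Lambert
relation the vision pipeline inverts.  Disc centres are sampled on a margin-
extended window so the gap fraction is stationary right up to the image
edge.  A Matern-style cluster process (Poisson parents, Gaussian-scattered
offspring discs, same expected disc count) produces clumped canopies whose
recovered clumping index falls below 1.

Thermal frames paint the same foliage mask with Gaussian leaf temperatures
over a uniform cold sky (default -40 °C, clear-sky apparent temperature,
far from the 0 °C segmentation cutoff).

``gen_survey`` assembles a full survey: anchors evenly spaced along a
straight route, a 1 Hz GPS track traversing it, visible + thermal frame
pairs timestamped at each anchor passage, and a 0.5 Hz micromet log.
Everything is seeded and bit-reproducible.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from datetime import datetime, timedelta, timezone
from pathlib import Path

import numpy as np
from PIL import Image

from .geomatch import TrackPoint, TreeAnchor
from .thermal import ThermalFrame, write_thermal_csv
from .vision import CanopyFrame

__all__ = [
    "SceneTruth",
    "gen_canopy_frame",
    "gen_thermal_frame",
    "gen_survey",
    "write_survey",
]

#: degrees of latitude per metre (Earth radius 6371 km)
DEG_PER_M = 1.0 / 111_195.0

TIMESTAMP_FMT = "%Y%m%dT%H%M%S%fZ"


@dataclass
class SceneTruth:
    """Ground truth recorded at generation time."""

    true_mask: np.ndarray          # H x W boolean, True = foliage
    true_lai: float
    true_gap_fraction: float       # closed form exp(-k * LAI)
    clustering: str                # "poisson" | "clustered"
    canopy_temp_mean: float = 28.0
    canopy_temp_sd: float = 1.0
    sky_temp: float = -40.0
    seed: int = 0


def _rasterize_discs(h: int, w: int, cx: np.ndarray, cy: np.ndarray,
                     r: float) -> np.ndarray:
    mask = np.zeros((h, w), dtype=bool)
    ri = int(math.ceil(r))
    for x, y in zip(cx, cy):
        x0, x1 = max(int(x) - ri, 0), min(int(x) + ri + 1, w)
        y0, y1 = max(int(y) - ri, 0), min(int(y) + ri + 1, h)
        if x0 >= x1 or y0 >= y1:
            continue
        yy, xx = np.ogrid[y0:y1, x0:x1]
        mask[y0:y1, x0:x1] |= (xx - x) ** 2 + (yy - y) ** 2 <= r * r
    return mask


def gen_canopy_frame(
    h: int,
    w: int,
    lai_target: float,
    k: float = 0.5,
    clustering: str = "poisson",
    seed: int = 0,
    disc_radius: float | None = None,
    cluster_mean_offspring: float = 25.0,
    cluster_sd_factor: float = 2.0,
    timestamp: datetime | None = None,
    position: tuple[float, float] | None = None,
) -> tuple[CanopyFrame, SceneTruth]:
    """Boolean-disc canopy frame with bimodal blue channel.

    Disc radius defaults to 2% of the image width — small relative to the
    5x5 gap-analysis blocks, so Poisson scenes are near-random at block
    scale.  Foliage pixels draw blue ~ N(60, 10), sky ~ N(220, 10), clipped
    to [0, 255]; red/green follow foliage-green and sky-grey tones (only
    blue enters the analysis).
    """
    if lai_target <= 0:
        raise ValueError(f"lai_target must be positive, got {lai_target}")
    gap = math.exp(-k * lai_target)
    if gap < 1e-6:
        raise ValueError(
            f"lai_target {lai_target} with k={k} implies gap fraction {gap:.2e} "
            "< 1e-6: saturated scene")
    if disc_radius is None:
        disc_radius = 0.02 * w
    r = float(disc_radius)
    rng = np.random.default_rng(seed)

    # intensity per unit area so that exp(-lambda * pi r^2) = exp(-k * LAI)
    lam = k * lai_target / (math.pi * r * r)
    if clustering == "poisson":
        margin = r
        area = (w + 2 * margin) * (h + 2 * margin)
        n = rng.poisson(lam * area)
        cx = rng.uniform(-margin, w + margin, n)
        cy = rng.uniform(-margin, h + margin, n)
    elif clustering == "clustered":
        sd = cluster_sd_factor * r
        margin = r + 3 * sd
        area = (w + 2 * margin) * (h + 2 * margin)
        lam_parent = lam / cluster_mean_offspring
        n_par = rng.poisson(lam_parent * area)
        px = rng.uniform(-margin, w + margin, n_par)
        py = rng.uniform(-margin, h + margin, n_par)
        counts = rng.poisson(cluster_mean_offspring, n_par)
        cx = np.repeat(px, counts) + rng.normal(0.0, sd, counts.sum())
        cy = np.repeat(py, counts) + rng.normal(0.0, sd, counts.sum())
    else:
        raise ValueError(f"unknown clustering {clustering!r}")

    foliage = _rasterize_discs(h, w, cx, cy, r)

    blue = np.where(foliage, rng.normal(60.0, 10.0, (h, w)),
                    rng.normal(220.0, 10.0, (h, w)))
    red = np.where(foliage, rng.normal(45.0, 10.0, (h, w)),
                   rng.normal(200.0, 10.0, (h, w)))
    green = np.where(foliage, rng.normal(80.0, 10.0, (h, w)),
                     rng.normal(210.0, 10.0, (h, w)))
    pixels = np.stack([red, green, blue], axis=-1)
    pixels = np.clip(np.rint(pixels), 0, 255).astype(np.uint8)

    frame = CanopyFrame(pixels=pixels, timestamp=timestamp, position=position)
    truth = SceneTruth(true_mask=foliage, true_lai=lai_target,
                       true_gap_fraction=gap, clustering=clustering, seed=seed)
    return frame, truth


def gen_thermal_frame(
    truth: SceneTruth,
    seed: int = 0,
    timestamp: datetime | None = None,
    position: tuple[float, float] | None = None,
    sky_cutoff: float = 0.0,
) -> ThermalFrame:
    """Thermal counterpart of a scene: Gaussian leaf temps over cold sky."""
    if truth.canopy_temp_mean <= sky_cutoff:
        raise ValueError(
            f"canopy_temp_mean {truth.canopy_temp_mean} °C at or below the "
            f"sky cutoff {sky_cutoff} °C would defeat segmentation")
    rng = np.random.default_rng(seed)
    h, w = truth.true_mask.shape
    temps = np.full((h, w), truth.sky_temp, dtype=float)
    n_leaf = int(truth.true_mask.sum())
    temps[truth.true_mask] = rng.normal(truth.canopy_temp_mean,
                                        truth.canopy_temp_sd, n_leaf)
    return ThermalFrame(temps=temps, timestamp=timestamp, position=position)


@dataclass
class SyntheticSurvey:
    """In-memory survey bundle: inputs plus per-tree ground truth."""

    anchors: list[TreeAnchor]
    track: list[TrackPoint]
    frames: list[tuple[str, datetime, CanopyFrame]]
    thermal_frames: list[tuple[str, datetime, ThermalFrame]]
    micromet: "pd.DataFrame"
    truth: dict


def gen_survey(
    n_trees: int = 20,
    route_length_m: float = 2520.0,
    frames_per_tree: int = 1,
    seed: int = 0,
    frame_size: tuple[int, int] = (120, 160),
    thermal_size: tuple[int, int] = (60, 90),
    speed_m_s: float = 7.0,
    start_lat: float = -37.8006,
    start_lon: float = 144.9573,
    anchor_offset_m: float = 8.0,
) -> SyntheticSurvey:
    """Generate a full synthetic survey along a straight northbound route.

    Anchors sit evenly spaced along the route, offset ``anchor_offset_m``
    east of the track (the nature strip).  The vehicle traverses at
    ``speed_m_s`` logging GPS at 1 Hz; ``frames_per_tree`` visible+thermal
    frame pairs are timestamped at 1 s cadence around each anchor passage.
    Micromet logs at 0.5 Hz.  Per-tree true LAI is uniform on [1, 4] and
    canopy temperature mean uniform on [24, 32] °C, a realistic street-tree
    spread for a warm survey day.
    """
    import pandas as pd

    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    rng = np.random.default_rng(seed)
    t0 = datetime(2016, 11, 17, 13, 0, 0, tzinfo=timezone.utc)

    duration = route_length_m / speed_m_s
    n_track = int(duration) + 1
    track = [
        TrackPoint(t0 + timedelta(seconds=i), start_lat + i * speed_m_s * DEG_PER_M,
                   start_lon)
        for i in range(n_track)
    ]

    cosd = math.cos(math.radians(start_lat))
    spacing = route_length_m / (n_trees + 1)
    anchors = []
    for i in range(n_trees):
        along = spacing * (i + 1)
        anchors.append(TreeAnchor(
            tree_id=f"T{i + 1:03d}",
            lat=start_lat + along * DEG_PER_M,
            lon=start_lon + anchor_offset_m * DEG_PER_M / cosd,
        ))

    hv, wv = frame_size
    ht, wt = thermal_size
    frames: list[tuple[str, datetime, CanopyFrame]] = []
    thermals: list[tuple[str, datetime, ThermalFrame]] = []
    truth_per_tree = {}
    for i, anchor in enumerate(anchors):
        true_lai = float(rng.uniform(1.0, 4.0))
        temp_mean = float(rng.uniform(24.0, 32.0))
        passage_s = round(spacing * (i + 1) / speed_m_s)
        truth_per_tree[anchor.tree_id] = {
            "true_lai": true_lai, "canopy_temp_mean": temp_mean,
        }
        for j in range(frames_per_tree):
            ts = t0 + timedelta(seconds=passage_s + j)
            stem = ts.strftime(TIMESTAMP_FMT)
            sub = int(rng.integers(0, 2**31 - 1))
            frame, truth = gen_canopy_frame(hv, wv, true_lai, seed=sub,
                                            timestamp=ts)
            frames.append((f"{stem}.png", ts, frame))
            _, t_truth = gen_canopy_frame(ht, wt, true_lai, seed=sub + 1,
                                          timestamp=ts)
            t_truth.canopy_temp_mean = temp_mean
            thermals.append((
                f"{stem}.csv", ts,
                gen_thermal_frame(t_truth, seed=sub + 2, timestamp=ts),
            ))

    met_times = np.arange(0.0, duration + 2.0, 2.0)  # 0.5 Hz
    micromet = pd.DataFrame({
        "timestamp": [(t0 + timedelta(seconds=float(s))).isoformat()
                      for s in met_times],
        "t_air_C": np.round(25.0 + 0.5 * np.sin(met_times / 600.0)
                            + rng.normal(0, 0.1, len(met_times)), 3),
        "rh_pct": np.round(50.0 + rng.normal(0, 1.0, len(met_times)), 2),
        "irradiance_Wm2": np.round(800.0 + rng.normal(0, 20.0, len(met_times)), 1),
    })

    truth = {
        "seed": seed, "n_trees": n_trees, "frames_per_tree": frames_per_tree,
        "route_length_m": route_length_m, "trees": truth_per_tree,
    }
    return SyntheticSurvey(anchors=anchors, track=track, frames=frames,
                           thermal_frames=thermals, micromet=micromet,
                           truth=truth)


def write_survey(survey: SyntheticSurvey, out_dir: str | Path) -> Path:
    """Write a survey to disk in the pipeline's input layout.

    Creates frames/*.png, thermal/*.csv, track.csv, anchors.csv,
    micromet.csv and truth.json under ``out_dir``.
    """
    import pandas as pd

    out = Path(out_dir)
    (out / "frames").mkdir(parents=True, exist_ok=True)
    (out / "thermal").mkdir(parents=True, exist_ok=True)

    for name, _, frame in survey.frames:
        Image.fromarray(frame.pixels).save(out / "frames" / name)
    for name, _, tf in survey.thermal_frames:
        write_thermal_csv(tf, out / "thermal" / name)

    pd.DataFrame({
        "timestamp": [p.timestamp.isoformat() for p in survey.track],
        "lat": [p.lat for p in survey.track],
        "lon": [p.lon for p in survey.track],
    }).to_csv(out / "track.csv", index=False)
    pd.DataFrame({
        "tree_id": [a.tree_id for a in survey.anchors],
        "lat": [a.lat for a in survey.anchors],
        "lon": [a.lon for a in survey.anchors],
    }).to_csv(out / "anchors.csv", index=False)
    survey.micromet.to_csv(out / "micromet.csv", index=False)
    (out / "truth.json").write_text(json.dumps(survey.truth, indent=1,
                                               sort_keys=True) + "\n")
    return out
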