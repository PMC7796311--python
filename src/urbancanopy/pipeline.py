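"""The survey pipeline: vision -> thermal -> matching -> aggregation -> maps.

``run_survey`` consumes a validated :class:`~urbancanopy.config.SurveyConfig`
and emits a per-tree observation CSV, an LAIe map (circle size = growth),
a TWSI map (circle color = water stress) and a run log.  Degenerate frames
(all sky, all canopy, too few thermal pixels) are excluded from per-tree
aggregation but never abort the run; only configuration or I/O failures do.
"""

from __future__ import annotations

import logging
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import geomatch, mapping, thermal, vision
from .config import SurveyConfig
from .synthetic import TIMESTAMP_FMT

__all__ = ["run_survey", "SurveyOutputs"]

logger = logging.getLogger(__name__)

FRAME_SUFFIXES = (".png", ".jpg", ".jpeg")


class SurveyOutputs:
    def __init__(self, observations: pd.DataFrame, csv_path: Path,
                 laie_geojson: Path, twsi_geojson: Path, log_path: Path,
                 counts: dict):
        self.observations = observations
        self.csv_path = csv_path
        self.laie_geojson = laie_geojson
        self.twsi_geojson = twsi_geojson
        self.log_path = log_path
        self.counts = counts


def _parse_stem(stem: str) -> datetime | None:
    for fmt in (TIMESTAMP_FMT, "%Y%m%dT%H%M%SZ"):
        try:
            return datetime.strptime(stem, fmt).replace(tzinfo=timezone.utc)
        except ValueError:
            continue
    try:
        return datetime.fromisoformat(stem).replace(tzinfo=timezone.utc)
    except ValueError:
        return None


def _timestamps_for(paths: list[Path], sidecar: Path) -> dict[str, datetime]:
    """Timestamp per filename: ISO-8601 stems, or a sidecar CSV of
    (filename, timestamp)."""
    if sidecar.exists():
        df = pd.read_csv(sidecar)
        ts = pd.to_datetime(df["timestamp"], utc=True)
        return {str(f): t.to_pydatetime() for f, t in zip(df["filename"], ts)}
    out = {}
    for p in paths:
        t = _parse_stem(p.stem)
        if t is None:
            raise ValueError(
                f"{p.name}: filename stem is not a timestamp and no "
                f"sidecar {sidecar.name} exists")
        out[p.name] = t
    return out


def _nearest_row(df: pd.DataFrame, when: datetime) -> pd.Series:
    times = pd.to_datetime(df["timestamp"], utc=True, format="ISO8601")
    i = (times - pd.Timestamp(when)).abs().argmin()
    return df.iloc[int(i)]


def run_survey(cfg: SurveyConfig) -> SurveyOutputs:
    """Execute the full pipeline for one survey date.

    Raises a descriptive error before any processing when inputs are
    missing or empty; degenerate frames only reduce coverage.
    """
    frame_paths = sorted(p for p in cfg.frames_dir.iterdir()
                         if p.suffix.lower() in FRAME_SUFFIXES)
    thermal_paths = sorted(cfg.thermal_dir.glob("*.csv"))
    thermal_paths = [p for p in thermal_paths if p.name != "timestamps.csv"]
    if not frame_paths and not thermal_paths:
        raise FileNotFoundError(
            f"no visible frames in {cfg.frames_dir} and no thermal frames in "
            f"{cfg.thermal_dir}")

    cfg.output_dir.mkdir(parents=True, exist_ok=True)
    log_path = cfg.output_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("urbancanopy")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    try:
        return _run(cfg, frame_paths, thermal_paths, log_path)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(cfg: SurveyConfig, frame_paths: list[Path],
         thermal_paths: list[Path], log_path: Path) -> SurveyOutputs:
    anchors = geomatch.read_anchors_csv(cfg.anchors)
    track = geomatch.read_track(cfg.track)
    micromet = pd.read_csv(cfg.micromet) if cfg.micromet else None

    vis_ts = _timestamps_for(frame_paths, cfg.frames_dir / "timestamps.csv")
    th_ts = _timestamps_for(thermal_paths, cfg.thermal_dir / "timestamps.csv")

    n_degenerate = 0

    # --- vision ---------------------------------------------------------
    vision_results: dict[str, dict] = {}
    for p in frame_paths:
        px = np.asarray(Image.open(p).convert("RGB"))
        frame = vision.CanopyFrame(pixels=px, timestamp=vis_ts[p.name])
        _, ga, arch = vision.analyze_frame(
            frame, k=cfg.vision.k, large_gap_fraction=cfg.vision.large_gap_fraction,
            smoothing_width=cfg.vision.smoothing_width, invert=cfg.vision.invert,
            blue_channel=cfg.vision.blue_channel)
        if arch.degenerate:
            n_degenerate += 1
            logger.info("frame %s degenerate: %s", p.name, arch.reason)
            continue
        vision_results[p.name] = {
            "lai": arch.lai, "omega0": arch.omega0, "laie": arch.laie,
        }
        logger.info("frame %s: lai=%.3f omega0=%.3f laie=%.3f",
                    p.name, arch.lai, arch.omega0, arch.laie)

    # --- thermal --------------------------------------------------------
    thermal_results: dict[str, dict] = {}
    for p in thermal_paths:
        tf = thermal.read_thermal_csv(p, timestamp=th_ts[p.name])
        ct = thermal.segment_canopy(
            tf, sky_cutoff=cfg.thermal.sky_cutoff,
            min_pixel_fraction=cfg.thermal.min_pixel_fraction,
            statistic=cfg.thermal.statistic)
        if not ct.valid:
            n_degenerate += 1
            logger.info("thermal %s invalid: %s", p.name, ct.reason)
            continue
        t_air = None
        if micromet is not None:
            row = _nearest_row(micromet, th_ts[p.name])
            t_air = float(row["t_air_C"])
        if cfg.thermal.reference_method == "energy_balance":
            rh = float(row["rh_pct"]) / 100.0
            met = thermal.MicrometState(
                t_air=t_air, rh=rh, r_ni=float(row["irradiance_Wm2"]),
                r_aw=cfg.thermal.r_aw, r_hr=cfg.thermal.r_hr,
                gamma=cfg.thermal.gamma)
            refs = thermal.reference_temps_energy_balance(met)
        else:
            try:
                refs = thermal.reference_temps_percentile(
                    ct, p_wet=cfg.thermal.p_wet, p_dry=cfg.thermal.p_dry)
            except thermal.InsufficientDataError as exc:
                n_degenerate += 1
                logger.info("thermal %s: %s", p.name, exc)
                continue
        ws = thermal.water_status(ct.t_canopy, refs, t_air=t_air)
        if ws.degenerate:
            n_degenerate += 1
            logger.info("thermal %s degenerate: %s", p.name, ws.reason)
            continue
        thermal_results[p.name] = {
            "twsi": ws.twsi, "ig": ws.ig, "td": ws.td, "t_canopy": ws.t_canopy,
        }
        logger.info("thermal %s: t_canopy=%.2f twsi=%.3f ig=%.3f",
                    p.name, ws.t_canopy, ws.twsi, ws.ig)

    # --- pair modalities into frame events ------------------------------
    # a visible frame adopts the nearest thermal frame within tolerance;
    # unpaired frames of either kind still contribute their own indices
    events: dict[str, dict] = {}
    th_items = sorted(th_ts.items(), key=lambda kv: kv[1])
    used_thermal: set[str] = set()
    for name, res in vision_results.items():
        ev = dict(res)
        ts = vis_ts[name]
        best, best_dt = None, cfg.thermal.pair_tolerance_s
        for tname, tts in th_items:
            dt = abs((tts - ts).total_seconds())
            if dt <= best_dt and tname in thermal_results:
                best, best_dt = tname, dt
        if best is not None:
            ev.update(thermal_results[best])
            used_thermal.add(best)
        events[name] = ev
    for tname, res in thermal_results.items():
        if tname not in used_thermal:
            events[f"thermal:{tname}"] = dict(res)

    frames = []
    for fid in events:
        ts = vis_ts[fid] if fid in vis_ts else th_ts[fid.removeprefix("thermal:")]
        frames.append((fid, ts))
    frames.sort(key=lambda f: (f[1], f[0]))
    if not frames:
        raise RuntimeError("every frame was degenerate; nothing to aggregate")

    assignments = geomatch.match_frames_to_trees(
        track, frames, anchors, max_distance_m=cfg.matching.max_distance_m)
    n_unassigned = int(assignments["tree_id"].isna().sum())

    survey_date = cfg.survey_date or frames[0][1].date().isoformat()
    observations = geomatch.aggregate_observations(
        assignments, events, anchors, survey_date,
        statistic=cfg.matching.statistic)
    if not observations:
        raise RuntimeError("no tree received a valid frame")
    by_tree: dict[str, list[str]] = {}
    for rec in assignments.itertuples(index=False):
        if rec.tree_id is not None:
            by_tree.setdefault(rec.tree_id, []).append(rec.frame_id)
    for obs in observations:
        logger.info("tree %s: n_frames=%d from %s", obs.tree_id, obs.n_frames,
                    by_tree.get(obs.tree_id, []))

    df = geomatch.observations_to_frame(observations)
    csv_path = cfg.output_dir / "observations.csv"
    df.to_csv(csv_path, index=False, float_format="%.6f")

    laie_spec = mapping.MapLayerSpec(
        variable="laie", size_scale=cfg.maps.laie_size_scale,
        colors=list(mapping.LAIE_RAMP[0]), radius_mode=cfg.maps.radius_mode,
        title="Effective LAI", date=survey_date)
    twsi_spec = mapping.MapLayerSpec(
        variable="twsi", size_scale=cfg.maps.twsi_size_scale,
        colors=list(mapping.TWSI_RAMP[0]), breaks=list(mapping.TWSI_RAMP[1]),
        title="Tree water stress index", date=survey_date)
    laie_geojson = cfg.output_dir / "map_laie.geojson"
    twsi_geojson = cfg.output_dir / "map_twsi.geojson"
    mapping.render_survey_map(observations, laie_spec, laie_geojson,
                              cfg.output_dir / "map_laie.html")
    mapping.render_survey_map(observations, twsi_spec, twsi_geojson,
                              cfg.output_dir / "map_twsi.html")

    counts = {
        "frames_read": len(frame_paths) + len(thermal_paths),
        "degenerate": n_degenerate,
        "unassigned": n_unassigned,
        "trees_observed": len(observations),
    }
    logger.info("survey complete: %s", counts)
    return SurveyOutputs(df, csv_path, laie_geojson, twsi_geojson, log_path,
                         counts)
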