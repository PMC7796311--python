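"""Survey map rendering: geo-located circles per tree.

Two standard layers: circle *size* scaled by effective LAI (growth) and
circle *color* scaled by TWSI (water stress).  Output is a GeoJSON
FeatureCollection (RFC 7946, WGS84 lon-lat) with one Point feature per tree
observation carrying all index properties plus the computed radius and
color, and an optional standalone HTML viewer that draws the circles on an
equirectangular SVG canvas (self-contained, no tiles).
"""

from __future__ import annotations

import json
import logging
from bisect import bisect_left
from dataclasses import dataclass, field
from pathlib import Path

from .geomatch import TreeObservation

__all__ = [
    "MapLayerSpec",
    "scale_radius",
    "color_for_value",
    "render_survey_map",
    "TWSI_RAMP",
    "LAIE_RAMP",
]

logger = logging.getLogger(__name__)

# green -> red, perceptually ordered for stress
TWSI_RAMP = (
    ["#1a9850", "#91cf60", "#d9ef8b", "#fee08b", "#fc8d59", "#d73027"],
    [1 / 6, 2 / 6, 3 / 6, 4 / 6, 5 / 6],
)
# viridis-like, dark -> bright for growth
LAIE_RAMP = (
    ["#440154", "#414487", "#2a788e", "#22a884", "#7ad151", "#fde725"],
    None,  # breakpoints computed from the survey's value range
)


@dataclass
class MapLayerSpec:
    """How one variable is drawn: circle sizes and a color ramp.

    ``colors`` has one more entry than ``breaks``; value v gets color i
    where i is the first break >= v (right-closed intervals), the last
    color when v exceeds every break.
    """

    variable: str
    size_scale: tuple[float, float] = (2.0, 10.0)  # min/max radius, metres
    colors: list[str] = field(default_factory=lambda: list(TWSI_RAMP[0]))
    breaks: list[float] | None = None
    title: str = ""
    date: str = ""
    radius_mode: str = "linear"  # or "area" (radius ~ sqrt of value)

    def __post_init__(self) -> None:
        rmin, rmax = self.size_scale
        if not rmin < rmax:
            raise ValueError(f"size_scale must satisfy min < max, got {self.size_scale}")
        if self.breaks is not None:
            if len(self.breaks) != len(self.colors) - 1:
                raise ValueError("need exactly len(colors) - 1 breakpoints")
            if any(b2 <= b1 for b1, b2 in zip(self.breaks, self.breaks[1:])):
                raise ValueError("breakpoints must be strictly increasing")


def scale_radius(
    value: float,
    value_range: tuple[float, float],
    size_scale: tuple[float, float],
    mode: str = "linear",
) -> float:
    """Map a value linearly onto [min_radius, max_radius].

    A zero-width value range puts every circle at the midpoint radius (with
    a logged warning).  ``mode="area"`` makes circle *area* proportional
    instead (radius grows with the square root of the scaled value).
    """
    vmin, vmax = value_range
    rmin, rmax = size_scale
    if vmax <= vmin:
        logger.warning("zero-width value range %s; all circles at midpoint radius",
                       value_range)
        return (rmin + rmax) / 2
    frac = (value - vmin) / (vmax - vmin)
    frac = min(max(frac, 0.0), 1.0)
    if mode == "area":
        frac = frac ** 0.5
    elif mode != "linear":
        raise ValueError(f"unknown radius mode {mode!r}")
    return rmin + frac * (rmax - rmin)


def color_for_value(value: float, breaks: list[float], colors: list[str]) -> str:
    """Pure bisection color lookup over right-closed intervals."""
    return colors[bisect_left(breaks, value)]


def _auto_breaks(values: list[float], n_colors: int) -> list[float]:
    vmin, vmax = min(values), max(values)
    if vmax <= vmin:
        vmax = vmin + 1.0
    step = (vmax - vmin) / n_colors
    return [vmin + step * i for i in range(1, n_colors)]


def render_survey_map(
    observations: list[TreeObservation],
    spec: MapLayerSpec,
    out_geojson: str | Path,
    out_html: str | Path | None = None,
) -> dict:
    """Write the GeoJSON layer (and optional HTML viewer) for one variable.

    One Point feature per observation; properties carry every index, the
    computed ``radius_m`` and ``color``.  Output bytes are deterministic
    for identical inputs (sorted keys, fixed float formatting).
    """
    if not observations:
        raise ValueError("cannot render a map with no observations")
    values = [getattr(o, spec.variable) for o in observations]
    finite = [v for v in values if v == v]
    if not finite:
        raise ValueError(f"no finite values of {spec.variable!r} to map")
    vrange = (min(finite), max(finite))
    breaks = spec.breaks if spec.breaks is not None else _auto_breaks(
        finite, len(spec.colors))

    features = []
    for obs, val in zip(observations, values):
        radius = scale_radius(val, vrange, spec.size_scale, mode=spec.radius_mode)
        color = color_for_value(val, breaks, spec.colors) if val == val else "#999999"
        props = {
            "tree_id": obs.tree_id,
            "survey_date": obs.survey_date,
            "laie": _num(obs.laie),
            "lai": _num(obs.lai),
            "omega0": _num(obs.omega0),
            "twsi": _num(obs.twsi),
            "ig": _num(obs.ig),
            "td": _num(obs.td),
            "t_canopy": _num(obs.t_canopy),
            "n_frames": obs.n_frames,
            "variable": spec.variable,
            "value": _num(val),
            "radius_m": round(radius, 6),
            "color": color,
        }
        features.append({
            "type": "Feature",
            "geometry": {"type": "Point",
                         "coordinates": [round(obs.lon, 8), round(obs.lat, 8)]},
            "properties": props,
        })
    collection = {
        "type": "FeatureCollection",
        "title": spec.title or f"{spec.variable} {spec.date}".strip(),
        "features": features,
    }
    text = json.dumps(collection, sort_keys=True, indent=1)
    Path(out_geojson).write_text(text + "\n")
    if out_html is not None:
        Path(out_html).write_text(_render_html(collection, spec))
    return collection


def _num(v: float) -> float | None:
    # GeoJSON has no NaN; degenerate indices serialize as null
    if isinstance(v, float) and v != v:
        return None
    return round(float(v), 6) if isinstance(v, float) else v


def _render_html(collection: dict, spec: MapLayerSpec) -> str:
    """Self-contained SVG viewer: equirectangular projection, hover titles."""
    feats = collection["features"]
    lons = [f["geometry"]["coordinates"][0] for f in feats]
    lats = [f["geometry"]["coordinates"][1] for f in feats]
    pad = 1e-4
    lon0, lon1 = min(lons) - pad, max(lons) + pad
    lat0, lat1 = min(lats) - pad, max(lats) + pad
    width, height = 700.0, 900.0

    def sx(lon: float) -> float:
        return (lon - lon0) / (lon1 - lon0) * width

    def sy(lat: float) -> float:
        return (lat1 - lat) / (lat1 - lat0) * height

    # metres-per-degree at the map centre fixes the radius scale
    mid_lat = (lat0 + lat1) / 2
    px_per_m = width / ((lon1 - lon0) * 111_195.0 * _cosd(mid_lat))
    circles = []
    for f in feats:
        p = f["properties"]
        lon, lat = f["geometry"]["coordinates"]
        r = max(p["radius_m"] * px_per_m, 2.0)
        val = p["value"]
        title = f"{p['tree_id']}: {spec.variable}={val}"
        circles.append(
            f'<circle cx="{sx(lon):.1f}" cy="{sy(lat):.1f}" r="{r:.1f}" '
            f'fill="{p["color"]}" fill-opacity="0.8" stroke="#333" '
            f'stroke-width="0.5"><title>{title}</title></circle>'
        )
    legend = "".join(
        f'<rect x="10" y="{20 + 18 * i}" width="14" height="14" fill="{c}"/>'
        for i, c in enumerate(spec.colors)
    )
    title = collection.get("title", spec.variable)
    return (
        "<!DOCTYPE html>\n<html><head><meta charset='utf-8'>"
        f"<title>{title}</title></head><body>"
        f"<h3>{title}</h3>"
        f'<svg width="{width:.0f}" height="{height:.0f}" '
        'style="background:#f4f4f0;border:1px solid #ccc">'
        + legend + "".join(circles) + "</svg></body></html>\n"
    )


def _cosd(deg: float) -> float:
    import math
    return math.cos(math.radians(deg))
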