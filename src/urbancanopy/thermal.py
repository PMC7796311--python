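"""Thermal-infrared canopy analysis: segmentation, references, stress indices.

Radiometric thermal cameras export per-pixel temperature matrices (°C) as
plain CSV.  Against a clear sky the apparent sky temperature is far below
zero, so a simple cutoff (default 0 °C) separates leaf material from sky.
The canopy temperature ``T_canopy`` aggregated over the leaf mask is
normalized between two reference temperatures,

    TWSI = (T_canopy - T_wet) / (T_dry - T_wet),

where ``T_wet`` is a fully transpiring surface and ``T_dry`` a
non-transpiring one.  The conductance-proportional thermal index is

    Ig = (T_dry - T_canopy) / (T_canopy - T_wet),

and temperature depression is ``TD = T_canopy - T_air``.

References are obtained two ways, selectable per survey:

* percentile: T_wet / T_dry as low/high percentiles (default 5th / 95th)
  of the canopy pixel-temperature distribution;
* energy balance, from micrometeorology:

      T_dry = T_air + r_HR * R_ni / (rho * c_p)
      T_wet = T_air + [r_HR * r_aw * gamma * R_ni / (rho * c_p)
                       - r_HR * delta_e] / (gamma * r_aw + s * r_HR)

  with R_ni the net isothermal radiation, r_aw the boundary-layer
  resistance to water vapour, r_HR the parallel resistance to heat and
  radiative transfer, gamma the psychrometric constant, s the slope of the
  saturation vapour pressure curve at T_air, and delta_e the vapour
  pressure deficit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import datetime
from pathlib import Path

import numpy as np

__all__ = [
    "ThermalFrame",
    "CanopyTemperature",
    "ReferenceTemperatures",
    "MicrometState",
    "WaterStatusResult",
    "ThermalParseError",
    "InsufficientDataError",
    "read_thermal_csv",
    "write_thermal_csv",
    "segment_canopy",
    "reference_temps_percentile",
    "saturation_vp",
    "svp_slope",
    "vpd",
    "reference_temps_energy_balance",
    "compute_twsi",
    "compute_ig",
    "compute_td",
    "water_status",
]

PLAUSIBLE_RANGE_C = (-60.0, 80.0)

# dry air at standard pressure
GAS_CONSTANT_DRY_AIR = 287.05  # J kg-1 K-1
STANDARD_PRESSURE_PA = 101325.0
CP_AIR = 1005.0  # J kg-1 K-1


class ThermalParseError(ValueError):
    """Malformed radiometric CSV (ragged or non-numeric), located by cell."""


class InsufficientDataError(ValueError):
    """Too few canopy pixels to estimate a temperature distribution."""


@dataclass
class ThermalFrame:
    """Per-pixel radiometric temperature grid in °C."""

    temps: np.ndarray
    timestamp: datetime | None = None
    position: tuple[float, float] | None = None
    range_violation: bool = False

    def __post_init__(self) -> None:
        t = np.asarray(self.temps, dtype=float)
        if t.ndim != 2:
            raise ValueError(f"expected a 2-D temperature grid, got shape {t.shape}")
        if not np.all(np.isfinite(t)):
            raise ValueError("temperature grid contains non-finite values")
        lo, hi = PLAUSIBLE_RANGE_C
        self.range_violation = bool((t < lo).any() or (t > hi).any())
        self.temps = t


@dataclass
class CanopyTemperature:
    """Leaf-material mask and aggregate canopy temperature for one frame."""

    mask: np.ndarray
    t_canopy: float
    pixel_temps: np.ndarray
    n_pixels: int
    valid: bool
    reason: str = ""


@dataclass
class ReferenceTemperatures:
    """Wet/dry reference surface temperatures (°C) and how they were derived."""

    t_wet: float
    t_dry: float
    method: str  # "percentile" | "energy_balance"
    degenerate: bool = False
    reason: str = ""


@dataclass
class MicrometState:
    """Micrometeorological inputs to the energy-balance references.

    Resistances are survey-level inputs (no wind profile is measured);
    defaults of 50 and 30 s m-1 are typical broadleaf values.  ``rho`` and
    ``cp`` default from air temperature at standard pressure; ``s_slope``
    and ``delta_e`` from the Tetens saturation vapour pressure curve.
    """

    t_air: float                  # °C
    rh: float                     # fraction 0-1
    r_ni: float                   # net isothermal radiation, W m-2
    r_aw: float = 50.0            # boundary-layer resistance to vapour, s m-1
    r_hr: float = 30.0            # parallel heat/radiative resistance, s m-1
    gamma: float = 66.0           # psychrometric constant, Pa K-1
    rho: float | None = None      # air density, kg m-3
    cp: float = CP_AIR            # specific heat of air, J kg-1 K-1
    s_slope: float | None = None  # d es/dT at t_air, Pa K-1
    delta_e: float | None = None  # vapour pressure deficit, Pa

    def __post_init__(self) -> None:
        if not 0.0 <= self.rh <= 1.0:
            raise ValueError(f"relative humidity {self.rh} outside [0, 1]")
        if self.rho is None:
            self.rho = STANDARD_PRESSURE_PA / (
                GAS_CONSTANT_DRY_AIR * (self.t_air + 273.15)
            )
        if self.s_slope is None:
            self.s_slope = svp_slope(self.t_air)
        if self.delta_e is None:
            self.delta_e = vpd(self.t_air, self.rh)
        if self.rho <= 0 or self.cp <= 0 or self.gamma <= 0:
            raise ValueError("rho, cp and gamma must be positive")
        if self.delta_e < 0:
            raise ValueError("vapour pressure deficit cannot be negative")


@dataclass
class WaterStatusResult:
    """TWSI, Ig and temperature depression for one frame."""

    twsi: float
    ig: float
    td: float
    t_canopy: float
    t_wet: float
    t_dry: float
    clamped: bool = False
    degenerate: bool = False
    reason: str = ""


# ---------------------------------------------------------------------------
# radiometric CSV I/O

def read_thermal_csv(
    path: str | Path,
    timestamp: datetime | None = None,
    position: tuple[float, float] | None = None,
) -> ThermalFrame:
    """Parse a radiometric CSV matrix (one row per pixel row, values in °C).

    A single non-numeric header line is auto-detected and skipped.  Ragged
    rows or non-numeric cells raise :class:`ThermalParseError` naming the
    offending row and column.
    """
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ThermalParseError(f"{path}: empty file")

    start = 0
    try:
        float(lines[0].split(",")[0])
    except ValueError:
        start = 1  # header line
    if start == len(lines):
        raise ThermalParseError(f"{path}: no data rows")

    rows: list[list[float]] = []
    width: int | None = None
    for i, line in enumerate(lines[start:], start=start + 1):
        cells = line.split(",")
        if width is None:
            width = len(cells)
        elif len(cells) != width:
            raise ThermalParseError(
                f"{path}: row {i} has {len(cells)} cells, expected {width}"
            )
        row = []
        for j, cell in enumerate(cells, start=1):
            try:
                row.append(float(cell))
            except ValueError:
                raise ThermalParseError(
                    f"{path}: non-numeric cell at row {i}, column {j}: {cell!r}"
                ) from None
        rows.append(row)
    return ThermalFrame(temps=np.array(rows), timestamp=timestamp, position=position)


def write_thermal_csv(frame: ThermalFrame, path: str | Path) -> None:
    """Write the grid back as CSV; float repr guarantees a value-exact round trip."""
    path = Path(path)
    with path.open("w") as fh:
        for row in frame.temps:
            fh.write(",".join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# segmentation and references

def segment_canopy(
    frame: ThermalFrame,
    sky_cutoff: float = 0.0,
    min_pixel_fraction: float = 0.05,
    statistic: str = "mean",
) -> CanopyTemperature:
    """Separate leaf material from sky by temperature cutoff.

    A pixel is canopy iff its temperature strictly exceeds ``sky_cutoff``
    (clear sky radiates tens of degrees below zero, so 0 °C is a robust
    default).  Frames whose canopy mask covers less than
    ``min_pixel_fraction`` of the pixels are flagged invalid.
    ``statistic`` selects the T_canopy aggregate: ``"mean"`` (default) or
    ``"median"`` (robust to residual sky).
    """
    mask = frame.temps > sky_cutoff
    temps = frame.temps[mask]
    n = int(mask.sum())
    if n < min_pixel_fraction * frame.temps.size:
        return CanopyTemperature(
            mask=mask, t_canopy=math.nan, pixel_temps=temps, n_pixels=n,
            valid=False,
            reason=f"only {n} canopy pixels (< {min_pixel_fraction:.0%} of frame)",
        )
    if statistic == "mean":
        t_canopy = float(temps.mean())
    elif statistic == "median":
        t_canopy = float(np.median(temps))
    else:
        raise ValueError(f"unknown aggregation statistic {statistic!r}")
    return CanopyTemperature(mask=mask, t_canopy=t_canopy, pixel_temps=temps,
                             n_pixels=n, valid=True)


def reference_temps_percentile(
    ct: CanopyTemperature, p_wet: float = 5.0, p_dry: float = 95.0
) -> ReferenceTemperatures:
    """Statistical references from the canopy temperature distribution.

    T_wet / T_dry are the ``p_wet``-th / ``p_dry``-th percentiles of masked
    pixel temperatures (linear interpolation between order statistics).
    A spread of zero (constant-temperature canopy) is flagged degenerate.
    """
    if ct.pixel_temps.size < 20:
        raise InsufficientDataError(
            f"{ct.pixel_temps.size} canopy pixels; need at least 20 for "
            "percentile references"
        )
    t_wet = float(np.percentile(ct.pixel_temps, p_wet))
    t_dry = float(np.percentile(ct.pixel_temps, p_dry))
    if not t_dry > t_wet:
        return ReferenceTemperatures(
            t_wet=t_wet, t_dry=t_dry, method="percentile", degenerate=True,
            reason="t_dry <= t_wet (no spread in canopy temperatures)",
        )
    return ReferenceTemperatures(t_wet=t_wet, t_dry=t_dry, method="percentile")


# ---------------------------------------------------------------------------
# psychrometrics (Tetens form)

def saturation_vp(t: float) -> float:
    """Saturation vapour pressure over water, Pa (Tetens), for t in °C."""
    if not -40.0 <= t <= 60.0:
        raise ValueError(f"temperature {t} °C outside supported range [-40, 60]")
    return 610.78 * math.exp(17.27 * t / (t + 237.3))


def svp_slope(t: float) -> float:
    """Analytic derivative of the Tetens curve, Pa K-1."""
    return saturation_vp(t) * 17.27 * 237.3 / (t + 237.3) ** 2


def vpd(t: float, rh: float) -> float:
    """Vapour pressure deficit es(t) * (1 - rh), Pa."""
    if not 0.0 <= rh <= 1.0:
        raise ValueError(f"relative humidity {rh} outside [0, 1]")
    return saturation_vp(t) * (1.0 - rh)


def reference_temps_energy_balance(met: MicrometState) -> ReferenceTemperatures:
    """Leaf energy-balance wet/dry references from micrometeorology.

    A dry surface sheds all absorbed net radiation as sensible heat; a wet
    surface additionally cools evaporatively against the vapour pressure
    deficit.  Both collapse to T_air as R_ni -> 0 and delta_e -> 0.
    """
    denom = met.gamma * met.r_aw + met.s_slope * met.r_hr
    if denom == 0:
        raise ValueError("gamma*r_aw + s*r_hr is zero: unphysical inputs")
    heat = met.r_hr * met.r_ni / (met.rho * met.cp)
    t_dry = met.t_air + heat
    t_wet = met.t_air + (met.gamma * met.r_aw * heat - met.r_hr * met.delta_e) / denom
    degenerate = not t_dry > t_wet
    return ReferenceTemperatures(
        t_wet=t_wet, t_dry=t_dry, method="energy_balance",
        degenerate=degenerate,
        reason="t_dry <= t_wet under given micromet" if degenerate else "",
    )


# ---------------------------------------------------------------------------
# stress indices

def compute_twsi(
    t_canopy: float, refs: ReferenceTemperatures
) -> tuple[float, bool]:
    """Normalized canopy temperature, clamped to [0, 1].

    Returns (twsi, clamped).  Field frames routinely fall outside the
    reference interval; clamping with a flag preserves the 0-1 contract.
    """
    if not refs.t_dry > refs.t_wet:
        return math.nan, False
    raw = (t_canopy - refs.t_wet) / (refs.t_dry - refs.t_wet)
    clamped = raw < 0.0 or raw > 1.0
    return min(max(raw, 0.0), 1.0), clamped


def compute_ig(t_canopy: float, refs: ReferenceTemperatures) -> float:
    """Conductance-proportional index (T_dry - Tc) / (Tc - T_wet).

    0 at the closed-stomata limit (Tc = T_dry), growing without bound as
    the canopy approaches the wet reference.  NaN when Tc <= T_wet.
    """
    if not refs.t_dry > refs.t_wet or t_canopy <= refs.t_wet:
        return math.nan
    return (refs.t_dry - t_canopy) / (t_canopy - refs.t_wet)


def compute_td(t_canopy: float, t_air: float) -> float:
    """Temperature depression Tc - Tair (°C); positive = canopy above air."""
    return t_canopy - t_air


def water_status(
    t_canopy: float, refs: ReferenceTemperatures, t_air: float | None = None
) -> WaterStatusResult:
    """Bundle TWSI, Ig and TD for one frame, carrying degeneracy flags."""
    twsi, clamped = compute_twsi(t_canopy, refs)
    ig = compute_ig(t_canopy, refs)
    td = compute_td(t_canopy, t_air) if t_air is not None else math.nan
    degenerate = refs.degenerate or math.isnan(twsi)
    return WaterStatusResult(
        twsi=twsi, ig=ig, td=td, t_canopy=t_canopy,
        t_wet=refs.t_wet, t_dry=refs.t_dry, clamped=clamped,
        degenerate=degenerate, reason=refs.reason if degenerate else "",
    )
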