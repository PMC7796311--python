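"""Survey configuration: a single declarative YAML file with sections.

Minimal config needs only the paths; every analysis parameter has a
documented default.  Validation collects *all* violations before raising,
so a bad file is fixed in one pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["SurveyConfig", "ConfigError", "validate_config"]


class ConfigError(ValueError):
    """Invalid configuration; message lists every violation found."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(violations))


@dataclass
class VisionParams:
    k: float = 0.5                   # Beer-Lambert extinction coefficient
    large_gap_fraction: float = 0.75
    smoothing_width: int = 5         # histogram moving-average width, bins
    blue_channel: int = 2
    invert: bool = False             # flip canopy/sky polarity (overcast scenes)


@dataclass
class ThermalParams:
    sky_cutoff: float = 0.0          # °C; canopy iff T > cutoff
    reference_method: str = "percentile"  # or "energy_balance"
    p_wet: float = 5.0
    p_dry: float = 95.0
    r_aw: float = 50.0               # s m-1
    r_hr: float = 30.0               # s m-1
    gamma: float = 66.0              # Pa K-1
    min_pixel_fraction: float = 0.05
    statistic: str = "mean"          # T_canopy aggregate
    pair_tolerance_s: float = 1.0    # visible<->thermal timestamp pairing


@dataclass
class MatchingParams:
    max_distance_m: float = 25.0
    statistic: str = "mean"          # per-tree aggregation


@dataclass
class MapParams:
    laie_size_scale: tuple[float, float] = (2.0, 10.0)
    twsi_size_scale: tuple[float, float] = (4.0, 4.001)  # near-constant size
    radius_mode: str = "linear"


@dataclass
class SurveyConfig:
    frames_dir: Path
    thermal_dir: Path
    track: Path
    anchors: Path
    output_dir: Path
    micromet: Path | None = None
    survey_date: str = ""
    vision: VisionParams = field(default_factory=VisionParams)
    thermal: ThermalParams = field(default_factory=ThermalParams)
    matching: MatchingParams = field(default_factory=MatchingParams)
    maps: MapParams = field(default_factory=MapParams)


_SECTIONS = {
    "vision": VisionParams,
    "thermal": ThermalParams,
    "matching": MatchingParams,
    "maps": MapParams,
}
_PATH_KEYS = ("frames_dir", "thermal_dir", "track", "anchors", "micromet",
              "output_dir")
_TOP_KEYS = set(_PATH_KEYS) | set(_SECTIONS) | {"survey_date"}


def _range_checks(cfg: SurveyConfig) -> list[str]:
    v: list[str] = []
    if cfg.vision.k <= 0:
        v.append(f"vision.k must be > 0, got {cfg.vision.k}")
    if not 0.0 < cfg.vision.large_gap_fraction < 1.0:
        v.append("vision.large_gap_fraction must be in (0, 1), got "
                 f"{cfg.vision.large_gap_fraction}")
    if cfg.vision.smoothing_width < 1:
        v.append("vision.smoothing_width must be >= 1")
    if cfg.vision.blue_channel not in (0, 1, 2):
        v.append(f"vision.blue_channel must be 0, 1 or 2, got {cfg.vision.blue_channel}")
    if cfg.thermal.reference_method not in ("percentile", "energy_balance"):
        v.append("thermal.reference_method must be 'percentile' or "
                 f"'energy_balance', got {cfg.thermal.reference_method!r}")
    if not 0.0 <= cfg.thermal.p_wet < cfg.thermal.p_dry <= 100.0:
        v.append("thermal percentiles must satisfy 0 <= p_wet < p_dry <= 100")
    if cfg.thermal.r_aw <= 0 or cfg.thermal.r_hr <= 0 or cfg.thermal.gamma <= 0:
        v.append("thermal resistances and gamma must be positive")
    if cfg.thermal.statistic not in ("mean", "median"):
        v.append(f"thermal.statistic must be mean|median, got {cfg.thermal.statistic!r}")
    if cfg.matching.max_distance_m <= 0:
        v.append("matching.max_distance_m must be positive")
    if cfg.matching.statistic not in ("mean", "median"):
        v.append("matching.statistic must be mean|median")
    if cfg.thermal.reference_method == "energy_balance" and cfg.micromet is None:
        v.append("energy_balance references require a micromet log")
    return v


def validate_config(source: str | Path | dict) -> SurveyConfig:
    """Parse and validate a config file (or pre-parsed dict).

    Applies defaults, checks ranges and path existence, and raises
    :class:`ConfigError` listing every violation at once.
    """
    if isinstance(source, (str, Path)):
        base = Path(source).parent
        raw = yaml.safe_load(Path(source).read_text())
    else:
        base, raw = Path("."), dict(source)
    if not isinstance(raw, dict):
        raise ConfigError(["config file is not a mapping"])

    violations: list[str] = []
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        violations.append(f"unknown keys: {sorted(unknown)}")

    sections = {}
    for name, cls in _SECTIONS.items():
        sub = raw.get(name, {}) or {}
        bad = set(sub) - set(cls.__dataclass_fields__)
        if bad:
            violations.append(f"unknown keys in [{name}]: {sorted(bad)}")
            sub = {k: v for k, v in sub.items() if k not in bad}
        sub = {k: tuple(v) if isinstance(v, list) else v for k, v in sub.items()}
        sections[name] = cls(**sub)

    paths: dict[str, Path | None] = {}
    for key in _PATH_KEYS:
        val = raw.get(key)
        if val is None:
            if key in ("micromet",):
                paths[key] = None
            else:
                violations.append(f"missing required path: {key}")
                paths[key] = None
            continue
        p = Path(val)
        if not p.is_absolute():
            p = base / p
        paths[key] = p
        if key != "output_dir" and not p.exists():
            violations.append(f"{key}: {p} does not exist")

    if violations:
        raise ConfigError(violations)

    cfg = SurveyConfig(
        frames_dir=paths["frames_dir"], thermal_dir=paths["thermal_dir"],
        track=paths["track"], anchors=paths["anchors"],
        output_dir=paths["output_dir"], micromet=paths["micromet"],
        survey_date=str(raw.get("survey_date", "")),
        vision=sections["vision"], thermal=sections["thermal"],
        matching=sections["matching"], maps=sections["maps"],
    )
    violations = _range_checks(cfg)
    if violations:
        raise ConfigError(violations)
    return cfg
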