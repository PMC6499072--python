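"""Run configuration: YAML parsing, strict validation, defaults.

Unknown keys are rejected (catching e.g. ``polcutoff`` typos) and every
threshold is checked against its documented domain with an error naming the
key and the valid range.  The fixed analysis constants default to the
published conventions: polarization cutoff 0.25, depletion area-ratio cutoff
0.1.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError
from .scene_synth import ActinProfile, SceneSpec

# key -> (default, lo, hi, lo_open, hi_open)
_RANGES: dict[str, tuple] = {
    "pol_cutoff": (0.25, -1.0, 1.0, False, False),
    "area_cutoff": (0.1, 0.0, 1.0, False, False),
    "ratio_delta": (0.05, 0.0, 1.0, False, True),
    "band_depth_um": (1.5, 0.0, 100.0, True, False),
    "central_fraction": (0.5, 0.0, 1.0, True, False),
    "spot_min_area_px": (4, 1, 10_000, False, False),
    "low_fraction": (0.5, 0.0, 1.0, True, True),
    "slab_depth_um": (1.5, 0.0, 100.0, True, False),
    "max_link_um": (2.0, 0.0, 1000.0, True, False),
    "min_track_len": (2, 2, 10_000, False, False),
}


@dataclass
class SimulateConfig:
    """What to synthesize when the run starts from a scene spec."""

    n_scenes: int = 10
    kind: str = "static"  # static | zstack | timelapse | vesicles
    polarized_fraction: float = 0.7
    depleted_fraction: float = 0.5
    scene: SceneSpec = field(default_factory=SceneSpec)


@dataclass
class RunConfig:
    """Validated, defaults-filled configuration for one pipeline run."""

    seed: int = 0
    out_dir: str = "synapsepol_out"
    inputs: list[str] = field(default_factory=list)
    channel_roles: dict[str, int] | None = None
    pixel_size: float | None = None
    z_step: float | None = None
    frame_interval: float | None = None
    pol_cutoff: float = 0.25
    area_cutoff: float = 0.1
    ratio_delta: float = 0.05
    band_depth_um: float = 1.5
    central_fraction: float = 0.5
    spot_min_area_px: int = 4
    low_fraction: float = 0.5
    slab_depth_um: float = 1.5
    max_link_um: float = 2.0
    min_track_len: int = 2
    simulate: SimulateConfig | None = None

    def effective_values(self) -> dict:
        """Every effective parameter, for the run manifest (no silent defaults)."""
        out = dataclasses.asdict(self)
        return out

    def config_hash(self) -> str:
        payload = json.dumps(self.effective_values(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


_TOP_KEYS = {f.name for f in dataclasses.fields(RunConfig)}
_SIM_KEYS = {f.name for f in dataclasses.fields(SimulateConfig)}
_SCENE_KEYS = {f.name for f in dataclasses.fields(SceneSpec)}
_PROFILE_KEYS = {f.name for f in dataclasses.fields(ActinProfile)}


def _check_range(key: str, value) -> None:
    default, lo, hi, lo_open, hi_open = _RANGES[key]
    ok = (value > lo if lo_open else value >= lo) and (value < hi if hi_open else value <= hi)
    if not ok:
        lo_b = "(" if lo_open else "["
        hi_b = ")" if hi_open else "]"
        raise ConfigError(f"{key} = {value!r} outside valid range {lo_b}{lo}, {hi}{hi_b}")


def validate_config(raw: str | dict | Path) -> RunConfig:
    """Parse + validate a YAML document (or dict) into a :class:`RunConfig`.

    Raises ``ConfigError`` naming any unknown key or out-of-range threshold.
    """
    if isinstance(raw, Path) or (isinstance(raw, str) and "\n" not in raw and raw.endswith((".yml", ".yaml"))):
        raw = Path(raw).read_text()
    if isinstance(raw, str):
        raw = yaml.safe_load(raw) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")

    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown key(s): {sorted(unknown)}")
    cfg = RunConfig()
    for key, value in raw.items():
        if key == "simulate":
            continue
        if key in _RANGES and value is not None:
            if not isinstance(value, (int, float)) or isinstance(value, bool):
                raise ConfigError(f"{key} must be a number, got {value!r}")
            _check_range(key, value)
        setattr(cfg, key, value)
    if "simulate" in raw and raw["simulate"] is not None:
        cfg.simulate = _parse_simulate(raw["simulate"])
    if cfg.channel_roles is not None and not all(
        isinstance(v, int) for v in cfg.channel_roles.values()
    ):
        raise ConfigError("channel_roles values must be integer channel indexes")
    return cfg


def _parse_simulate(block: dict) -> SimulateConfig:
    if not isinstance(block, dict):
        raise ConfigError("simulate must be a mapping")
    unknown = set(block) - _SIM_KEYS
    if unknown:
        raise ConfigError(f"unknown simulate key(s): {sorted(unknown)}")
    sim = SimulateConfig()
    for key, value in block.items():
        if key == "scene":
            continue
        setattr(sim, key, value)
    if sim.kind not in ("static", "zstack", "timelapse", "vesicles"):
        raise ConfigError(f"simulate.kind = {sim.kind!r} not one of static|zstack|timelapse|vesicles")
    if not 0.0 <= sim.polarized_fraction <= 1.0:
        raise ConfigError("simulate.polarized_fraction outside [0, 1]")
    if not 0.0 <= sim.depleted_fraction <= 1.0:
        raise ConfigError("simulate.depleted_fraction outside [0, 1]")
    if sim.n_scenes < 1:
        raise ConfigError("simulate.n_scenes must be >= 1")
    scene_block = block.get("scene") or {}
    unknown = set(scene_block) - _SCENE_KEYS
    if unknown:
        raise ConfigError(f"unknown scene key(s): {sorted(unknown)}")
    kwargs = dict(scene_block)
    if "actin_profile" in kwargs:
        prof = kwargs["actin_profile"]
        if not isinstance(prof, dict) or set(prof) - _PROFILE_KEYS:
            raise ConfigError("bad actin_profile block")
        kwargs["actin_profile"] = ActinProfile(**prof)
    if "shape_yx" in kwargs:
        kwargs["shape_yx"] = tuple(kwargs["shape_yx"])
    if "drift_px" in kwargs:
        kwargs["drift_px"] = tuple(kwargs["drift_px"])
    sim.scene = SceneSpec(**kwargs)
    sim.scene.validate()
    return sim
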