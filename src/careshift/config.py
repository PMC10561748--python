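"""Configuration: defaults, YAML loading with strict validation, hashing.

Every tunable the analyses and the simulator consume lives here with its
default; a YAML config file overrides any subset, and unknown keys are
rejected rather than ignored so typos cannot silently change an analysis.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields

import yaml

from .errors import ConfigError
from .geometry import CapacitanceParams, SensorLayout, build_layout
from .simulator import MotionProfile, TransductionParams


@dataclass
class LayoutConfig:
    rows: int = 5
    cols: int = 4
    pitch_mm: float = 80.0
    electrode_side_mm: float = 20.0


@dataclass
class CapacitanceConfig:
    kappa: float = 3.0
    area_mm2: float = 400.0
    l_min_mm: float = 2.5


@dataclass
class TransductionConfig:
    gain_counts_per_f: float = 1e11
    baseline_count: float = 200.0
    saturation_count: float = 20000.0
    noise_sd: float = 2.0


@dataclass
class MotionConfig:
    seat_offset: tuple = (0.0, 0.0)
    descent_velocity: float = 50.0
    approach_start: float = 5.0
    footprint: tuple = (300.0, 300.0)
    start_height: float = 200.0
    clothing_thickness: float = 5.0
    compression_tau: float = 0.3
    trial_duration: float | None = None
    lateral_drift: float = 0.0
    settle_overshoot: tuple = (0.0, 15.0)
    settle_tau: float = 0.6
    approach_entry_y: float = 300.0
    sweep_height: float = 100.0
    edge_softness: float = 40.0
    head_peak_velocity: float | None = None


@dataclass
class AnalysisConfig:
    velocity_channels: tuple = (8, 13)
    derivative_mode: str = "smoothed"       # raw | smoothed
    derivative_smooth_width: int = 5
    cog_statistic: str = "mean"             # mean | median
    cog_smooth_width: int = 1               # odd; 1 = no smoothing
    contact_threshold_mm: float = 5.0
    contact_hold_s: float = 0.1
    contact_baseline_s: float = 1.0
    peak_prominence_mm_s: float = 5.0
    peak_min_separation_s: float = 0.5
    quantile_rule: str = "linear"


@dataclass
class Config:
    layout: LayoutConfig = field(default_factory=LayoutConfig)
    capacitance: CapacitanceConfig = field(default_factory=CapacitanceConfig)
    transduction: TransductionConfig = field(default_factory=TransductionConfig)
    motion: MotionConfig = field(default_factory=MotionConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)

    # -- factories for the domain objects the library consumes ------------
    def build_layout(self) -> SensorLayout:
        return build_layout(
            rows=self.layout.rows,
            cols=self.layout.cols,
            pitch=self.layout.pitch_mm,
            electrode_side=self.layout.electrode_side_mm,
        )

    def capacitance_params(self) -> CapacitanceParams:
        return CapacitanceParams(
            kappa=self.capacitance.kappa,
            area_mm2=self.capacitance.area_mm2,
            l_min_mm=self.capacitance.l_min_mm,
        )

    def transduction_params(self, seed: int = 0) -> TransductionParams:
        return TransductionParams(
            gain_counts_per_f=self.transduction.gain_counts_per_f,
            baseline_count=self.transduction.baseline_count,
            saturation_count=self.transduction.saturation_count,
            noise_sd=self.transduction.noise_sd,
            seed=seed,
        )

    def motion_profile(self) -> MotionProfile:
        m = self.motion
        return MotionProfile(
            seat_offset=tuple(m.seat_offset),
            descent_velocity=m.descent_velocity,
            approach_start=m.approach_start,
            footprint=tuple(m.footprint),
            start_height=m.start_height,
            clothing_thickness=m.clothing_thickness,
            compression_tau=m.compression_tau,
            trial_duration=m.trial_duration,
            lateral_drift=m.lateral_drift,
            settle_overshoot=tuple(m.settle_overshoot),
            settle_tau=m.settle_tau,
            approach_entry_y=m.approach_entry_y,
            sweep_height=m.sweep_height,
            edge_softness=m.edge_softness,
            head_peak_velocity=m.head_peak_velocity,
        )


def _apply(obj, data: dict, path: str):
    known = {f.name: f for f in fields(obj)}
    for key, value in data.items():
        if key not in known:
            raise ConfigError(f"unknown configuration key '{path}{key}'")
        current = getattr(obj, key)
        if dataclasses.is_dataclass(current):
            if not isinstance(value, dict):
                raise ConfigError(f"'{path}{key}' must be a mapping")
            _apply(current, value, f"{path}{key}.")
        else:
            if isinstance(value, list):
                value = tuple(value)
            setattr(obj, key, value)


def default_config() -> Config:
    return Config()


def load_config(path=None) -> Config:
    """Load a YAML configuration over the defaults; None gives the defaults.

    Raises
    ------
    ConfigError
        On unknown keys or structurally invalid sections.
    """
    cfg = Config()
    if path is None:
        return cfg
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} must contain a mapping")
    _apply(cfg, data, "")
    return cfg


def config_dict(cfg: Config) -> dict:
    return dataclasses.asdict(cfg)


def config_hash(cfg: Config) -> str:
    """Stable short hash of the full configuration, for output provenance."""
    payload = json.dumps(config_dict(cfg), sort_keys=True, default=list)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
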