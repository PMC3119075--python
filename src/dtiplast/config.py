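"""Pipeline configuration: one versioned YAML schema for every stage.

Defaults mirror the study protocol: 15-direction b=1000 scheme with one b0,
three repeats, motion-screen threshold tau = 0.05, nearest-neighbour
resampling, 0.3-mm smoothing kernel, FDR level q = 0.05, 26-connectivity
and a 5-voxel minimum cluster size.  Every run writes its fully resolved
configuration next to its outputs so reruns are reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

CONFIG_VERSION = 1


class ConfigError(ValueError):
    """Schema violation, reported with the offending field."""


@dataclass
class SimulationConfig:
    grid: tuple[int, int, int] = (16, 16, 4)
    voxel_size_mm: tuple[float, float, float] = (0.2, 0.2, 1.2)
    n_directions: int = 15
    bvalue: float = 1000.0
    n_repeats: int = 3
    s0: float = 1000.0
    noise_sigma_fraction: float = 1.0 / 60.0
    noise_model: str = "rician"
    bias_amplitude: float = 0.0
    n_per_group: int = 8
    age_months: int = 4
    perturb: bool = True
    n_ghost_events: int = 0
    ghost_fraction: float = 0.10
    # acquisition metadata carried through to output headers (not used
    # computationally): TR/TE = 4000/25 ms, Delta/delta = 10/4.5 ms
    acquisition_metadata: dict = field(default_factory=lambda: {
        "TR_ms": 4000.0, "TE_ms": 25.0, "Delta_ms": 10.0, "delta_ms": 4.5})


@dataclass
class QCConfig:
    tau: float = 0.05
    phase_axis: int = 1


@dataclass
class FitConfig:
    method: str = "wls"                   # "wls" or "ols"


@dataclass
class NormalizationConfig:
    est_smooth_fwhm_mm: float = 0.2       # parameter estimation only
    smooth_fwhm_mm: float = 0.3           # applied to the output maps
    interpolation: str = "nearest"
    affine: bool = True                   # 12-parameter stage after the rigid fit


@dataclass
class StatsConfig:
    indices: tuple[str, ...] = ("ADC", "FA")
    q_level: float = 0.05
    connectivity: int = 26
    min_cluster_size: int = 5


@dataclass
class MorphometryConfig:
    threshold: float = 120.0              # one global threshold per marker
    connectivity: int = 8
    min_area_px: int = 5
    pixel_size_um: float = 0.5
    perimeter_convention: str = "crofton"


@dataclass
class PipelineConfig:
    version: int = CONFIG_VERSION
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    qc: QCConfig = field(default_factory=QCConfig)
    fit: FitConfig = field(default_factory=FitConfig)
    normalization: NormalizationConfig = field(default_factory=NormalizationConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    morphometry: MorphometryConfig = field(default_factory=MorphometryConfig)

    def validate(self) -> "PipelineConfig":
        if self.fit.method not in ("wls", "ols"):
            raise ConfigError(f"fit.method: expected 'wls' or 'ols', got {self.fit.method!r}")
        if not (0 < self.stats.q_level < 1):
            raise ConfigError(f"stats.q_level: must be in (0,1), got {self.stats.q_level}")
        if self.stats.connectivity not in (6, 18, 26):
            raise ConfigError(f"stats.connectivity: must be 6/18/26, got {self.stats.connectivity}")
        if self.qc.tau < 0:
            raise ConfigError(f"qc.tau: must be >= 0, got {self.qc.tau}")
        if self.simulation.noise_model not in ("rician", "gaussian"):
            raise ConfigError(
                f"simulation.noise_model: 'rician' or 'gaussian', got {self.simulation.noise_model!r}")
        if self.normalization.interpolation not in ("nearest", "trilinear"):
            raise ConfigError(
                f"normalization.interpolation: 'nearest' or 'trilinear', got "
                f"{self.normalization.interpolation!r}")
        if self.morphometry.perimeter_convention not in ("crofton", "boundary"):
            raise ConfigError(
                f"morphometry.perimeter_convention: 'crofton' or 'boundary', got "
                f"{self.morphometry.perimeter_convention!r}")
        return self


def _to_dict(obj) -> dict:
    if dataclasses.is_dataclass(obj):
        return {f.name: _to_dict(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, tuple):
        return [_to_dict(x) for x in obj]
    if isinstance(obj, dict):
        return {k: _to_dict(v) for k, v in obj.items()}
    return obj


def _from_dict(cls, data: dict):
    kwargs = {}
    fields = {f.name: f for f in dataclasses.fields(cls)}
    for key, value in data.items():
        if key not in fields:
            raise ConfigError(f"unknown config field {cls.__name__}.{key}")
        ftype = fields[key].type
        default = fields[key].default_factory() if fields[key].default_factory \
            is not dataclasses.MISSING else fields[key].default
        if dataclasses.is_dataclass(default):
            kwargs[key] = _from_dict(type(default), value or {})
        elif isinstance(default, tuple) and value is not None:
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    return cls(**kwargs)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_to_dict(config), fh, sort_keys=False)


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return _from_dict(PipelineConfig, data).validate()
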