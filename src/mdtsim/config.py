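"""Run configuration: nested dataclasses with YAML round-trip and overrides.

Defaults reproduce the study conditions: Weibel G0-G3 dimensions, air at
rho = 1.22 kg/m^3 / eta = 1.78e-5 Pa s, 4 um particles of density
5230 kg/m^3 and relative permeability 9, inlet rate 15 L/min, tumor
r/R_G1 = 0.8 at the mid-branch station, and a 32.5 x 19 mm bulk magnet
calibrated to a 3.42 T peak surface field at 40 mm from the lung plane.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as dc_field

import yaml

__all__ = [
    "LungConfig", "TumorConfig", "FlowConfig", "ParticleConfig",
    "MagnetConfig", "AirConfig", "RunConfig", "Config",
]


@dataclass
class LungConfig:
    #: per-generation (length, radius) in millimeters
    dims_mm: list = dc_field(default_factory=lambda: [
        [120.0, 9.0], [47.6, 6.1], [19.0, 4.15], [7.6, 2.8]])
    half_angle_deg: float = 35.0


@dataclass
class TumorConfig:
    enabled: bool = True
    r_ratio: float = 0.8
    location: str = "P1"
    alpha_deg: float = 0.0
    host_branch: int | None = None  # default: first G1 daughter


@dataclass
class FlowConfig:
    q_lpm: float = 15.0
    skew: float = 0.3
    source: str = "analytic"  # or "vtk:<path>"


@dataclass
class ParticleConfig:
    n: int = 10000
    d_p_um: float = 4.0
    mu_r_p: float = 9.0
    rho_p: float = 5230.0
    seeding: str = "flux"  # or "uniform"


@dataclass
class MagnetConfig:
    enabled: bool = True
    preset: str | None = "M1_77K"
    a_mm: float | None = None     # explicit geometry overrides the preset
    t_mm: float | None = None
    b_t: float | None = None      # target peak surface field (T)
    d_mm: float = 40.0            # top surface to lung center plane
    offset_xy_mm: list = dc_field(default_factory=lambda: [0.0, 0.0])
    jc_model: str = "constant"
    kim_b0: float = 1.5


@dataclass
class AirConfig:
    rho: float = 1.22
    eta: float = 1.78e-5


@dataclass
class RunConfig:
    seed: int = 12345
    dt_max: float = 2e-4
    ds_max_mm: float = 0.25
    ds_near_mm: float = 0.1
    t_max_factor: float = 3.0
    field_spacing_mm: float = 1.0
    denominator: str = "released"  # or "host_branch"


@dataclass
class Config:
    lung: LungConfig = dc_field(default_factory=LungConfig)
    tumor: TumorConfig = dc_field(default_factory=TumorConfig)
    flow: FlowConfig = dc_field(default_factory=FlowConfig)
    particles: ParticleConfig = dc_field(default_factory=ParticleConfig)
    magnet: MagnetConfig = dc_field(default_factory=MagnetConfig)
    air: AirConfig = dc_field(default_factory=AirConfig)
    run: RunConfig = dc_field(default_factory=RunConfig)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "Config":
        kwargs = {}
        for f in dataclasses.fields(cls):
            sub = d.get(f.name, {})
            sub_cls = f.default_factory().__class__
            known = {x.name for x in dataclasses.fields(sub_cls)}
            unknown = set(sub) - known
            if unknown:
                raise ValueError(f"unknown {f.name} config keys: {sorted(unknown)}")
            kwargs[f.name] = sub_cls(**sub)
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        return cls(**kwargs)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "Config":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    # -- functional updates ------------------------------------------------

    def with_overrides(self, overrides: dict) -> "Config":
        """Copy with dotted-key overrides, e.g. ``{"particles.d_p_um": 6}``."""
        d = self.to_dict()
        for key, value in overrides.items():
            section, _, name = key.partition(".")
            if not name or section not in d or name not in d[section]:
                raise KeyError(f"unknown config key {key!r}")
            d[section][name] = value
        return Config.from_dict(d)
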