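"""Named magnet presets, the default study configuration, and a toy case.

The bulk-superconductor Jc(B) curves behind the published peak fields exist
only as figures, but every deposition result depends on the magnet solely
through its external field, which the peak surface value pins down.  Each
preset therefore carries a constant Jc calibrated so the simulated peak
surface field reproduces the printed value exactly; the Kim model remains
available for users with their own curve data.

Size presets (radius x thickness mm -> B_T): 15x9 -> 2.11 T, 25x15 -> 3.02,
32.5x19 -> 3.42, 40x23 -> 3.70, 50x29 -> 3.99.  Operating-temperature
presets (32.5x19 mm): M1_77K 3.42 T, M2_60K 6.95 T, M2_50K 10.80 T.
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import Config
from .magnet_field import JcCurve, calibrate_jc

__all__ = ["NamedPreset", "PRESET_TABLE", "make_presets", "get_preset",
           "default_config", "make_toy_case"]


@dataclass(frozen=True)
class NamedPreset:
    label: str
    a_mm: float
    t_mm: float
    b_t: float
    jc: JcCurve


#: label -> (radius mm, thickness mm, peak surface field T)
PRESET_TABLE: dict[str, tuple[float, float, float]] = {
    "size_15": (15.0, 9.0, 2.11),
    "size_25": (25.0, 15.0, 3.02),
    "size_32p5": (32.5, 19.0, 3.42),
    "size_40": (40.0, 23.0, 3.70),
    "size_50": (50.0, 29.0, 3.99),
    "M1_77K": (32.5, 19.0, 3.42),
    "M2_60K": (32.5, 19.0, 6.95),
    "M2_50K": (32.5, 19.0, 10.80),
}


def make_presets() -> list[NamedPreset]:
    """All presets with constant-Jc curves calibrated to their peak fields."""
    out = []
    for label, (a_mm, t_mm, b_t) in PRESET_TABLE.items():
        jc = calibrate_jc(b_t, a_mm * 1e-3, t_mm * 1e-3, model="constant")
        out.append(NamedPreset(label, a_mm, t_mm, b_t, jc))
    return out


def get_preset(label: str) -> NamedPreset:
    if label not in PRESET_TABLE:
        raise KeyError(f"unknown magnet preset {label!r}; "
                       f"known: {sorted(PRESET_TABLE)}")
    a_mm, t_mm, b_t = PRESET_TABLE[label]
    jc = calibrate_jc(b_t, a_mm * 1e-3, t_mm * 1e-3, model="constant")
    return NamedPreset(label, a_mm, t_mm, b_t, jc)


def default_config() -> Config:
    """The baseline study configuration (see module docstring)."""
    return Config()


def make_toy_case() -> Config:
    """Reduced CI-scale case: straight duct, wall tumor, small close magnet.

    A single G0-sized duct hosts a mid-length tumor; the smallest preset sits
    12 mm below the duct plane; 200 particles and a 2 mm field grid keep the
    full pipeline under half a minute.
    """
    cfg = Config()
    cfg.lung.dims_mm = [[120.0, 9.0]]
    cfg.tumor.host_branch = 0
    cfg.tumor.r_ratio = 0.6
    cfg.magnet.preset = "size_15"
    cfg.magnet.d_mm = 12.0
    cfg.particles.n = 200
    cfg.run.field_spacing_mm = 2.0
    return cfg
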