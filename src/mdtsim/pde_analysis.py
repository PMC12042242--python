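"""Particle-deposition-efficiency computation and parameter-sweep orchestration.

The figure of merit is the particle deposition efficiency

    PDE = 100 * (particles deposited on the tumor surface)
              / (particles entering the branch)

The denominator is ambiguous in the source definition; both readings are
computed: ``released`` (all particles entering the trachea, the default) and
``host_branch`` (particles whose path visits the tumor's branch).

``run_case`` executes the full stationary-then-transient pipeline
(magnetize -> field map -> flow -> seed -> integrate -> PDE); ``run_sweep``
repeats it along one parameter axis with per-point deterministic sub-seeds
and writes a CSV table and a plot.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from . import airflow, lung_geometry, magnet_field, particle_transport
from .config import Config
from .fixtures import get_preset
from .magnet_field import BulkMagnet, FieldMap, build_field_map, calibrate_jc, magnetize
from .particle_transport import DtControl, ParticleSpec, Status

__all__ = ["PDERecord", "compute_pde", "run_case", "run_sweep",
           "records_to_frame", "plot_sweep", "SWEEP_AXES",
           "build_tree", "magnet_from_config", "bean_validation_table"]

#: sweep-axis name -> dotted config key
SWEEP_AXES = {
    "d_p_um": "particles.d_p_um",
    "mu_r_p": "particles.mu_r_p",
    "q_lpm": "flow.q_lpm",
    "r_ratio": "tumor.r_ratio",
    "location": "tumor.location",
    "alpha_deg": "tumor.alpha_deg",
    "d_mm": "magnet.d_mm",
    "d": "magnet.d_mm",
    "preset": "magnet.preset",
    "skew": "flow.skew",
}

_CSV_COLUMNS = [
    "case", "magnet", "b_t", "d_mm", "d_p_um", "mu_r_p", "q_lpm",
    "r_ratio", "location", "alpha_deg", "skew", "seed",
    "n_entered", "n_on_tumor", "n_wall", "n_exited", "n_suspended",
    "pde", "pde_host_branch", "error",
]


@dataclass
class PDERecord:
    """One sweep point: parameters, deposition counts, and the PDE statistic."""

    params: dict
    n_entered: int = 0
    n_on_tumor: int = 0
    n_wall: int = 0
    n_exited: int = 0
    n_suspended: int = 0
    pde: float = float("nan")
    pde_host_branch: float = float("nan")
    seed: int | None = None
    error: str | None = None
    diagnostics: dict = dc_field(default_factory=dict)

    def as_row(self) -> dict:
        row = {c: self.params.get(c) for c in _CSV_COLUMNS}
        row.update(
            seed=self.seed, n_entered=self.n_entered, n_on_tumor=self.n_on_tumor,
            n_wall=self.n_wall, n_exited=self.n_exited, n_suspended=self.n_suspended,
            pde=self.pde, pde_host_branch=self.pde_host_branch, error=self.error,
        )
        return row


def compute_pde(result, tree, denominator_mode: str = "released") -> PDERecord:
    """PDE record from a finished transport result.

    Numerator: particles deposited on the tumor surface.  Denominator:
    all released particles (``released``) or those whose branch log visits
    the tumor host branch (``host_branch``).  Suspended particles count in
    the denominator but never the numerator.
    """
    ens = result.ensemble if hasattr(result, "ensemble") else result
    status = ens.status
    n = ens.n
    n_tumor = int(np.sum(status == Status.DEPOSITED_TUMOR))
    rec = PDERecord(
        params={},
        n_entered=n,
        n_on_tumor=n_tumor,
        n_wall=int(np.sum(status == Status.DEPOSITED_WALL)),
        n_exited=int(np.sum(status == Status.EXITED_OUTLET)),
        n_suspended=int(np.sum((status == Status.SUSPENDED) | (status == Status.ERROR))),
    )
    if denominator_mode not in ("released", "host_branch"):
        raise ValueError(f"unknown denominator mode {denominator_mode!r}")
    host = tree.tumor.branch_id if tree.tumor is not None else None
    n_host = (sum(1 for log in ens.branch_logs if host in log)
              if host is not None else 0)
    rec.diagnostics["n_host_branch"] = n_host
    rec.pde = 100.0 * n_tumor / n if n else float("nan")
    rec.pde_host_branch = 100.0 * n_tumor / n_host if n_host else float("nan")
    denom = n if denominator_mode == "released" else n_host
    if denom == 0:
        rec.error = f"zero denominator for mode {denominator_mode!r}"
    return rec


# --------------------------------------------------------------------------
# Stage builders
# --------------------------------------------------------------------------

def build_tree(cfg: Config) -> lung_geometry.LungTree:
    tree = lung_geometry.build_weibel_tree(
        [tuple(d) for d in cfg.lung.dims_mm], cfg.lung.half_angle_deg)
    if cfg.tumor.enabled:
        tree = lung_geometry.add_tumor(
            tree, cfg.tumor.r_ratio, cfg.tumor.location,
            cfg.tumor.alpha_deg, cfg.tumor.host_branch)
    return tree


def magnet_from_config(cfg: Config, tree) -> BulkMagnet | None:
    """Magnet with its axis through the tumor station, top face at z = -d."""
    m = cfg.magnet
    if not m.enabled:
        return None
    if m.a_mm is not None and m.t_mm is not None and m.b_t is not None:
        a, t, bt, label = m.a_mm * 1e-3, m.t_mm * 1e-3, m.b_t, "custom"
    elif m.preset is not None:
        p = get_preset(m.preset)
        a, t, bt, label = p.a_mm * 1e-3, p.t_mm * 1e-3, p.b_t, p.label
    else:
        raise ValueError("magnet config needs a preset or explicit a/t/b_t")
    jc = calibrate_jc(bt, a, t, model=m.jc_model, b0=m.kim_b0)
    if tree.tumor is not None:
        align = tree.tumor.station_point
    else:
        align = tree.root.end
    center = (float(align[0] + m.offset_xy_mm[0] * 1e-3),
              float(align[1] + m.offset_xy_mm[1] * 1e-3),
              -m.d_mm * 1e-3)
    # axis +z: the magnet sits behind the lung plane, top face toward it
    return BulkMagnet(a, t, jc, center=center, axis=(0.0, 0.0, 1.0))


_FIELD_CACHE: dict = {}
_CURRENT_CACHE: dict = {}


def _field_map_for(cfg: Config, tree, magnet: BulkMagnet | None) -> FieldMap:
    spacing = cfg.run.field_spacing_mm * 1e-3
    lo, hi = tree.bounding_box(margin=2e-3)
    box = (lo, hi)
    if magnet is None:
        return FieldMap.zero(box, spacing)
    mkey = (magnet.a, magnet.t, magnet.jc.model, magnet.jc.jc0, magnet.jc.b0)
    key = (mkey, magnet.center, spacing,
           tuple(np.round(lo, 4)), tuple(np.round(hi, 4)))
    if key not in _FIELD_CACHE:
        if mkey not in _CURRENT_CACHE:
            _CURRENT_CACHE[mkey] = magnetize(magnet)
        _FIELD_CACHE[key] = build_field_map(magnet, _CURRENT_CACHE[mkey], box, spacing)
    return _FIELD_CACHE[key]


def _flow_for(cfg: Config, tree):
    if cfg.flow.source.startswith("vtk:"):
        return airflow.import_flow(cfg.flow.source[4:], rho_a=cfg.air.rho,
                                   eta=cfg.air.eta)
    return airflow.solve_flow(tree, cfg.flow.q_lpm, skew=cfg.flow.skew,
                              rho_a=cfg.air.rho, eta=cfg.air.eta)


def _case_params(cfg: Config, label: str | None = None) -> dict:
    b_t = cfg.magnet.b_t
    if cfg.magnet.enabled and b_t is None and cfg.magnet.preset:
        from .fixtures import PRESET_TABLE

        b_t = PRESET_TABLE[cfg.magnet.preset][2]
    return {
        "case": label or "case",
        "magnet": (cfg.magnet.preset or "custom") if cfg.magnet.enabled else "none",
        "b_t": b_t if cfg.magnet.enabled else None,
        "d_mm": cfg.magnet.d_mm if cfg.magnet.enabled else None,
        "d_p_um": cfg.particles.d_p_um,
        "mu_r_p": cfg.particles.mu_r_p,
        "q_lpm": cfg.flow.q_lpm,
        "r_ratio": cfg.tumor.r_ratio if cfg.tumor.enabled else None,
        "location": cfg.tumor.location if cfg.tumor.enabled else None,
        "alpha_deg": cfg.tumor.alpha_deg if cfg.tumor.enabled else None,
        "skew": cfg.flow.skew,
    }


# --------------------------------------------------------------------------
# Case and sweep drivers
# --------------------------------------------------------------------------

def run_case(cfg: Config, seed: int | None = None, label: str | None = None) -> PDERecord:
    """Full pipeline for one configuration; deterministic given the seed."""
    seed = cfg.run.seed if seed is None else int(seed)
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    tree = build_tree(cfg)
    magnet = magnet_from_config(cfg, tree)
    field_map = _field_map_for(cfg, tree, magnet)
    timings["field_s"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    flow = _flow_for(cfg, tree)
    timings["flow_s"] = time.perf_counter() - t0

    spec = ParticleSpec(d_p=cfg.particles.d_p_um * 1e-6,
                        rho_p=cfg.particles.rho_p,
                        mu_r_p=cfg.particles.mu_r_p)
    ens = particle_transport.seed_particles(cfg.particles.n, tree, flow, seed,
                                            sampling=cfg.particles.seeding)
    dtc = DtControl(dt_max=cfg.run.dt_max,
                    ds_max=cfg.run.ds_max_mm * 1e-3,
                    ds_max_near_tumor=cfg.run.ds_near_mm * 1e-3)
    t_max = cfg.run.t_max_factor * flow.transit_time()

    t0 = time.perf_counter()
    result = particle_transport.integrate(ens, flow, field_map, spec, tree=tree,
                                          dt_control=dtc, t_max=t_max)
    timings["transport_s"] = time.perf_counter() - t0

    rec = compute_pde(result, tree, cfg.run.denominator)
    rec.params = _case_params(cfg, label)
    rec.seed = seed
    rec.diagnostics.update(timings, steps=result.steps, t_max=t_max,
                           transit_s=flow.transit_time() if hasattr(flow, "transit_time") else None)
    return rec


def _subseed(master: int, index: int) -> int:
    return int(np.random.SeedSequence([int(master), int(index)])
               .generate_state(1)[0] % (2**31))


def run_sweep(cfg: Config, axis: str, values, out_dir=None,
              master_seed: int | None = None) -> list[PDERecord]:
    """One :func:`run_case` per value of ``axis``; per-point failures recorded.

    Each point gets a fresh deterministic sub-seed derived from the master
    seed by counter, logged in its record.
    """
    if axis not in SWEEP_AXES:
        raise ValueError(f"unknown sweep axis {axis!r}; known: {sorted(SWEEP_AXES)}")
    key = SWEEP_AXES[axis]
    master = cfg.run.seed if master_seed is None else int(master_seed)
    records = []
    for i, value in enumerate(values):
        sub = _subseed(master, i)
        try:
            point = cfg.with_overrides({key: value})
            rec = run_case(point, seed=sub, label=f"{axis}={value}")
        except Exception as exc:  # per-point failure: record and continue
            rec = PDERecord(params={"case": f"{axis}={value}"}, seed=sub,
                            error=f"{type(exc).__name__}: {exc}")
        rec.params.setdefault(axis, value)
        records.append(rec)
    if out_dir is not None:
        import pathlib

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        records_to_frame(records).to_csv(out / f"sweep_{axis}.csv", index=False)
        plot_sweep(records, axis, out / f"sweep_{axis}.png")
    return records


def records_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame([r.as_row() for r in records], columns=_CSV_COLUMNS)


def plot_sweep(records, axis: str, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xs, ys = [], []
    for r in records:
        if r.error is None:
            xs.append(r.params.get(axis))
            ys.append(r.pde)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    if xs and isinstance(xs[0], str):
        ax.bar(range(len(xs)), ys)
        ax.set_xticks(range(len(xs)), xs)
    else:
        ax.plot(xs, ys, "o-")
    ax.set_xlabel(axis)
    ax.set_ylabel("PDE on tumor (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# --------------------------------------------------------------------------
# Magnetostatic validation table (CLI `validate-field`)
# --------------------------------------------------------------------------

def bean_validation_table() -> pd.DataFrame:
    """Bean closed form vs Biot-Savart surface-center field, all size presets."""
    rows = []
    for a_mm, t_mm, bt in ((15, 9, 2.11), (25, 15, 3.02), (32.5, 19, 3.42),
                           (40, 23, 3.70), (50, 29, 3.99)):
        a, t = a_mm * 1e-3, t_mm * 1e-3
        jc = calibrate_jc(bt, a, t)
        mag = BulkMagnet(a, t, jc)
        sim = magnet_field.peak_surface_field(mag)
        bean = magnet_field.trapped_field_peak(jc.jc0, a, t)
        rows.append({"a_mm": a_mm, "t_mm": t_mm, "B_bean_T": bean,
                     "B_biot_savart_T": sim,
                     "rel_err_pct": 100.0 * abs(sim - bean) / bean})
    return pd.DataFrame(rows)
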