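"""Lagrangian transport of magnetic drug particles in the airway.

Each particle obeys Newton's law with two forces (all others — gravity,
lift, Brownian, unsteady — are negligible at this scale and omitted):

* Schiller-Naumann drag,
  ``F_d = 3 pi eta d_p (u - v) (1 + 0.15 Re_p^0.687)``, the Stokes force
  with a finite-Reynolds correction (``Re_p = rho |u - v| d_p / eta``);
* magnetophoresis,
  ``F_m = (pi/4) d_p^3 mu0 mu_r K grad(H^2)`` with the contrast factor
  ``K = (mu_rp - mu_r) / (mu_rp + 2 mu_r)``.

The drag relaxation time ``tau = rho_p d_p^2 / (18 eta f)`` is 1e-5..1e-3 s,
far below the step sizes convenient for tracking, so the integrator treats
the drag exactly (exponential update with coefficients frozen per step) and
is unconditionally stable; steps are capped by a displacement limit instead
of tau.  Boundary rules: particles stick on wall or tumor contact and freeze
on crossing an outlet disc (absorbing states).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

from .magnet_field import MU0

__all__ = [
    "Status",
    "ParticleSpec",
    "ParticleState",
    "ParticleEnsemble",
    "DtControl",
    "TransportResult",
    "drag_force",
    "magnetophoretic_force",
    "contrast_factor",
    "seed_particles",
    "integrate",
]


class Status(IntEnum):
    IN_FLIGHT = 0
    DEPOSITED_WALL = 1
    DEPOSITED_TUMOR = 2
    EXITED_OUTLET = 3
    SUSPENDED = 4
    ERROR = 5


@dataclass(frozen=True)
class ParticleSpec:
    """Drug particle: diameter (m), density (kg/m^3), relative permeability."""

    d_p: float = 4e-6
    rho_p: float = 5230.0
    mu_r_p: float = 9.0

    def __post_init__(self) -> None:
        if self.d_p <= 0 or self.rho_p <= 0:
            raise ValueError("particle diameter and density must be positive")
        if self.mu_r_p <= 1.0:
            raise ValueError("particles must be paramagnetic (mu_r_p > 1)")

    @property
    def mass(self) -> float:
        """``m_p = (pi/6) d_p^3 rho_p``."""
        return np.pi / 6.0 * self.d_p**3 * self.rho_p

    def stokes_time(self, eta: float) -> float:
        """Stokes-limit velocity relaxation time ``rho_p d_p^2 / (18 eta)``."""
        return self.rho_p * self.d_p**2 / (18.0 * eta)


def contrast_factor(mu_r_p: float, mu_r: float = 1.0) -> float:
    """Clausius-Mossotti-type factor ``(mu_rp - mu_r)/(mu_rp + 2 mu_r)``."""
    return (mu_r_p - mu_r) / (mu_r_p + 2.0 * mu_r)


def drag_force(u, v, spec: ParticleSpec, rho: float, eta: float) -> np.ndarray:
    """Schiller-Naumann drag force (N) on a particle moving at ``v`` in air at ``u``.

    Continuous at ``u = v`` where it reduces to (zero) Stokes drag.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    rel = u - v
    re_p = rho * np.linalg.norm(rel, axis=-1) * spec.d_p / eta
    f = 1.0 + 0.15 * re_p**0.687
    return 3.0 * np.pi * eta * spec.d_p * np.expand_dims(f, -1) * rel if rel.ndim > 1 \
        else 3.0 * np.pi * eta * spec.d_p * f * rel


def magnetophoretic_force(spec: ParticleSpec, mu_r: float, grad_h2) -> np.ndarray:
    """``F_m = (pi/4) d_p^3 mu0 mu_r K grad(H^2)``, parallel to grad(H^2)."""
    k = contrast_factor(spec.mu_r_p, mu_r)
    return np.pi / 4.0 * spec.d_p**3 * MU0 * mu_r * k * np.asarray(grad_h2, dtype=float)


@dataclass
class ParticleState:
    """Single-particle view (position, velocity, status, time, branch log)."""

    position: np.ndarray
    velocity: np.ndarray
    status: Status
    time: float
    branch_log: list


@dataclass
class ParticleEnsemble:
    """Vectorized particle population used by the integrator."""

    x: np.ndarray            # (n, 3)
    v: np.ndarray            # (n, 3)
    status: np.ndarray       # (n,) Status values
    time: np.ndarray         # (n,)
    branch_logs: list        # list of per-particle ordered branch-id lists

    @property
    def n(self) -> int:
        return self.x.shape[0]

    def __getitem__(self, i: int) -> ParticleState:
        return ParticleState(self.x[i].copy(), self.v[i].copy(),
                             Status(int(self.status[i])), float(self.time[i]),
                             list(self.branch_logs[i]))

    def counts(self) -> dict:
        return {s.name.lower(): int(np.sum(self.status == s)) for s in Status}


def seed_particles(n: int, tree, flow, rng_seed: int,
                   sampling: str = "flux") -> ParticleEnsemble:
    """Seed ``n`` particles on the inlet disc with the local air velocity.

    ``flux`` sampling (default) weights positions by the parabolic inlet
    velocity profile, so the seeded population represents the inhaled dose
    per unit time; ``uniform`` weights by area.
    """
    if n < 1:
        raise ValueError("need at least one particle")
    rng = np.random.default_rng(rng_seed)
    root = tree.root
    r_max = root.radius
    u01 = rng.random(n)
    if sampling == "flux":
        zeta = np.sqrt(1.0 - np.sqrt(1.0 - u01))
    elif sampling == "uniform":
        zeta = np.sqrt(u01)
    else:
        raise ValueError(f"unknown sampling {sampling!r}")
    ang = 2.0 * np.pi * rng.random(n)
    e1 = root.side_hat
    e2 = np.cross(root.direction, e1)
    eps = 1e-6
    x = (root.start[None, :] + eps * root.direction[None, :]
         + (zeta * r_max * np.cos(ang))[:, None] * e1
         + (zeta * r_max * np.sin(ang))[:, None] * e2)
    v = flow.velocity(x)
    return ParticleEnsemble(
        x=x, v=v,
        status=np.full(n, int(Status.IN_FLIGHT)),
        time=np.zeros(n),
        branch_logs=[[int(root.id)] for _ in range(n)],
    )


@dataclass(frozen=True)
class DtControl:
    """Step-size policy: hard cap plus displacement limits (m per step)."""

    dt_max: float = 2e-4
    ds_max: float = 2.5e-4
    ds_max_near_tumor: float = 1e-4
    bisect_tol: float = 1e-6


@dataclass
class TransportResult:
    ensemble: ParticleEnsemble
    steps: int
    t_max: float
    trajectories: list | None = None

    def counts(self) -> dict:
        return self.ensemble.counts()


def _segment_sphere_entry(x0, x1, center, radius):
    """Fraction along segments x0->x1 at first sphere crossing (inf if none)."""
    d = x1 - x0
    f = x0 - center
    a = np.sum(d * d, axis=1)
    b = 2.0 * np.sum(f * d, axis=1)
    c = np.sum(f * f, axis=1) - radius**2
    disc = b * b - 4 * a * c
    out = np.full(x0.shape[0], np.inf)
    ok = (disc >= 0) & (a > 0)
    sq = np.sqrt(np.where(ok, disc, 0.0))
    t1 = (-b - sq) / (2 * np.where(ok, a, 1.0))
    t2 = (-b + sq) / (2 * np.where(ok, a, 1.0))
    t = np.where((t1 >= 0.0) & (t1 <= 1.0), t1, np.where((t2 >= 0.0) & (t2 <= 1.0), t2, np.inf))
    out[ok] = t[ok]
    return out


def integrate(
    ensemble: ParticleEnsemble,
    flow,
    field_map,
    spec: ParticleSpec,
    tree=None,
    dt_control: DtControl = DtControl(),
    t_max: float | None = None,
    mu_r_medium: float = 1.0,
    record_stride: int = 0,
    max_steps: int = 200_000,
) -> TransportResult:
    """Advance all in-flight particles to an absorbing state or ``t_max``.

    Semi-implicit exponential update per step (exact for frozen
    coefficients)::

        v_inf = u + F_m tau / m                     (local drift velocity)
        v'    = v_inf + (v - v_inf) exp(-dt/tau)
        x'    = x + v_inf dt + (v - v_inf) tau (1 - exp(-dt/tau))

    With ``tree`` given, boundary crossings are located by bisection on the
    lumen indicator and classified as tumor, outlet or wall (stick/freeze
    rules).  ``tree=None`` integrates in free space (oracle/unit-test mode).
    Particles still airborne at ``t_max`` are marked suspended.
    """
    if t_max is None:
        t_max = 3.0 * flow.transit_time() if hasattr(flow, "transit_time") else 1.0
    eta = flow.eta
    rho_a = flow.rho_a
    cm = np.pi / 4.0 * spec.d_p**3 * MU0 * mu_r_medium * contrast_factor(spec.mu_r_p, mu_r_medium)
    drag0 = 3.0 * np.pi * eta * spec.d_p
    mass = spec.mass
    tumor = tree.tumor if tree is not None else None

    x, v, status, time = ensemble.x, ensemble.v, ensemble.status, ensemble.time
    current_branch = (tree.branch_of(x) if tree is not None
                      else np.full(ensemble.n, -1))

    # immediate deposition of particles seeded on/outside the boundary
    if tree is not None:
        onb = ~tree.inside_lumen(x) & (status == Status.IN_FLIGHT)
        status[onb] = int(Status.DEPOSITED_WALL)

    traj = [[] for _ in range(ensemble.n)] if record_stride else None
    steps = 0
    while True:
        alive = np.nonzero(status == Status.IN_FLIGHT)[0]
        if alive.size == 0 or steps >= max_steps:
            break
        steps += 1
        xa, va = x[alive], v[alive]
        u = flow.velocity(xa)
        gh2 = field_map.grad_h2_at(xa) if field_map is not None else np.zeros_like(xa)
        re_p = rho_a * np.linalg.norm(u - va, axis=1) * spec.d_p / eta
        f_sn = 1.0 + 0.15 * re_p**0.687
        tau = mass / (drag0 * f_sn)
        v_inf = u + (cm / (drag0 * f_sn))[:, None] * gh2

        # step size: displacement cap (tighter near the tumor), time cap
        ds = np.full(alive.size, dt_control.ds_max)
        if tumor is not None:
            near = np.linalg.norm(xa - tumor.center, axis=1) < 2.5 * tumor.radius
            ds[near] = dt_control.ds_max_near_tumor
        speed = np.maximum(np.linalg.norm(v_inf, axis=1), np.linalg.norm(va, axis=1))
        dt = np.minimum(dt_control.dt_max, ds / np.maximum(speed, 1e-9))
        dt = np.minimum(dt, np.maximum(t_max - time[alive], 1e-12))

        ex = np.exp(-dt / tau)
        dv = va - v_inf
        x_new = xa + v_inf * dt[:, None] + dv * (tau * (1.0 - ex))[:, None]
        v_new = v_inf + dv * ex[:, None]

        bad = ~np.isfinite(x_new).all(axis=1) | ~np.isfinite(v_new).all(axis=1)
        if np.any(bad):
            status[alive[bad]] = int(Status.ERROR)

        if tree is None:
            x[alive], v[alive] = x_new, v_new
            time[alive] += dt
        else:
            hit_t = (np.full(alive.size, np.inf) if tumor is None else
                     _segment_sphere_entry(xa, x_new, tumor.center, tumor.radius))
            left = ~tree.inside_lumen(x_new)
            crossed = np.nonzero((hit_t <= 1.0) | left)[0]
            ok = np.setdiff1d(np.arange(alive.size), crossed, assume_unique=True)
            idx_ok = alive[ok]
            x[idx_ok], v[idx_ok] = x_new[ok], v_new[ok]
            time[idx_ok] += dt[ok]
            for j in crossed:
                if status[alive[j]] != Status.IN_FLIGHT:
                    continue
                i = alive[j]
                if hit_t[j] <= 1.0:
                    xs = xa[j] + hit_t[j] * (x_new[j] - xa[j])
                    x[i], v[i] = xs, v_new[j]
                    status[i] = int(Status.DEPOSITED_TUMOR)
                    time[i] += hit_t[j] * dt[j]
                    continue
                lo_f, hi_f = 0.0, 1.0
                for _ in range(40):
                    mid = 0.5 * (lo_f + hi_f)
                    xm = xa[j] + mid * (x_new[j] - xa[j])
                    if tree.inside_lumen(xm[None, :])[0]:
                        lo_f = mid
                    else:
                        hi_f = mid
                    if hi_f - lo_f < dt_control.bisect_tol / max(
                            np.linalg.norm(x_new[j] - xa[j]), 1e-12):
                        break
                xs = xa[j] + lo_f * (x_new[j] - xa[j])
                xprobe = xa[j] + hi_f * (x_new[j] - xa[j])
                x[i], v[i] = xs, v_new[j]
                time[i] += hi_f * dt[j]
                status[i] = int(_classify_crossing(tree, xprobe, tumor))

        # track branch visits
        if tree is not None:
            still = np.nonzero(status == Status.IN_FLIGHT)[0]
            if still.size:
                nb = tree.branch_of(x[still])
                changed = np.nonzero((nb != current_branch[still]) & (nb >= 0))[0]
                for j in changed:
                    i = still[j]
                    ensemble.branch_logs[i].append(int(nb[j]))
                current_branch[still] = np.where(nb >= 0, nb, current_branch[still])

        timeout = (status == Status.IN_FLIGHT) & (time >= t_max - 1e-12)
        status[timeout] = int(Status.SUSPENDED)

        if record_stride and steps % record_stride == 0:
            for i in range(ensemble.n):
                if status[i] == Status.IN_FLIGHT:
                    traj[i].append((time[i], *x[i]))

    status[status == Status.IN_FLIGHT] = int(Status.SUSPENDED)
    return TransportResult(ensemble, steps, t_max, trajectories=traj)


def export_trajectories(result: TransportResult, csv_path=None, vtk_path=None) -> None:
    """Write recorded trajectories as per-particle CSV and/or VTK polylines.

    Requires ``integrate(..., record_stride=k)``; each CSV row is
    (id, t, x, y, z, final_status).
    """
    if result.trajectories is None:
        raise ValueError("no trajectories recorded; pass record_stride to integrate()")
    if csv_path is not None:
        import pandas as pd

        rows = []
        for i, tr in enumerate(result.trajectories):
            status = Status(int(result.ensemble.status[i])).name.lower()
            for t, x, y, z in tr:
                rows.append((i, t, x, y, z, status))
        pd.DataFrame(rows, columns=["id", "t", "x", "y", "z", "status"]).to_csv(
            csv_path, index=False)
    if vtk_path is not None:
        from . import vtkio

        lines = [np.array([p[1:] for p in tr]) for tr in result.trajectories
                 if len(tr) >= 2]
        vtkio.write_polylines(vtk_path, lines)


def _classify_crossing(tree, x_outside, tumor) -> Status:
    """Label the boundary reached by a trajectory leaving the open lumen."""
    if tumor is not None and np.linalg.norm(x_outside - tumor.center) <= tumor.radius * (1 + 1e-9):
        return Status.DEPOSITED_TUMOR
    for b in tree.outlets:
        s, radial = b.frame_coords(x_outside[None, :])
        if s[0] >= b.length - 1e-9 and radial[0] <= b.radius + 1e-6:
            return Status.EXITED_OUTLET
    return Status.DEPOSITED_WALL
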