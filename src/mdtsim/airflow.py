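"""Steady laminar airflow surrogate for the Weibel tree.

The paper-scale problem is steady inspiration at 7.5-60 L/min, Re ~ 1e3,
laminar.  Instead of a full Navier-Stokes solve, the field is assembled from
mechanisms that control aerosol deposition at this scale:

* a Hagen-Poiseuille resistance network sets the flow split between branches,
  with the tumor constriction entering the host branch resistance through the
  local open-area function;
* each branch carries a fully developed parabolic profile for its flow, with
  the daughter-branch profile skewed toward the carinal (inner) wall and
  relaxing to symmetric over one branch length;
* a short funnel zone upstream of each bifurcation turns the flow into the
  daughter tubes (a tracer entering the zone exits inside a daughter);
* the tumor cap deflects streamlines like a sphere in a stream (potential
  dipole scaled by the local velocity), so inertialess particles pass around
  the cap while inertial ones can impact it;
* a viscous slowdown within one cap radius of the tumor surface stands in
  for the separated corner (horseshoe) and wake regions of a wall-mounted
  bluff bump at duct Reynolds numbers of order 1e3: recirculating near-field
  speeds are an order of magnitude below the free stream, which lengthens
  particle residence next to the cap without reopening it to tracers.

The field is linear in Q by construction and zero outside the lumen.
``import_flow`` substitutes an externally computed field with the same query
contract.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from numpy.polynomial.legendre import leggauss

from .lung_geometry import LungTree, open_area

__all__ = [
    "AIR_DENSITY",
    "AIR_VISCOSITY",
    "FlowField",
    "UniformFlow",
    "GriddedFlowField",
    "solve_flow",
    "import_flow",
    "lpm_to_m3s",
]

#: Table-2 air properties (kg/m^3, Pa s).
AIR_DENSITY = 1.22
AIR_VISCOSITY = 1.78e-5

_FUNNEL_GAIN = 3.0       # e-folding count of the bifurcation funnel zone
_FUNNEL_TARGET = 0.8     # tracers are steered to within this fraction of Rc
_DIPOLE_CUTOFF = 4.0     # tumor dipole influence radius, in tumor radii
_POCKET_EXTENT = 1.0     # separated-region thickness around the cap, in tumor radii
_POCKET_FLOOR = 0.15     # recirculation speed as a fraction of the local free stream


def lpm_to_m3s(q_lpm: float) -> float:
    return q_lpm / 60000.0


def _branch_resistance(tree: LungTree, bid: int, eta: float, n_quad: int = 400) -> float:
    """Poiseuille resistance 8*eta*pi * integral ds / A_open(s)^2."""
    b = tree[bid]
    if tree.tumor is not None and tree.tumor.branch_id == bid:
        s = np.linspace(0.0, b.length, n_quad)
        area = np.asarray(open_area(tree, s))
        if np.any(area <= 0):
            raise ValueError("tumor fully occludes the host branch")
        return 8.0 * eta * np.pi * np.trapezoid(1.0 / area**2, s)
    return 8.0 * eta * b.length / (np.pi * b.radius**4)


def _network_flows(tree: LungTree, q_total: float, eta: float) -> np.ndarray:
    """Per-branch volumetric flow from the resistance network (outlets at equal pressure)."""
    n = len(tree.branches)
    r_branch = np.array([_branch_resistance(tree, i, eta) for i in range(n)])
    r_eq = np.zeros(n)

    def equivalent(bid: int) -> float:
        b = tree[bid]
        if not b.children:
            r_eq[bid] = r_branch[bid]
        else:
            inv = sum(1.0 / equivalent(c) for c in b.children)
            r_eq[bid] = r_branch[bid] + 1.0 / inv
        return r_eq[bid]

    equivalent(tree.root.id)
    flows = np.zeros(n)
    flows[tree.root.id] = q_total

    def split(bid: int) -> None:
        b = tree[bid]
        if not b.children:
            return
        inv = np.array([1.0 / r_eq[c] for c in b.children])
        for c, frac in zip(b.children, inv / inv.sum()):
            flows[c] = flows[bid] * frac
            split(c)

    split(tree.root.id)
    return flows


@dataclass
class FlowField:
    """Analytic surrogate velocity field over a :class:`LungTree` lumen."""

    tree: LungTree
    q: float                 # inlet volumetric rate, m^3/s
    branch_flows: np.ndarray
    skew: float = 0.3
    rho_a: float = AIR_DENSITY
    eta: float = AIR_VISCOSITY

    # -- bulk helpers ------------------------------------------------------

    def mean_speed(self, bid: int) -> float:
        b = self.tree[bid]
        return self.branch_flows[bid] / (np.pi * b.radius**2)

    def inlet_mean_speed(self) -> float:
        return self.mean_speed(self.tree.root.id)

    def inlet_reynolds(self) -> float:
        b = self.tree.root
        return self.rho_a * self.inlet_mean_speed() * 2.0 * b.radius / self.eta

    def transit_time(self) -> float:
        """Convective inlet-to-outlet time along the branch means."""
        total, b = 0.0, self.tree.root
        while True:
            total += b.length / self.mean_speed(b.id)
            if not b.children:
                return total
            b = self.tree[b.children[0]]

    # -- velocity query ----------------------------------------------------

    def velocity(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        u = np.zeros_like(pts)
        bid = self.tree.branch_of(pts)
        in_tumor = self.tree.in_tumor(pts)
        for b_id in np.unique(bid):
            if b_id < 0:
                continue
            sel = np.nonzero((bid == b_id) & ~in_tumor)[0]
            if sel.size:
                u[sel] = self._branch_velocity(b_id, pts[sel])
        return u

    def _branch_velocity(self, b_id: int, pts: np.ndarray) -> np.ndarray:
        tree = self.tree
        b = tree[b_id]
        rel = pts - b.start
        s = rel @ b.direction
        perp = rel - s[:, None] * b.direction
        radial = np.linalg.norm(perp, axis=1)
        zeta = np.minimum(radial / b.radius, 1.0)
        ubar = self.mean_speed(b_id)
        axial = 2.0 * ubar * (1.0 - zeta**2)

        # carinal skew of daughter profiles, relaxing over one branch length
        if b.parent is not None and self.skew != 0.0:
            s_loc = self.skew * np.maximum(0.0, 1.0 - s / b.length)
            inner = -b.sign * b.side_hat
            with np.errstate(invalid="ignore", divide="ignore"):
                cosphi = np.where(radial > 1e-12, (perp @ inner) / np.maximum(radial, 1e-12), 0.0)
            axial = axial * (1.0 + s_loc * zeta * cosphi)

        # continuity through the tumor constriction: the open cross-section
        # shrinks under the cap's shadow, so the local speed scales with the
        # blocked-area ratio
        tum = tree.tumor
        if tum is not None and tum.branch_id == b_id:
            shadow = np.abs(s - tum.station_s) < tum.radius
            if np.any(shadow):
                area_full = np.pi * b.radius**2
                ratio = area_full / np.asarray(open_area(tree, s[shadow]))
                axial = axial.copy()
                axial[shadow] *= ratio

        u = axial[:, None] * b.direction

        # bifurcation funnel: steer flow into the daughter tubes
        if b.children:
            ell = b.radius
            zone = s > b.length - ell
            if np.any(zone):
                side = perp @ b.side_hat
                for cid in b.children:
                    child = tree[cid]
                    csel = zone & ((side >= 0) if child.sign > 0 else (side < 0))
                    if not np.any(csel):
                        continue
                    relc = pts[csel] - child.start
                    sc = relc @ child.direction
                    pc = relc - sc[:, None] * child.direction
                    pc_n = np.linalg.norm(pc, axis=1)
                    shrink = np.minimum(1.0, _FUNNEL_TARGET * child.radius
                                        / np.maximum(pc_n, 1e-12)) - 1.0
                    u_lat = (_FUNNEL_GAIN / ell) * axial[csel, None] * shrink[:, None] * pc
                    u[csel] += u_lat

        # potential-flow deflection around the tumor cap
        if tum is not None and tum.branch_id == b_id:
            svec = pts - tum.center
            dist = np.linalg.norm(svec, axis=1)
            near = (dist < _DIPOLE_CUTOFF * tum.radius) & (dist > 1e-12)
            if np.any(near):
                sv = svec[near]
                dn = dist[near][:, None]
                shat = sv / dn
                u_loc = u[near]
                dot = np.sum(u_loc * shat, axis=1, keepdims=True)
                dip = -(tum.radius**3 / (2.0 * dn**3)) * (3.0 * dot * shat - u_loc)
                taper = np.clip(_DIPOLE_CUTOFF - dist[near] / tum.radius, 0.0, 1.0)
                u[near] += taper[:, None] * dip
                # Separated corner/wake regions hug the bump below its apex;
                # the gap above the apex carries the fast bypass jet and is
                # left untouched.
                wall_dir = (tum.center - tum.station_point) / b.radius
                below_apex = (perp[near] @ wall_dir) >= b.radius - 1.25 * tum.radius
                q = np.clip((dist[near] - tum.radius) / (_POCKET_EXTENT * tum.radius),
                            _POCKET_FLOOR, 1.0)
                u[near] *= np.where(below_apex, q, 1.0)[:, None]
        return u

    # -- diagnostics -------------------------------------------------------

    def flux_through(self, b_id: int, s_frac: float = 0.5,
                     n_rad: int = 48, n_ang: int = 96) -> float:
        """Axial volume flux through the branch cross-section at ``s_frac``."""
        b = self.tree[b_id]
        xg, wg = leggauss(n_rad)
        rr = 0.5 * b.radius * (xg + 1.0)
        wr = 0.5 * b.radius * wg
        ang = 2.0 * np.pi * (np.arange(n_ang) + 0.5) / n_ang
        e1 = b.side_hat
        e2 = np.cross(b.direction, e1)
        station = b.start + s_frac * b.length * b.direction
        R, A = np.meshgrid(rr, ang, indexing="ij")
        pts = (station[None, :]
               + (R * np.cos(A)).ravel()[:, None] * e1
               + (R * np.sin(A)).ravel()[:, None] * e2)
        u = self.velocity(pts)
        un = u @ b.direction
        w2d = np.outer(wr * rr, np.full(n_ang, 2.0 * np.pi / n_ang)).ravel()
        return float(np.sum(un * w2d))

    def station_mean_speed(self, b_id: int, s: float, rng=None, n: int = 4000) -> float:
        """Area-mean |u| over the *open* lumen at axial station ``s`` (meters)."""
        rng = np.random.default_rng(0) if rng is None else rng
        b = self.tree[b_id]
        e1 = b.side_hat
        e2 = np.cross(b.direction, e1)
        station = b.start + s * b.direction
        rad = b.radius * np.sqrt(rng.random(n))
        ang = 2.0 * np.pi * rng.random(n)
        pts = (station[None, :] + (rad * np.cos(ang))[:, None] * e1
               + (rad * np.sin(ang))[:, None] * e2)
        keep = self.tree.inside_lumen(pts)
        u = self.velocity(pts[keep])
        return float(np.mean(np.linalg.norm(u, axis=1)))


@dataclass
class UniformFlow:
    """Constant-velocity stand-in used by transport unit tests and oracles."""

    u: np.ndarray
    rho_a: float = AIR_DENSITY
    eta: float = AIR_VISCOSITY

    def velocity(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        return np.broadcast_to(np.asarray(self.u, dtype=float), pts.shape).copy()


def solve_flow(
    tree: LungTree,
    q_lpm: float = 15.0,
    skew: float = 0.3,
    rho_a: float = AIR_DENSITY,
    eta: float = AIR_VISCOSITY,
) -> FlowField:
    """Build the surrogate flow field for inlet rate ``q_lpm`` (L/min)."""
    if q_lpm <= 0:
        raise ValueError("inlet flow rate must be positive")
    q = lpm_to_m3s(q_lpm)
    flows = _network_flows(tree, q, eta)
    return FlowField(tree, q, flows, skew=skew, rho_a=rho_a, eta=eta)


# --------------------------------------------------------------------------
# External (gridded) fields
# --------------------------------------------------------------------------

class GriddedFlowField:
    """Velocity field interpolated from a structured grid (e.g. a CFD export).

    Conservation is *checked and reported*, not enforced: see
    :meth:`conservation_report`.
    """

    def __init__(self, origin, spacing, shape, u_grid,
                 rho_a: float = AIR_DENSITY, eta: float = AIR_VISCOSITY):
        from scipy.interpolate import RegularGridInterpolator

        self.origin = np.asarray(origin, dtype=float)
        self.spacing = float(spacing)
        self.shape = tuple(shape)
        self.u_grid = np.asarray(u_grid, dtype=float)
        self.rho_a = rho_a
        self.eta = eta
        axes = [self.origin[i] + self.spacing * np.arange(self.shape[i]) for i in range(3)]
        self._interp = RegularGridInterpolator(axes, self.u_grid, method="linear",
                                               bounds_error=False, fill_value=0.0)

    def velocity(self, pts: np.ndarray) -> np.ndarray:
        return self._interp(np.atleast_2d(pts))

    def conservation_report(self) -> Mapping[str, float]:
        """Divergence statistics of the gridded field (finite differences)."""
        h = self.spacing
        div = (
            np.gradient(self.u_grid[..., 0], h, axis=0)
            + np.gradient(self.u_grid[..., 1], h, axis=1)
            + np.gradient(self.u_grid[..., 2], h, axis=2)
        )
        speed = np.linalg.norm(self.u_grid, axis=-1)
        scale = max(float(speed.max()), 1e-300) / h
        return {
            "max_abs_div": float(np.abs(div).max()),
            "rms_div": float(np.sqrt(np.mean(div**2))),
            "normalized_max_div": float(np.abs(div).max() / scale),
            "zero_fraction": float(np.mean(speed == 0.0)),
        }

    def coverage_report(self, tree: LungTree, n: int = 2000, rng=None) -> Mapping[str, float]:
        """Fraction of lumen sample points with zero (uncovered) velocity."""
        rng = np.random.default_rng(0) if rng is None else rng
        lo, hi = tree.bounding_box()
        pts, got = [], 0
        while got < n:
            cand = rng.uniform(lo, hi, size=(4 * n, 3))
            keep = cand[tree.inside_lumen(cand)]
            pts.append(keep)
            got += len(keep)
        pts = np.concatenate(pts)[:n]
        u = self.velocity(pts)
        zero = np.linalg.norm(u, axis=1) == 0.0
        return {"uncovered_fraction": float(np.mean(zero))}


def import_flow(path, rho_a: float = AIR_DENSITY, eta: float = AIR_VISCOSITY) -> GriddedFlowField:
    """Load a velocity field from a legacy-VTK structured-points file.

    The file must carry a 3-component point-data array named ``velocity``
    (as written by :func:`export_velocity_vtk`).
    """
    from . import vtkio

    origin, spacing, shape, arrays = vtkio.read_structured_points(path)
    if "velocity" not in arrays:
        raise ValueError(f"{path}: no 'velocity' vector array in VTK file")
    return GriddedFlowField(origin, spacing, shape, arrays["velocity"],
                            rho_a=rho_a, eta=eta)


def export_velocity_vtk(flow, tree: LungTree, path, spacing: float = 2e-3,
                        margin: float = 2e-3) -> None:
    """Sample ``flow`` on a lumen-masked grid and write legacy VTK."""
    from . import vtkio

    lo, hi = tree.bounding_box(margin=margin)
    shape = tuple(int(np.ceil((hi[i] - lo[i]) / spacing)) + 1 for i in range(3))
    xs, ys, zs = (lo[i] + spacing * np.arange(shape[i]) for i in range(3))
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    u = np.zeros_like(pts)
    mask = tree.inside_lumen(pts)
    u[mask] = flow.velocity(pts[mask])
    vtkio.write_structured_points(path, lo, spacing, shape,
                                  vectors={"velocity": u.reshape(shape + (3,))})
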