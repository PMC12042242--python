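"""Static magnetic field of a fully magnetized bulk superconducting cylinder.

A single-grain bulk high-temperature superconductor, once magnetized, carries
a persistent azimuthal current density equal to its critical current density
``Jc`` everywhere (Bean critical-state idealization, no flux creep).  The
trapped field at the center of the top surface then has the closed form

    B_T = k * mu0 * Jc * a,      k = t/(2a) * asinh(a/t)

for a cylinder of radius ``a`` and thickness ``t``.  This module computes the
full 3-D field of that current distribution by Biot-Savart superposition of
circular loops (off-axis loop field via complete elliptic integrals), supports
the field-dependent Kim model ``Jc(B) = Jc0 * B0/(B0 + |B|)`` through a
damped fixed-point magnetization, calibrates ``Jc0`` so that the simulated
peak surface field matches a measured value, and precomputes Cartesian maps
of ``B``, ``H`` and ``grad(H^2)`` for the particle-transport stage.

Everything is SI; positions are world-frame 3-vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.interpolate import RectBivariateSpline
from scipy.optimize import brentq
from scipy.special import ellipe, ellipk

MU0 = 4.0e-7 * np.pi

__all__ = [
    "MU0",
    "JcCurve",
    "BulkMagnet",
    "CurrentDistribution",
    "FieldMap",
    "bean_k_factor",
    "trapped_field_peak",
    "magnetize",
    "field_at_point",
    "field_at_points",
    "calibrate_jc",
    "build_field_map",
    "on_axis_field",
    "dipole_moment",
]


# --------------------------------------------------------------------------
# Bean closed forms
# --------------------------------------------------------------------------

def bean_k_factor(a: float, t: float) -> float:
    """Finite-cylinder Bean correction factor ``k = t/(2a) asinh(a/t)``.

    Converts the infinite-cylinder Bean trapped field ``mu0 Jc a`` to the
    value at the center of the top surface of a cylinder of radius ``a`` and
    thickness ``t``.  Equal to the exact on-axis Biot-Savart result for a
    uniform azimuthal current density.
    """
    if a <= 0 or t <= 0:
        raise ValueError(f"magnet dimensions must be positive, got a={a}, t={t}")
    return t / (2.0 * a) * np.arcsinh(a / t)


def trapped_field_peak(jc0: float, a: float, t: float) -> float:
    """Peak trapped flux density ``B_T = k mu0 Jc0 a`` (constant-Jc mode)."""
    return bean_k_factor(a, t) * MU0 * jc0 * a


def on_axis_field(jc0: float, a: float, t: float, z: np.ndarray | float) -> np.ndarray | float:
    """Exact on-axis ``Bz`` at height ``z`` above the top surface (constant Jc).

    ``Bz(z) = (mu0 Jc/2) [ (z+t) asinh(a/(z+t)) - z asinh(a/z) ]`` for z >= 0;
    the z = 0 limit reproduces :func:`trapped_field_peak`.
    """
    z = np.asarray(z, dtype=float)
    zt = z + t
    term1 = zt * np.arcsinh(a / zt)
    term2 = np.where(z > 0, z * np.arcsinh(a / np.where(z > 0, z, 1.0)), 0.0)
    return 0.5 * MU0 * jc0 * (term1 - term2)


def dipole_moment(jc0: float, a: float, t: float) -> float:
    """Magnetic moment ``m = pi Jc0 t a^3 / 3`` of the uniform current cylinder."""
    return np.pi * jc0 * t * a**3 / 3.0


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class JcCurve:
    """Critical current density model.

    ``constant``: Jc(B) = jc0.  ``kim``: Jc(B) = jc0 * b0 / (b0 + |B|).
    """

    model: Literal["constant", "kim"]
    jc0: float
    b0: float | None = None

    def __post_init__(self) -> None:
        if self.jc0 <= 0:
            raise ValueError("Jc0 must be positive")
        if self.model == "kim" and (self.b0 is None or self.b0 <= 0):
            raise ValueError("Kim model requires B0 > 0")
        if self.model not in ("constant", "kim"):
            raise ValueError(f"unknown Jc model {self.model!r}")

    def __call__(self, b_abs: np.ndarray | float) -> np.ndarray | float:
        b_abs = np.abs(np.asarray(b_abs, dtype=float))
        if self.model == "constant":
            return np.broadcast_to(self.jc0, b_abs.shape).copy() if b_abs.shape else self.jc0
        return self.jc0 * self.b0 / (self.b0 + b_abs)


@dataclass(frozen=True)
class BulkMagnet:
    """Cylindrical bulk superconducting magnet.

    ``center`` is the center of the *top* surface (the face toward the lung);
    the body extends a distance ``t`` behind it along ``-axis``.
    """

    a: float
    t: float
    jc: JcCurve
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        if self.a <= 0 or self.t <= 0:
            raise ValueError("magnet dimensions must be positive")
        ax = np.asarray(self.axis, dtype=float)
        n = np.linalg.norm(ax)
        if not np.isfinite(n) or n == 0:
            raise ValueError("axis must be a nonzero vector")
        object.__setattr__(self, "axis", tuple(ax / n))
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))

    @property
    def k_factor(self) -> float:
        return bean_k_factor(self.a, self.t)

    def to_local(self, pts: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World points -> (rho, z, rho_hat) in the magnet frame.

        z is measured from the top surface along ``axis`` (positive in front
        of the magnet); rho_hat is the world-frame radial unit vector (zero
        on the axis).
        """
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        ax = np.asarray(self.axis)
        rel = pts - np.asarray(self.center)
        z = rel @ ax
        rho_vec = rel - z[:, None] * ax
        rho = np.linalg.norm(rho_vec, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            rho_hat = np.where(rho[:, None] > 1e-300, rho_vec / rho[:, None], 0.0)
        return rho, z, rho_hat


@dataclass
class CurrentDistribution:
    """Azimuthal current density sampled on a quadrature grid of the cross-section.

    ``r_nodes``/``z_nodes`` are flattened (r', z') Gauss-Legendre nodes inside
    the cylinder (z' in [-t, 0] from the top face), ``weights`` the matching
    area weights (dr' dz'), and ``j`` the local current density (A/m^2).
    """

    r_nodes: np.ndarray
    z_nodes: np.ndarray
    weights: np.ndarray
    j: np.ndarray
    shape: tuple[int, int]
    converged: bool = True
    iterations: int = 1
    residuals: list = field(default_factory=list)

    def moment(self) -> float:
        """Total magnetic moment ``sum(pi r'^2 J dA)`` of the distribution."""
        return float(np.sum(np.pi * self.r_nodes**2 * self.j * self.weights))


class MagnetizationError(RuntimeError):
    """Kim-model fixed point failed to converge; carries the residual history."""

    def __init__(self, residuals: list[float]):
        super().__init__(
            f"magnetization fixed point did not converge after {len(residuals)} "
            f"iterations (last residual {residuals[-1]:.3e})"
        )
        self.residuals = residuals


# --------------------------------------------------------------------------
# Quadrature node construction
# --------------------------------------------------------------------------

def _gl_panels(edges: np.ndarray, order: int) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Legendre nodes/weights over consecutive panels [edges[i], edges[i+1]]."""
    x0, w0 = leggauss(order)
    nodes, weights = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        h = 0.5 * (hi - lo)
        nodes.append(lo + h * (x0 + 1.0))
        weights.append(h * w0)
    return np.concatenate(nodes), np.concatenate(weights)


def _source_nodes(a: float, t: float, refined: bool) -> tuple[np.ndarray, np.ndarray, np.ndarray, tuple[int, int]]:
    """Quadrature nodes over the (r', z') cross-section.

    The refined set packs panels geometrically toward the top face and both
    radial extremes, where the integrand is near-singular for probe points on
    or near the surface.  The coarse set is ample for probes with a clearance
    of a few tenths of ``a``.
    """
    if refined:
        r_edges = a * np.array([0.0, 1 / 27, 1 / 9, 1 / 3, 2 / 3, 8 / 9, 26 / 27, 1.0])
        z_edges = -t * np.array([1.0, 1 / 3, 1 / 9, 1 / 27, 0.0])
        rn, rw = _gl_panels(r_edges, 10)
        zn, zw = _gl_panels(z_edges, 10)
    else:
        rn, rw = _gl_panels(np.array([0.0, a]), 32)
        zn, zw = _gl_panels(np.array([-t, 0.0]), 20)
    R, Z = np.meshgrid(rn, zn, indexing="ij")
    W = np.outer(rw, zw)
    return R.ravel(), Z.ravel(), W.ravel(), (rn.size, zn.size)


# --------------------------------------------------------------------------
# Biot-Savart superposition of circular loops
# --------------------------------------------------------------------------

def _loop_superposition(
    rho: np.ndarray,
    z: np.ndarray,
    src_r: np.ndarray,
    src_z: np.ndarray,
    src_i: np.ndarray,
    chunk: int = 256,
    reg: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """(B_rho, B_z) at cylindrical probe points from a set of current loops.

    Each loop has radius ``src_r``, height ``src_z`` and current ``src_i``.
    Uses the standard complete-elliptic-integral expressions; ``reg`` is a
    lower bound on the near-loop denominator (squared distance to the loop)
    used to regularize self-field evaluations inside the conductor.
    """
    rho = np.asarray(rho, dtype=float).ravel()
    z = np.asarray(z, dtype=float).ravel()
    brho = np.zeros_like(rho)
    bz = np.zeros_like(rho)
    for lo in range(0, rho.size, chunk):
        sl = slice(lo, min(lo + chunk, rho.size))
        p = rho[sl][:, None]
        dz = z[sl][:, None] - src_z[None, :]
        R = src_r[None, :]
        q = (R + p) ** 2 + dz**2
        denom = (R - p) ** 2 + dz**2
        if reg > 0.0:
            denom = np.maximum(denom, reg)
        m = np.clip(4.0 * R * p / q, 0.0, 1.0 - 1e-14)
        K = ellipk(m)
        E = ellipe(m)
        pref = MU0 * src_i[None, :] / (2.0 * np.pi * np.sqrt(q))
        bz[sl] = np.sum(pref * (K + E * (R**2 - p**2 - dz**2) / denom), axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            br = pref * dz / np.where(p > 0, p, 1.0) * (-K + E * (R**2 + p**2 + dz**2) / denom)
        brho[sl] = np.sum(np.where(p > 0, br, 0.0), axis=1)
    return brho, bz


def field_at_points(
    magnet: BulkMagnet,
    current: CurrentDistribution,
    pts: np.ndarray,
    reg: float = 0.0,
) -> np.ndarray:
    """Magnetostatic ``B`` (T) at world points ``pts`` (N, 3) -> (N, 3)."""
    pts = np.atleast_2d(np.asarray(pts, dtype=float))
    rho, z, rho_hat = magnet.to_local(pts)
    src_i = current.j * current.weights
    brho, bz = _loop_superposition(rho, z, current.r_nodes, current.z_nodes, src_i, reg=reg)
    ax = np.asarray(magnet.axis)
    return brho[:, None] * rho_hat + bz[:, None] * ax


def field_at_point(magnet: BulkMagnet, current: CurrentDistribution, x) -> np.ndarray:
    """``B`` (T) at a single world point; see :func:`field_at_points`."""
    return field_at_points(magnet, current, np.asarray(x, dtype=float)[None, :])[0]


# --------------------------------------------------------------------------
# Magnetization
# --------------------------------------------------------------------------

def magnetize(
    magnet: BulkMagnet,
    damping: float = 0.5,
    tol: float = 1e-3,
    max_iter: int = 100,
) -> CurrentDistribution:
    """Fully magnetized critical-state current distribution of ``magnet``.

    Constant-Jc mode returns the uniform distribution in one pass.  Kim mode
    iterates ``J(r,z) <- Jc(|B(r,z)|)`` with under-relaxation until the
    maximum relative change drops below ``tol``.
    """
    rn, zn, w, shape = _source_nodes(magnet.a, magnet.t, refined=True)
    if magnet.jc.model == "constant":
        j = np.full(rn.shape, magnet.jc.jc0)
        return CurrentDistribution(rn, zn, w, j, shape, converged=True, iterations=1)

    # Self-field regularization scale: half the local panel spacing.
    reg = (0.02 * min(magnet.a, magnet.t)) ** 2
    j = np.full(rn.shape, magnet.jc.jc0)
    residuals: list[float] = []
    for it in range(1, max_iter + 1):
        brho, bz = _loop_superposition(rn, zn, rn, zn, j * w, reg=reg)
        b_abs = np.hypot(brho, bz)
        j_target = np.asarray(magnet.jc(b_abs))
        j_new = (1.0 - damping) * j + damping * j_target
        res = float(np.max(np.abs(j_new - j) / np.maximum(np.abs(j), 1.0)))
        residuals.append(res)
        j = j_new
        if res < tol:
            return CurrentDistribution(rn, zn, w, j, shape, converged=True,
                                       iterations=it, residuals=residuals)
    raise MagnetizationError(residuals)


def peak_surface_field(magnet: BulkMagnet, current: CurrentDistribution | None = None) -> float:
    """Simulated |B| at the center of the magnet top surface."""
    if current is None:
        current = magnetize(magnet)
    b = field_at_point(magnet, current, np.asarray(magnet.center))
    return float(np.linalg.norm(b))


def calibrate_jc(
    target_bt: float,
    a: float,
    t: float,
    model: Literal["constant", "kim"] = "constant",
    b0: float = 1.5,
) -> JcCurve:
    """Jc curve whose magnetized peak surface field equals ``target_bt``.

    Constant mode inverts the Bean closed form exactly; Kim mode root-finds
    on ``Jc0`` at fixed ``b0`` against the simulated peak field.
    """
    if target_bt <= 0:
        raise ValueError("target peak field must be positive")
    jc0_const = target_bt / (bean_k_factor(a, t) * MU0 * a)
    if model == "constant":
        return JcCurve("constant", jc0_const)

    def residual(jc0: float) -> float:
        m = BulkMagnet(a, t, JcCurve("kim", jc0, b0))
        return peak_surface_field(m) - target_bt

    # Kim suppression means jc0 must exceed the constant-mode value.
    lo, hi = jc0_const, jc0_const * (1.0 + 2.0 * target_bt / b0)
    while residual(hi) < 0:
        hi *= 2.0
        if hi > 1e3 * jc0_const:
            raise RuntimeError("Kim calibration bracket failed")
    jc0 = brentq(residual, lo, hi, rtol=1e-6)
    return JcCurve("kim", jc0, b0)


# --------------------------------------------------------------------------
# Field maps
# --------------------------------------------------------------------------

class _AxiTable:
    """Bicubic spline of (B_rho, B_z) on an axisymmetric (rho, z) table.

    The field of the magnetized cylinder is axisymmetric, so a 2-D table plus
    spline evaluation replaces per-point Biot-Savart sums when populating 3-D
    Cartesian maps.  Valid for probes with z-clearance >= ``z_min`` above the
    top surface.
    """

    def __init__(self, magnet: BulkMagnet, current: CurrentDistribution,
                 rho_max: float, z_min: float, z_max: float, step: float = 1e-3):
        pad = 4.0 * step
        self.rho = np.arange(0.0, rho_max + pad + step, step)
        self.z = np.arange(z_min - pad, z_max + pad + step, step)
        P, Z = np.meshgrid(self.rho, self.z, indexing="ij")
        src_i = current.j * current.weights
        brho, bz = _loop_superposition(P.ravel(), Z.ravel(), current.r_nodes,
                                       current.z_nodes, src_i, chunk=2048)
        self._brho = RectBivariateSpline(self.rho, self.z, brho.reshape(P.shape))
        self._bz = RectBivariateSpline(self.rho, self.z, bz.reshape(P.shape))

    def eval(self, rho: np.ndarray, z: np.ndarray):
        brho = self._brho.ev(rho, z)
        bz = self._bz.ev(rho, z)
        return brho, bz

    def eval_grad_h2(self, rho: np.ndarray, z: np.ndarray):
        """(dH2/drho, dH2/dz) with H = B/mu0 (air/tissue, M = 0)."""
        brho = self._brho.ev(rho, z)
        bz = self._bz.ev(rho, z)
        dbr_dr = self._brho.ev(rho, z, dx=1)
        dbz_dr = self._bz.ev(rho, z, dx=1)
        dbr_dz = self._brho.ev(rho, z, dy=1)
        dbz_dz = self._bz.ev(rho, z, dy=1)
        inv = 1.0 / MU0**2
        g_rho = 2.0 * inv * (brho * dbr_dr + bz * dbz_dr)
        g_z = 2.0 * inv * (brho * dbr_dz + bz * dbz_dz)
        return g_rho, g_z


class FieldMapLookupError(KeyError):
    """Probe point outside the stored field-map bounding box."""


@dataclass
class FieldMap:
    """B, H and grad(H^2) on a regular Cartesian grid with trilinear queries.

    Outside the magnet ``M = 0`` so ``H = B / mu0`` identically; only ``B``
    and ``grad(H^2)`` are stored, ``H`` is derived on demand.
    """

    origin: np.ndarray
    spacing: float
    shape: tuple[int, int, int]
    b: np.ndarray          # (nx, ny, nz, 3)
    grad_h2: np.ndarray    # (nx, ny, nz, 3)

    @classmethod
    def zero(cls, box, spacing: float) -> "FieldMap":
        """All-zero map (magnet disabled) over ``box = (lo, hi)``."""
        lo, hi = (np.asarray(b, dtype=float) for b in box)
        shape = tuple(int(np.ceil((hi[i] - lo[i]) / spacing)) + 1 for i in range(3))
        return cls(lo, spacing, shape, np.zeros(shape + (3,)), np.zeros(shape + (3,)))

    @property
    def is_zero(self) -> bool:
        return not np.any(self.b)

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(self.origin[i] + self.spacing * np.arange(self.shape[i])
                     for i in range(3))

    def h(self) -> np.ndarray:
        return self.b / MU0

    def _trilinear(self, data: np.ndarray, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        f = (pts - self.origin) / self.spacing
        eps = 1e-9
        if np.any(f < -eps) or np.any(f > np.asarray(self.shape) - 1 + eps):
            raise FieldMapLookupError("probe point outside field map box")
        f = np.clip(f, 0.0, np.asarray(self.shape, dtype=float) - 1 - 1e-12)
        i0 = f.astype(int)
        w = f - i0
        out = np.zeros((pts.shape[0], data.shape[-1]))
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    wt = (np.where(dx, w[:, 0], 1 - w[:, 0])
                          * np.where(dy, w[:, 1], 1 - w[:, 1])
                          * np.where(dz, w[:, 2], 1 - w[:, 2]))
                    out += wt[:, None] * data[i0[:, 0] + dx, i0[:, 1] + dy, i0[:, 2] + dz]
        return out

    def b_at(self, pts: np.ndarray) -> np.ndarray:
        if self.is_zero:
            return np.zeros((np.atleast_2d(pts).shape[0], 3))
        return self._trilinear(self.b, pts)

    def h_at(self, pts: np.ndarray) -> np.ndarray:
        return self.b_at(pts) / MU0

    def grad_h2_at(self, pts: np.ndarray) -> np.ndarray:
        if self.is_zero:
            return np.zeros((np.atleast_2d(pts).shape[0], 3))
        return self._trilinear(self.grad_h2, pts)

    # -- diagnostics -------------------------------------------------------

    def divergence(self) -> np.ndarray:
        """Centered-difference div(B) on interior nodes, (nx-2, ny-2, nz-2)."""
        h = self.spacing
        return (
            (self.b[2:, 1:-1, 1:-1, 0] - self.b[:-2, 1:-1, 1:-1, 0])
            + (self.b[1:-1, 2:, 1:-1, 1] - self.b[1:-1, :-2, 1:-1, 1])
            + (self.b[1:-1, 1:-1, 2:, 2] - self.b[1:-1, 1:-1, :-2, 2])
        ) / (2.0 * h)

    def h2(self) -> np.ndarray:
        return np.sum(self.b**2, axis=-1) / MU0**2

    # -- I/O ---------------------------------------------------------------

    def to_csv(self, path) -> None:
        """Documented CSV export: x,y,z,Bx,By,Bz,gHx,gHy,gHz (SI units)."""
        import pandas as pd

        xs, ys, zs = self.axes()
        X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
        cols = {
            "x": X.ravel(), "y": Y.ravel(), "z": Z.ravel(),
            "Bx": self.b[..., 0].ravel(), "By": self.b[..., 1].ravel(),
            "Bz": self.b[..., 2].ravel(),
            "gHx": self.grad_h2[..., 0].ravel(),
            "gHy": self.grad_h2[..., 1].ravel(),
            "gHz": self.grad_h2[..., 2].ravel(),
        }
        pd.DataFrame(cols).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FieldMap":
        import pandas as pd

        df = pd.read_csv(path)
        xs = np.unique(df["x"].to_numpy())
        ys = np.unique(df["y"].to_numpy())
        zs = np.unique(df["z"].to_numpy())
        shape = (xs.size, ys.size, zs.size)
        spacing = float(xs[1] - xs[0]) if xs.size > 1 else float(zs[1] - zs[0])
        order = np.lexsort((df["z"], df["y"], df["x"]))
        b = np.stack([df[c].to_numpy()[order].reshape(shape) for c in ("Bx", "By", "Bz")], axis=-1)
        g = np.stack([df[c].to_numpy()[order].reshape(shape) for c in ("gHx", "gHy", "gHz")], axis=-1)
        return cls(np.array([xs[0], ys[0], zs[0]]), spacing, shape, b, g)

    def to_vtk(self, path) -> None:
        from . import vtkio

        vtkio.write_structured_points(
            path, self.origin, self.spacing, self.shape,
            vectors={"B": self.b, "gradH2": self.grad_h2},
        )


def build_field_map(
    magnet: BulkMagnet,
    current: CurrentDistribution,
    box,
    spacing: float = 1e-3,
) -> FieldMap:
    """Precompute ``B`` and ``grad(H^2)`` on a Cartesian grid over ``box``.

    ``box = (lo, hi)`` must enclose the lumen; the magnet itself must lie
    outside the box (the map represents the air/tissue region where M = 0).
    """
    lo, hi = (np.asarray(b, dtype=float) for b in box)
    if np.any(hi <= lo):
        raise ValueError("field map box is empty")
    shape = tuple(int(np.ceil((hi[i] - lo[i]) / spacing)) + 1 for i in range(3))
    xs, ys, zs = (lo[i] + spacing * np.arange(shape[i]) for i in range(3))
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    rho, z, rho_hat = magnet.to_local(pts)
    z_min = float(z.min())
    if z_min <= 0.05 * magnet.a:
        raise ValueError("field map box intersects or touches the magnet body")
    table = _AxiTable(magnet, current, float(rho.max()), z_min, float(z.max()),
                      step=min(1.5e-3, spacing))
    brho, bz = table.eval(rho, z)
    g_rho, g_z = table.eval_grad_h2(rho, z)
    ax = np.asarray(magnet.axis)
    b = brho[:, None] * rho_hat + bz[:, None] * ax
    g = g_rho[:, None] * rho_hat + g_z[:, None] * ax
    return FieldMap(lo, spacing, shape, b.reshape(shape + (3,)), g.reshape(shape + (3,)))
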