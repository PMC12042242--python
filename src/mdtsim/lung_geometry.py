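"""Planar Weibel G0-G3 airway tree with an obstructing epithelial tumor.

The airway is the classic symmetric dichotomous (Weibel) tree truncated at
generation 3: a trachea G0 and three generations of daughter branches, all
axes lying in the z = 0 plane, each branch a capped circular cylinder.  A
bronchial wall tumor is modeled as a sphere of radius ``r = r_ratio * R_host``
centered *on* the host-branch wall, so the part protruding into the lumen is
a spherical cap that grows from the epithelium and progressively obstructs
the airway.

Default dimensions (length, radius, mm): G0 120/9, G1 47.6/6.1, G2 19/4.15,
G3 7.6/2.8.  All stored quantities are SI meters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "WEIBEL_DIMS_MM",
    "TUMOR_STATIONS",
    "BranchSegment",
    "Tumor",
    "LungTree",
    "build_weibel_tree",
    "add_tumor",
    "classify_point",
    "open_area",
    "lens_area",
]

#: (length, radius) per generation, millimeters.
WEIBEL_DIMS_MM: tuple[tuple[float, float], ...] = (
    (120.0, 9.0),
    (47.6, 6.1),
    (19.0, 4.15),
    (7.6, 2.8),
)

#: Axial stations of the tumor center as fractions of the host branch length:
#: proximal / mid / distal thirds.
TUMOR_STATIONS = {"P0": 1.0 / 6.0, "P1": 0.5, "P2": 5.0 / 6.0}

_Z = np.array([0.0, 0.0, 1.0])


@dataclass(frozen=True)
class BranchSegment:
    """One cylindrical airway segment.

    ``side_hat = z_hat x direction`` is the in-plane normal used to define
    the tumor azimuth and the carinal-skew direction; ``sign`` records which
    daughter of its parent this branch is (+1/-1, 0 for the trachea).
    """

    id: int
    generation: int
    length: float
    radius: float
    start: np.ndarray
    direction: np.ndarray
    parent: int | None
    children: tuple[int, ...] = ()
    sign: int = 0

    @property
    def end(self) -> np.ndarray:
        return self.start + self.length * self.direction

    @property
    def side_hat(self) -> np.ndarray:
        return np.cross(_Z, self.direction)

    def frame_coords(self, pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Axial coordinate s and radial distance for world points (N, 3)."""
        pts = np.atleast_2d(pts)
        rel = pts - self.start
        s = rel @ self.direction
        perp = rel - s[:, None] * self.direction
        return s, np.linalg.norm(perp, axis=1)

    def contains(self, pts: np.ndarray, tol: float = 0.0) -> np.ndarray:
        s, radial = self.frame_coords(pts)
        return (s >= -tol) & (s <= self.length + tol) & (radial <= self.radius + tol)


@dataclass(frozen=True)
class Tumor:
    """Wall tumor: sphere of radius ``r`` centered on the host lumen wall.

    ``alpha_deg = 0`` places the tumor on the wall facing the magnet (the
    -z side of the planar tree); positive angles rotate it about the branch
    axis toward ``+side_hat``.
    """

    branch_id: int
    r_ratio: float
    location: str
    alpha_deg: float
    center: np.ndarray
    radius: float
    station_point: np.ndarray  # tumor axial station on the branch centerline
    station_s: float

    def cap_height(self) -> float:
        """Maximum protrusion of the cap into the lumen (equals ``radius``)."""
        return self.radius


@dataclass(frozen=True)
class LungTree:
    """Weibel airway tree: branch list, optional tumor, inlet/outlet discs."""

    branches: tuple[BranchSegment, ...]
    half_angle_deg: float
    tumor: Tumor | None = None

    def __getitem__(self, bid: int) -> BranchSegment:
        return self.branches[bid]

    @property
    def root(self) -> BranchSegment:
        return self.branches[0]

    @property
    def outlets(self) -> tuple[BranchSegment, ...]:
        return tuple(b for b in self.branches if not b.children)

    def inlet_center(self) -> np.ndarray:
        return self.root.start

    def path_length(self) -> float:
        """Centerline length from the inlet to any outlet (symmetric tree)."""
        total, b = 0.0, self.root
        while True:
            total += b.length
            if not b.children:
                return total
            b = self.branches[b.children[0]]

    def bounding_box(self, margin: float = 0.0):
        pts = []
        for b in self.branches:
            for p in (b.start, b.end):
                pts.append(p)
        pts = np.array(pts)
        lo = pts.min(axis=0) - self._max_radius() - margin
        hi = pts.max(axis=0) + self._max_radius() + margin
        return lo, hi

    def _max_radius(self) -> float:
        return max(b.radius for b in self.branches)

    # -- point queries -----------------------------------------------------

    def containing_branches(self, pts: np.ndarray, tol: float = 0.0) -> np.ndarray:
        """(N, n_branches) boolean containment matrix."""
        pts = np.atleast_2d(pts)
        return np.column_stack([b.contains(pts, tol) for b in self.branches])

    def branch_of(self, pts: np.ndarray) -> np.ndarray:
        """Branch id owning each point, -1 if outside all.

        Overlap regions at junctions go to the deepest containing branch;
        same-generation ties (sibling overlap near a carina) go to the branch
        whose axis is relatively closest.
        """
        pts = np.atleast_2d(pts)
        inside = self.containing_branches(pts)
        gens = np.array([b.generation for b in self.branches], dtype=float)
        closeness = np.empty((pts.shape[0], len(self.branches)))
        for j, b in enumerate(self.branches):
            _, radial = b.frame_coords(pts)
            closeness[:, j] = 1.0 - np.minimum(radial / b.radius, 1.0)
        score = np.where(inside, 10.0 * (gens[None, :] + 1.0) + closeness, -1.0)
        best = np.argmax(score, axis=1)
        best[~inside.any(axis=1)] = -1
        return best

    def in_tumor(self, pts: np.ndarray, tol: float = 0.0) -> np.ndarray:
        if self.tumor is None:
            return np.zeros(np.atleast_2d(pts).shape[0], dtype=bool)
        d = np.linalg.norm(np.atleast_2d(pts) - self.tumor.center, axis=1)
        return d <= self.tumor.radius + tol

    def inside_lumen(self, pts: np.ndarray) -> np.ndarray:
        """Inside the open airway: in some branch cylinder, not in the tumor."""
        return self.containing_branches(pts).any(axis=1) & ~self.in_tumor(pts)


def _rotate_in_plane(d: np.ndarray, angle_rad: float) -> np.ndarray:
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return np.array([c * d[0] - s * d[1], s * d[0] + c * d[1], 0.0])


def build_weibel_tree(
    dims_mm: Sequence[tuple[float, float]] = WEIBEL_DIMS_MM,
    half_angle_deg: float = 35.0,
) -> LungTree:
    """Build the symmetric planar tree from per-generation (length, radius).

    The trachea runs along +x ending at the carina (origin); each bifurcation
    opens by ``half_angle_deg`` per daughter about z.  A single-row ``dims_mm``
    yields a straight duct (used by the toy fixture).
    """
    if len(dims_mm) < 1:
        raise ValueError("need at least one generation")
    for L, R in dims_mm:
        if L <= 0 or R <= 0:
            raise ValueError("branch dimensions must be positive")
    if len(dims_mm) > 1 and not (0.0 < half_angle_deg < 90.0):
        raise ValueError("bifurcation half-angle must be in (0, 90) degrees")

    dims = [(L * 1e-3, R * 1e-3) for L, R in dims_mm]
    L0, R0 = dims[0]
    branches: list[BranchSegment] = [
        BranchSegment(0, 0, L0, R0, np.array([-L0, 0.0, 0.0]),
                      np.array([1.0, 0.0, 0.0]), None)
    ]
    frontier = [0]
    half = np.deg2rad(half_angle_deg)
    for gen in range(1, len(dims)):
        L, R = dims[gen]
        new_frontier = []
        for pid in frontier:
            parent = branches[pid]
            kids = []
            for sgn in (+1, -1):
                bid = len(branches)
                d = _rotate_in_plane(parent.direction, sgn * half)
                branches.append(BranchSegment(bid, gen, L, R, parent.end.copy(), d,
                                              pid, sign=sgn))
                kids.append(bid)
                new_frontier.append(bid)
            branches[pid] = replace(parent, children=tuple(kids))
        frontier = new_frontier
    return LungTree(tuple(branches), half_angle_deg)


def add_tumor(
    tree: LungTree,
    r_ratio: float = 0.8,
    location: str = "P1",
    alpha_deg: float = 0.0,
    host_branch: int | None = None,
) -> LungTree:
    """Attach a wall tumor to ``tree`` (returns a new tree).

    Default host is the first G1 daughter (the +y branch, the one the magnet
    axis is aligned over); for a single-branch tree the duct itself hosts.
    """
    if not (0.0 < r_ratio <= 1.0):
        raise ValueError("r_ratio must be in (0, 1]")
    if location not in TUMOR_STATIONS:
        raise ValueError(f"unknown tumor location {location!r}; use P0/P1/P2")
    if not (-90.0 <= alpha_deg <= 90.0):
        raise ValueError("alpha must be within [-90, 90] degrees")
    if host_branch is None:
        host_branch = 1 if len(tree.branches) > 1 else 0
    host = tree[host_branch]
    s_frac = TUMOR_STATIONS[location]
    s = s_frac * host.length
    station = host.start + s * host.direction
    alpha = np.deg2rad(alpha_deg)
    wall_dir = -np.cos(alpha) * _Z + np.sin(alpha) * host.side_hat
    center = station + host.radius * wall_dir
    tumor = Tumor(host_branch, r_ratio, location, alpha_deg, center,
                  r_ratio * host.radius, station, s)
    return LungTree(tree.branches, tree.half_angle_deg, tumor)


# --------------------------------------------------------------------------
# Cross-section occlusion
# --------------------------------------------------------------------------

def lens_area(r1: float, r2: float, d: float) -> float:
    """Intersection area of two discs with radii r1, r2 and center distance d."""
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        return np.pi * min(r1, r2) ** 2
    a1 = np.arccos(np.clip((d**2 + r1**2 - r2**2) / (2 * d * r1), -1, 1))
    a2 = np.arccos(np.clip((d**2 + r2**2 - r1**2) / (2 * d * r2), -1, 1))
    tri = 0.5 * np.sqrt(max((-d + r1 + r2) * (d + r1 - r2) * (d - r1 + r2) * (d + r1 + r2), 0.0))
    return r1**2 * a1 + r2**2 * a2 - tri


def open_area(tree: LungTree, s: np.ndarray | float) -> np.ndarray | float:
    """Open lumen cross-section area of the host branch at axial station ``s``.

    The tumor sphere cuts the plane at ``s`` in a disc of radius
    ``sqrt(r^2 - (s - s_c)^2)`` centered on the wall circle; the open area is
    the branch disc minus the lens overlap.
    """
    if tree.tumor is None:
        raise ValueError("tree has no tumor")
    host = tree[tree.tumor.branch_id]
    R, r, sc = host.radius, tree.tumor.radius, tree.tumor.station_s
    s_arr = np.atleast_1d(np.asarray(s, dtype=float))
    full = np.pi * R**2
    out = np.full(s_arr.shape, full)
    mask = np.abs(s_arr - sc) < r
    for i in np.nonzero(mask)[0]:
        rs = np.sqrt(r**2 - (s_arr[i] - sc) ** 2)
        out[i] = full - lens_area(R, rs, R)
    return out if np.ndim(s) else float(out[0])


# --------------------------------------------------------------------------
# Point classification
# --------------------------------------------------------------------------

def classify_point(tree: LungTree, x, tol: float = 1e-6) -> str:
    """Classify a world point against the watertight airway surface.

    Returns one of ``lumen``, ``wall``, ``tumor_surface``, ``outlet``,
    ``outside``.  Surface labels are assigned within ``tol`` of the
    corresponding boundary; the tumor takes precedence over the wall it
    grows from, and outlet discs over the adjoining wall rim.
    """
    x = np.asarray(x, dtype=float)[None, :]
    in_cyl = bool(tree.containing_branches(x, tol=tol).any())
    if tree.tumor is not None:
        dist = float(np.linalg.norm(x[0] - tree.tumor.center))
        if abs(dist - tree.tumor.radius) <= tol and in_cyl:
            return "tumor_surface"
        if dist < tree.tumor.radius - tol:
            return "outside"  # tumor interior is solid tissue
    for b in tree.outlets:
        s, radial = b.frame_coords(x)
        if abs(s[0] - b.length) <= tol and radial[0] <= b.radius + tol:
            return "outlet"
    if bool(tree.containing_branches(x, tol=-tol).any()):
        return "lumen"
    if in_cyl:
        return "wall"  # within the tol band of the airway surface
    return "outside"
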