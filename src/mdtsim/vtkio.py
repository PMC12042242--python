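"""Minimal legacy-VTK (ASCII) writers/readers used for export and exchange.

Covers exactly what the package needs: STRUCTURED_POINTS with point-data
scalars/vectors (field maps, velocity samples), POLYDATA polylines (particle
trajectories) and POLYDATA triangle meshes with cell scalars (airway surface
with a tagged tumor patch).  Files are plain text and readable by ParaView.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "write_structured_points",
    "read_structured_points",
    "write_polylines",
    "write_triangle_mesh",
    "tree_surface_mesh",
]


def _write_array_block(fh, data: np.ndarray) -> None:
    np.savetxt(fh, data.reshape(-1, data.shape[-1]) if data.ndim > 1 else data[:, None],
               fmt="%.9g")


def write_structured_points(path, origin, spacing, shape,
                            scalars: dict | None = None,
                            vectors: dict | None = None) -> None:
    """Write a regular grid; arrays are (nx, ny, nz[, 3]) with x slowest.

    VTK stores points x-fastest, so arrays are transposed on output.
    """
    nx, ny, nz = shape
    n = nx * ny * nz
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nmdtsim structured grid\nASCII\n")
        fh.write("DATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        fh.write(f"ORIGIN {origin[0]:.9g} {origin[1]:.9g} {origin[2]:.9g}\n")
        fh.write(f"SPACING {spacing:.9g} {spacing:.9g} {spacing:.9g}\n")
        fh.write(f"POINT_DATA {n}\n")
        for name, arr in (scalars or {}).items():
            fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
            _write_array_block(fh, np.asarray(arr).transpose(2, 1, 0).ravel())
        for name, arr in (vectors or {}).items():
            fh.write(f"VECTORS {name} float\n")
            a = np.asarray(arr)
            _write_array_block(fh, a.transpose(2, 1, 0, 3).reshape(-1, 3))


def read_structured_points(path):
    """Inverse of :func:`write_structured_points`.

    Returns ``(origin, spacing, shape, arrays)`` with arrays in
    (nx, ny, nz[, 3]) layout.
    """
    origin = spacing = shape = None
    arrays: dict[str, np.ndarray] = {}
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    n_pts = 0
    while i < len(lines):
        parts = lines[i].split()
        i += 1
        if not parts:
            continue
        kw = parts[0].upper()
        if kw == "DIMENSIONS":
            shape = tuple(int(p) for p in parts[1:4])
        elif kw == "ORIGIN":
            origin = np.array([float(p) for p in parts[1:4]])
        elif kw == "SPACING":
            spacing = float(parts[1])
        elif kw == "POINT_DATA":
            n_pts = int(parts[1])
        elif kw in ("SCALARS", "VECTORS"):
            name = parts[1]
            ncomp = 1 if kw == "SCALARS" else 3
            if kw == "SCALARS":
                i += 1  # LOOKUP_TABLE line
            vals: list[float] = []
            while i < len(lines) and len(vals) < n_pts * ncomp:
                vals.extend(float(v) for v in lines[i].split())
                i += 1
            arr = np.array(vals)
            nx, ny, nz = shape
            if ncomp == 1:
                arrays[name] = arr.reshape(nz, ny, nx).transpose(2, 1, 0)
            else:
                arrays[name] = arr.reshape(nz, ny, nx, 3).transpose(2, 1, 0, 3)
    if shape is None or origin is None or spacing is None:
        raise ValueError(f"{path}: not a structured-points legacy VTK file")
    return origin, spacing, shape, arrays


def write_polylines(path, polylines) -> None:
    """Write a list of (n_i, 3) arrays as VTK polylines (e.g. trajectories)."""
    pts = np.concatenate([np.asarray(p, dtype=float) for p in polylines]) \
        if polylines else np.zeros((0, 3))
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nmdtsim trajectories\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {len(pts)} float\n")
        _write_array_block(fh, pts)
        total = sum(len(p) + 1 for p in polylines)
        fh.write(f"LINES {len(polylines)} {total}\n")
        off = 0
        for p in polylines:
            ids = " ".join(str(off + j) for j in range(len(p)))
            fh.write(f"{len(p)} {ids}\n")
            off += len(p)


def write_triangle_mesh(path, vertices, triangles, cell_scalars: dict | None = None) -> None:
    vertices = np.asarray(vertices, dtype=float)
    triangles = np.asarray(triangles, dtype=int)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nmdtsim surface\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {len(vertices)} float\n")
        _write_array_block(fh, vertices)
        fh.write(f"POLYGONS {len(triangles)} {4 * len(triangles)}\n")
        for tri in triangles:
            fh.write(f"3 {tri[0]} {tri[1]} {tri[2]}\n")
        if cell_scalars:
            fh.write(f"CELL_DATA {len(triangles)}\n")
            for name, arr in cell_scalars.items():
                fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
                _write_array_block(fh, np.asarray(arr, dtype=float))


def tree_surface_mesh(tree, n_theta: int = 24, axial_step: float = 2e-3):
    """Triangulated airway surface with the tumor patch tagged (cell scalar 1).

    Branch walls are sampled as cylinder quad strips; the tumor cap is the
    part of its sphere inside the host cylinder.  Intended for visualization,
    not for the point classification (which is analytic).
    """
    verts: list[np.ndarray] = []
    tris: list[tuple[int, int, int]] = []
    tags: list[float] = []

    def add_ring_strip(rings, tag):
        base = len(verts)
        nr = len(rings[0])
        for ring in rings:
            verts.extend(ring)
        for i in range(len(rings) - 1):
            for j in range(nr):
                a = base + i * nr + j
                b = base + i * nr + (j + 1) % nr
                c = base + (i + 1) * nr + j
                d = base + (i + 1) * nr + (j + 1) % nr
                tris.append((a, b, d))
                tris.append((a, d, c))
                tags.extend([tag, tag])

    theta = 2.0 * np.pi * np.arange(n_theta) / n_theta
    for b in tree.branches:
        e1 = b.side_hat
        e2 = np.cross(b.direction, e1)
        n_ax = max(2, int(np.ceil(b.length / axial_step)) + 1)
        rings = []
        for s in np.linspace(0.0, b.length, n_ax):
            c = b.start + s * b.direction
            rings.append([c + b.radius * (np.cos(t) * e1 + np.sin(t) * e2)
                          for t in theta])
        add_ring_strip(rings, 0.0)

    if tree.tumor is not None:
        tum = tree.tumor
        host = tree[tum.branch_id]
        nhat = (tum.center - tum.station_point) / np.linalg.norm(
            tum.center - tum.station_point)
        t1 = host.direction
        t2 = np.cross(nhat, t1)
        base = len(verts)
        n_u, n_v = 24, 24
        grid = np.zeros((n_u, n_v), dtype=int)
        for iu, uu in enumerate(np.linspace(0.0, np.pi, n_u)):
            for iv, vv in enumerate(np.linspace(0.0, 2 * np.pi, n_v, endpoint=False)):
                p = tum.center + tum.radius * (
                    -np.cos(uu) * nhat
                    + np.sin(uu) * (np.cos(vv) * t1 + np.sin(vv) * t2))
                grid[iu, iv] = len(verts)
                verts.append(p)
        for iu in range(n_u - 1):
            for iv in range(n_v):
                a, bq = grid[iu, iv], grid[iu, (iv + 1) % n_v]
                c, d = grid[iu + 1, iv], grid[iu + 1, (iv + 1) % n_v]
                centroid = (verts[a] + verts[bq] + verts[c] + verts[d]) / 4.0
                if host.contains(centroid[None, :])[0]:
                    tris.append((a, bq, d))
                    tris.append((a, d, c))
                    tags.extend([1.0, 1.0])
        _ = base
    return np.asarray(verts), np.asarray(tris, dtype=int), np.asarray(tags)
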