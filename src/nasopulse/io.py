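"""File formats: binary STL (via trimesh), legacy ASCII VTK, patch-table JSON.

Legacy VTK is used in its two classic flavours: ``STRUCTURED_POINTS`` for
cell-centered grid fields (written as point data at the cell centers) and
``POLYDATA`` for surfaces and parcel clouds.  The writers emit plain text so
outputs stay diff-able and portable.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import trimesh

from .config import NasopulseError
from .geometry import FlowGrid, PatchInfo, SurfaceMesh

__all__ = [
    "write_stl",
    "read_stl",
    "write_patch_json",
    "read_patch_json",
    "write_vtk_structured_points",
    "read_vtk_structured_points",
    "write_vtk_polydata_mesh",
    "write_vtk_point_cloud",
    "grid_fields_to_vtk",
]


# ---------------------------------------------------------------------------
# STL + patch sidecar
# ---------------------------------------------------------------------------


def write_stl(mesh: SurfaceMesh, path: str | Path) -> None:
    """Binary STL of the triangulated surface (patches go to the JSON sidecar)."""
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    Path(path).write_bytes(tm.export(file_type="stl"))


def read_stl(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read an STL file; returns (vertices, faces)."""
    tm = trimesh.load(str(path), file_type="stl", process=False)
    return np.asarray(tm.vertices, float), np.asarray(tm.faces, np.int64)


def write_patch_json(mesh: SurfaceMesh, path: str | Path) -> None:
    areas = mesh.patch_areas()
    table = {
        name: {
            "role": info.role,
            "region": info.region,
            "area_mm2": areas[name] * 1e6,
        }
        for name, info in mesh.patch_table.items()
    }
    Path(path).write_text(json.dumps(table, indent=2, sort_keys=True))


def read_patch_json(path: str | Path) -> dict[str, PatchInfo]:
    raw = json.loads(Path(path).read_text())
    return {k: PatchInfo(role=v["role"], region=v["region"]) for k, v in raw.items()}


# ---------------------------------------------------------------------------
# Legacy VTK structured points (grid fields)
# ---------------------------------------------------------------------------


def write_vtk_structured_points(
    path: str | Path,
    origin: np.ndarray,
    dx: float,
    fields: dict[str, np.ndarray],
    title: str = "nasopulse grid fields",
) -> None:
    """Write cell-centered fields as legacy-VTK point data at cell centers.

    Scalar fields have shape (nx, ny, nz); vector fields (nx, ny, nz, 3).
    """
    if not fields:
        raise NasopulseError("no fields to write")
    shapes = {v.shape[:3] for v in fields.values()}
    if len(shapes) != 1:
        raise NasopulseError(f"inconsistent field shapes: {shapes}")
    nx, ny, nz = shapes.pop()
    first_center = np.asarray(origin, float) + 0.5 * dx
    lines = [
        "# vtk DataFile Version 3.0",
        title,
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx} {ny} {nz}",
        f"ORIGIN {first_center[0]:.12g} {first_center[1]:.12g} {first_center[2]:.12g}",
        f"SPACING {dx:.12g} {dx:.12g} {dx:.12g}",
        f"POINT_DATA {nx * ny * nz}",
    ]
    for name, arr in fields.items():
        if arr.ndim == 3:
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            flat = arr.astype(float).ravel(order="F")
            lines.extend(" ".join(f"{v:.9g}" for v in flat[i : i + 9]) for i in range(0, len(flat), 9))
        elif arr.ndim == 4 and arr.shape[3] == 3:
            lines.append(f"VECTORS {name} double")
            # x fastest, then y, then z (VTK point order)
            flat = arr.astype(float).transpose(2, 1, 0, 3).reshape(-1, 3)
            lines.extend(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}" for v in flat)
        else:
            raise NasopulseError(f"field {name} has unsupported shape {arr.shape}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_vtk_structured_points(
    path: str | Path,
) -> tuple[np.ndarray, float, dict[str, np.ndarray]]:
    """Read back a structured-points file written by this package.

    Returns (grid origin = first center - dx/2, dx, fields dict).
    """
    tokens = Path(path).read_text().split("\n")
    it = iter(tokens)
    dims = None
    first_center = None
    spacing = None
    fields: dict[str, np.ndarray] = {}
    npoints = 0
    i = 0
    lines = tokens
    while i < len(lines):
        ln = lines[i].strip()
        i += 1
        if not ln:
            continue
        parts = ln.split()
        key = parts[0].upper()
        if key == "DIMENSIONS":
            dims = tuple(int(x) for x in parts[1:4])
        elif key == "ORIGIN":
            first_center = np.array([float(x) for x in parts[1:4]])
        elif key == "SPACING":
            spacing = float(parts[1])
        elif key == "POINT_DATA":
            npoints = int(parts[1])
        elif key == "SCALARS":
            name = parts[1]
            i += 1  # skip LOOKUP_TABLE
            vals: list[float] = []
            while len(vals) < npoints:
                vals.extend(float(x) for x in lines[i].split())
                i += 1
            arr = np.array(vals).reshape(dims, order="F")
            fields[name] = arr
        elif key == "VECTORS":
            name = parts[1]
            vals = []
            while len(vals) < 3 * npoints:
                vals.extend(float(x) for x in lines[i].split())
                i += 1
            arr = np.array(vals).reshape(dims[2], dims[1], dims[0], 3).transpose(2, 1, 0, 3)
            fields[name] = arr
    if dims is None or first_center is None or spacing is None:
        raise NasopulseError(f"{path} is not a structured-points VTK file")
    origin = first_center - 0.5 * spacing
    del it
    return origin, spacing, fields


def load_velocity_vtk(grid: FlowGrid, path: str | Path, field: str = "velocity") -> None:
    """Set the grid's velocity from an externally supplied structured-points
    file (same dimensions and spacing as the grid)."""
    origin, dx, fields = read_vtk_structured_points(path)
    if field not in fields:
        raise NasopulseError(f"{path} has no vector field {field!r}")
    vel = fields[field]
    if vel.shape[:3] != grid.shape:
        raise NasopulseError(
            f"velocity grid {vel.shape[:3]} does not match flow grid {grid.shape}"
        )
    if abs(dx - grid.dx) > 1e-9 * grid.dx or np.any(np.abs(origin - grid.origin) > 1e-9):
        raise NasopulseError("velocity file origin/spacing does not match the grid")
    grid.velocity = vel


def grid_fields_to_vtk(grid: FlowGrid, path: str | Path, extra: dict[str, np.ndarray] | None = None) -> None:
    """Dump the standard field set of a :class:`FlowGrid`."""
    fields: dict[str, np.ndarray] = {
        "inside": grid.inside.astype(float),
        "velocity": grid.velocity,
        "k_sgs": grid.k_sgs,
        "scalar_c": grid.scalar_c,
        "source": grid.source,
    }
    if extra:
        fields.update(extra)
    write_vtk_structured_points(path, grid.origin, grid.dx, fields)


# ---------------------------------------------------------------------------
# Legacy VTK polydata (surfaces, parcel clouds)
# ---------------------------------------------------------------------------


def write_vtk_polydata_mesh(mesh: SurfaceMesh, path: str | Path, cell_data: dict[str, np.ndarray] | None = None) -> None:
    """Triangulated surface with per-triangle patch ids as cell data."""
    v = mesh.vertices
    f = mesh.faces
    lines = [
        "# vtk DataFile Version 3.0",
        "nasopulse surface; patch names in JSON sidecar",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {len(v)} double",
    ]
    lines.extend(f"{p[0]:.12g} {p[1]:.12g} {p[2]:.12g}" for p in v)
    lines.append(f"POLYGONS {len(f)} {4 * len(f)}")
    lines.extend(f"3 {a} {b} {c}" for a, b, c in f)
    lines.append(f"CELL_DATA {len(f)}")
    lines.append("SCALARS patch_id int 1")
    lines.append("LOOKUP_TABLE default")
    lines.extend(str(int(x)) for x in mesh.patch_of_triangle)
    for name, arr in (cell_data or {}).items():
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        lines.extend(f"{float(x):.9g}" for x in arr)
    Path(path).write_text("\n".join(lines) + "\n")


def read_vtk_polydata(path: str | Path) -> tuple[np.ndarray, np.ndarray, dict[str, np.ndarray]]:
    """Read back a polydata file written by this package.

    Returns (points, faces, cell/point data).  Faces is empty for clouds.
    """
    lines = Path(path).read_text().split("\n")
    pts: np.ndarray | None = None
    faces = np.zeros((0, 3), np.int64)
    data: dict[str, np.ndarray] = {}
    i = 0
    ndata = 0
    while i < len(lines):
        parts = lines[i].split()
        i += 1
        if not parts:
            continue
        key = parts[0].upper()
        if key == "POINTS":
            n = int(parts[1])
            vals = []
            while len(vals) < 3 * n:
                vals.extend(float(x) for x in lines[i].split())
                i += 1
            pts = np.array(vals).reshape(n, 3)
        elif key == "POLYGONS":
            n = int(parts[1])
            rows = []
            for _ in range(n):
                nums = lines[i].split()
                rows.append([int(x) for x in nums[1:]])
                i += 1
            faces = np.array(rows, np.int64)
        elif key in ("CELL_DATA", "POINT_DATA"):
            ndata = int(parts[1])
        elif key == "SCALARS":
            name = parts[1]
            i += 1  # LOOKUP_TABLE
            vals = []
            while len(vals) < ndata:
                vals.extend(float(x) for x in lines[i].split())
                i += 1
            data[name] = np.array(vals)
    if pts is None:
        raise NasopulseError(f"{path} is not a polydata VTK file")
    return pts, faces, data


def write_vtk_point_cloud(
    points: np.ndarray, path: str | Path, point_data: dict[str, np.ndarray] | None = None
) -> None:
    """Point cloud (e.g. deposited parcels) with scalar point data."""
    n = len(points)
    lines = [
        "# vtk DataFile Version 3.0",
        "nasopulse parcel cloud",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {n} double",
    ]
    lines.extend(f"{p[0]:.12g} {p[1]:.12g} {p[2]:.12g}" for p in points)
    lines.append(f"VERTICES {n} {2 * n}")
    lines.extend(f"1 {i}" for i in range(n))
    if point_data:
        lines.append(f"POINT_DATA {n}")
        for name, arr in point_data.items():
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            lines.extend(f"{float(x):.9g}" for x in arr)
    Path(path).write_text("\n".join(lines) + "\n")
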