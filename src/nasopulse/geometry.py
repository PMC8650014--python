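"""Synthetic airway geometries and their voxelized flow grids.

The patient airway is replaced by parameterized surrogates built from a single
swept-tube primitive: a circular (optionally corrugated) cross-section swept
along a planar centerline with a twist-free frame.  Three generators are
provided:

* :func:`build_duct` - straight circular duct (integrator / profile checks),
* :func:`build_bend` - bend with straight extensions (the classical
  deposition-efficiency benchmark geometry),
* :func:`build_nasal_surrogate` - two nasal channels joined by a 180-degree
  U-bend behind the closed soft palate, with a nasal-valve constriction,
  45-degree nosepieces, corrugated (turbinate-like) channel walls and labelled
  dorsal olfactory patches.

All meshes are watertight triangulations with a named patch per triangle.
:func:`voxelize` fills a mesh with an axis-aligned voxel grid (ray-parity
inside test) and returns a :class:`FlowGrid` that carries the Eulerian fields.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import cached_property
from typing import Callable

import numpy as np
from scipy import ndimage

from .config import GeometryError, ParameterError, ResolutionError, log

__all__ = [
    "PatchInfo",
    "SurfaceMesh",
    "DuctChart",
    "FlowGrid",
    "NasalSurrogateParams",
    "build_duct",
    "build_bend",
    "build_nasal_surrogate",
    "voxelize",
]


# ---------------------------------------------------------------------------
# Surface mesh
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PatchInfo:
    """Role (inlet/outlet/wall) and anatomical region tag of a patch."""

    role: str
    region: str


@dataclass
class SurfaceMesh:
    """Watertight triangulated boundary with named patches.

    ``patch_of_triangle`` holds, per triangle, an index into ``patch_names``;
    ``patch_table`` maps each name to its :class:`PatchInfo`.  For swept
    geometries ``tri_s`` / ``tri_theta`` record the centerline arclength and
    azimuth each wall triangle was generated at (NaN for cap triangles), and
    ``chart`` retains the sweep description for flow-field construction.
    """

    vertices: np.ndarray  # (n, 3) float64, metres
    faces: np.ndarray  # (m, 3) int64
    patch_of_triangle: np.ndarray  # (m,) int64
    patch_names: list[str]
    patch_table: dict[str, PatchInfo]
    tri_s: np.ndarray | None = None
    tri_theta: np.ndarray | None = None
    chart: "DuctChart | None" = None

    # -- derived quantities -------------------------------------------------

    def triangle_areas(self) -> np.ndarray:
        v = self.vertices
        a, b, c = (v[self.faces[:, i]] for i in range(3))
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    @property
    def total_area(self) -> float:
        return float(self.triangle_areas().sum())

    def patch_areas(self) -> dict[str, float]:
        areas = self.triangle_areas()
        out: dict[str, float] = {}
        for idx, name in enumerate(self.patch_names):
            out[name] = float(areas[self.patch_of_triangle == idx].sum())
        return out

    def enclosed_volume(self) -> float:
        """Volume enclosed by the watertight surface (divergence theorem)."""
        v = self.vertices
        a, b, c = (v[self.faces[:, i]] for i in range(3))
        return abs(float(np.einsum("ij,ij->i", a, np.cross(b, c)).sum())) / 6.0

    def patch_id(self, name: str) -> int:
        return self.patch_names.index(name)

    def patches_with_role(self, role: str) -> list[str]:
        return [n for n, info in self.patch_table.items() if info.role == role]

    @property
    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        return self.vertices.min(axis=0), self.vertices.max(axis=0)

    # -- validation ---------------------------------------------------------

    def is_watertight(self) -> bool:
        """True iff every edge is shared by exactly two triangles."""
        e = np.concatenate(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        e.sort(axis=1)
        _, counts = np.unique(e, axis=0, return_counts=True)
        return bool(np.all(counts == 2))

    def validate(self) -> None:
        """Raise :class:`GeometryError` on structural defects."""
        areas = self.triangle_areas()
        if np.any(areas <= 0.0):
            raise GeometryError("mesh contains degenerate (zero-area) triangles")
        pa = self.patch_areas()
        if any(a <= 0.0 for a in pa.values()):
            empty = [n for n, a in pa.items() if a <= 0.0]
            raise GeometryError(f"empty patches: {empty}")
        if abs(sum(pa.values()) - self.total_area) > 1e-12 * self.total_area:
            raise GeometryError("patch areas do not sum to total area")
        if not self.is_watertight():
            raise GeometryError("mesh is not watertight")

    def region_of_patch(self, name: str) -> str:
        return self.patch_table[name].region


# ---------------------------------------------------------------------------
# Sweep chart (centerline + cross-section description)
# ---------------------------------------------------------------------------


@dataclass
class DuctChart:
    """Discrete description of a swept tube.

    The centerline is sampled at rings ``i = 0..ns-1``; ``frames`` are
    twist-free (the binormal is the constant out-of-plane unit vector for the
    planar centerlines used here).  The wall radius at ring ``i`` and azimuth
    ``theta`` is ``r0[i] * (1 + amp[i] * cos(nlobes * theta))``.
    """

    s: np.ndarray  # (ns,) arclength [m]
    points: np.ndarray  # (ns, 3)
    tangents: np.ndarray  # (ns, 3)
    normals: np.ndarray  # (ns, 3)
    binormals: np.ndarray  # (ns, 3)
    r0: np.ndarray  # (ns,) base radius [m]
    amp: np.ndarray  # (ns,) corrugation amplitude (dimensionless)
    nlobes: int
    region_of_interval: list[str]  # (ns-1,) wall region label per ring interval

    @property
    def length(self) -> float:
        return float(self.s[-1])

    @cached_property
    def curvature(self) -> np.ndarray:
        """Signed centerline curvature dT/ds . N per sample (1/m)."""
        dT = np.gradient(self.tangents, self.s, axis=0)
        return np.einsum("ij,ij->i", dT, self.normals)

    def wall_radius(self, i: np.ndarray, theta: np.ndarray) -> np.ndarray:
        return self.r0[i] * (1.0 + self.amp[i] * np.cos(self.nlobes * theta))

    def section_area(self, s: np.ndarray) -> np.ndarray:
        """Cross-section area A(s) = pi r0^2 (1 + a^2/2)."""
        r0 = np.interp(s, self.s, self.r0)
        a = np.interp(s, self.s, self.amp)
        return math.pi * r0**2 * (1.0 + 0.5 * a**2)

    def min_radius(self) -> float:
        return float((self.r0 * (1.0 - np.abs(self.amp))).min())

    def interp(self, s: np.ndarray, arr: np.ndarray) -> np.ndarray:
        """Linear interpolation of a per-ring array (scalar or vector)."""
        if arr.ndim == 1:
            return np.interp(s, self.s, arr)
        return np.stack([np.interp(s, self.s, arr[:, k]) for k in range(arr.shape[1])], axis=-1)


def _sweep_centerline(
    start: np.ndarray, psi0: float, segments: list[tuple], ds: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Robust re-implementation of the centerline walk (exact arc points)."""
    pts = [np.asarray(start, float)]
    psi_list = [psi0]
    s_list = [0.0]
    seg_of = []
    pos = np.asarray(start, float).copy()
    psi = psi0
    s_acc = 0.0

    def tangent(p: float) -> np.ndarray:
        return np.array([math.sin(p), 0.0, math.cos(p)])

    for si, seg in enumerate(segments):
        if seg[0] == "straight":
            length = seg[1]
            if length <= 0:
                raise ParameterError("segment length must be positive")
            n = max(2, int(round(length / ds)) + 1)
            t = tangent(psi)
            for a in np.linspace(0.0, 1.0, n)[1:]:
                pts.append(pos + a * length * t)
                psi_list.append(psi)
                s_list.append(s_acc + a * length)
                seg_of.append(si)
            pos = pos + length * t
            s_acc += length
        else:
            radius, dpsi = seg[1], seg[2]
            if radius <= 0 or dpsi == 0:
                raise ParameterError("arc radius must be positive and turn nonzero")
            side = math.copysign(1.0, dpsi)
            t = tangent(psi)
            inward = np.array([t[2], 0.0, -t[0]]) * side
            center = pos + radius * inward
            arc_len = abs(dpsi) * radius
            n = max(3, int(round(arc_len / ds)) + 1)
            for a in np.linspace(0.0, 1.0, n)[1:]:
                p = psi + a * dpsi
                tp = tangent(p)
                inw = np.array([tp[2], 0.0, -tp[0]]) * side
                pts.append(center - radius * inw)
                psi_list.append(p)
                s_list.append(s_acc + a * arc_len)
                seg_of.append(si)
            pos = pts[-1].copy()
            psi += dpsi
            s_acc += arc_len

    points = np.array(pts)
    psis = np.array(psi_list)
    tangents = np.stack([np.sin(psis), np.zeros_like(psis), np.cos(psis)], axis=1)
    # exact analytic arclength (chord accumulation would bias arcs short)
    s = np.array(s_list)
    return s, points, tangents, np.array(seg_of)


def _sweep_mesh(chart: DuctChart, n_theta: int, inlet_region: str = "inlet", outlet_region: str = "outlet") -> SurfaceMesh:
    """Triangulate a chart into a watertight tube with end caps.

    Wall triangles inherit the region label of their ring interval; the caps
    become the ``inlet`` and ``outlet`` patches.
    """
    ns = len(chart.s)
    theta = 2.0 * math.pi * np.arange(n_theta) / n_theta
    cos_t, sin_t = np.cos(theta), np.sin(theta)

    # ring vertices: (ns, n_theta, 3)
    r = chart.r0[:, None] * (1.0 + chart.amp[:, None] * np.cos(chart.nlobes * theta)[None, :])
    ring = (
        chart.points[:, None, :]
        + r[:, :, None] * (cos_t[None, :, None] * chart.normals[:, None, :]
                           + sin_t[None, :, None] * chart.binormals[:, None, :])
    )
    verts = ring.reshape(-1, 3)
    # cap centers
    c_in = len(verts)
    c_out = len(verts) + 1
    verts = np.vstack([verts, chart.points[0], chart.points[-1]])

    def vid(i: int | np.ndarray, j: np.ndarray) -> np.ndarray:
        return i * n_theta + (j % n_theta)

    faces = []
    tri_s = []
    tri_theta = []
    regions = []
    j = np.arange(n_theta)
    for i in range(ns - 1):
        a = vid(i, j)
        b = vid(i, j + 1)
        c = vid(i + 1, j)
        d = vid(i + 1, j + 1)
        faces.append(np.stack([a, b, d], axis=1))
        faces.append(np.stack([a, d, c], axis=1))
        smid = 0.5 * (chart.s[i] + chart.s[i + 1])
        tmid = theta[j] + math.pi / n_theta
        tri_s.append(np.full(n_theta, smid))
        tri_s.append(np.full(n_theta, smid))
        tri_theta.append(tmid)
        tri_theta.append(tmid)
        regions.extend([chart.region_of_interval[i]] * (2 * n_theta))

    # caps (fans); winding chosen so cap normals point outward-ish (not relied on)
    a = vid(0, j)
    b = vid(0, j + 1)
    faces.append(np.stack([np.full(n_theta, c_in), b, a], axis=1))
    tri_s.append(np.full(n_theta, chart.s[0]))
    tri_theta.append(theta[j])
    regions.extend([inlet_region] * n_theta)
    a = vid(ns - 1, j)
    b = vid(ns - 1, j + 1)
    faces.append(np.stack([np.full(n_theta, c_out), a, b], axis=1))
    tri_s.append(np.full(n_theta, chart.s[-1]))
    tri_theta.append(theta[j])
    regions.extend([outlet_region] * n_theta)

    faces_arr = np.concatenate(faces).astype(np.int64)
    tri_s_arr = np.concatenate(tri_s)
    tri_theta_arr = np.concatenate(tri_theta)
    # cap tri_s/theta are not meaningful; mark NaN theta for caps
    ncap = 2 * n_theta
    tri_theta_arr[-ncap:] = np.nan

    # patch bookkeeping
    patch_names: list[str] = []
    patch_table: dict[str, PatchInfo] = {}
    ids = np.empty(len(regions), dtype=np.int64)
    for k, name in enumerate(regions):
        if name not in patch_table:
            role = "inlet" if name == inlet_region else "outlet" if name == outlet_region else "wall"
            patch_table[name] = PatchInfo(role=role, region=name)
            patch_names.append(name)
        ids[k] = patch_names.index(name)

    mesh = SurfaceMesh(
        vertices=verts,
        faces=faces_arr,
        patch_of_triangle=ids,
        patch_names=patch_names,
        patch_table=patch_table,
        tri_s=tri_s_arr,
        tri_theta=tri_theta_arr,
        chart=chart,
    )
    return mesh


def _straight_chart(
    radius: float,
    length: float,
    ds: float,
    region: str = "wall",
    origin: np.ndarray | None = None,
) -> DuctChart:
    n = max(2, int(round(length / ds)) + 1)
    s = np.linspace(0.0, length, n)
    origin = np.zeros(3) if origin is None else np.asarray(origin, float)
    points = origin + np.outer(s, np.array([0.0, 0.0, 1.0]))
    tangents = np.tile([0.0, 0.0, 1.0], (n, 1))
    normals = np.tile([1.0, 0.0, 0.0], (n, 1))
    binormals = np.tile([0.0, 1.0, 0.0], (n, 1))
    return DuctChart(
        s=s,
        points=points,
        tangents=tangents,
        normals=normals,
        binormals=binormals,
        r0=np.full(n, radius),
        amp=np.zeros(n),
        nlobes=1,
        region_of_interval=[region] * (n - 1),
    )


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------


def build_duct(radius: float, length: float, resolution: int = 64) -> SurfaceMesh:
    """Straight circular duct along +z with ``inlet``/``outlet``/``wall`` patches.

    ``resolution`` is the number of circumferential segments (>= 8).
    """
    if radius <= 0 or length <= 0:
        raise ParameterError("duct radius and length must be positive")
    if resolution < 8:
        raise ParameterError("need at least 8 circumferential segments")
    ds = min(length / 4.0, 2.0 * math.pi * radius / resolution)
    chart = _straight_chart(radius, length, ds)
    mesh = _sweep_mesh(chart, n_theta=resolution)
    mesh.validate()
    return mesh


def build_bend(
    tube_radius: float,
    bend_radius: float,
    angle: float,
    resolution: int = 64,
    ext_length: float | None = None,
) -> SurfaceMesh:
    """Bend of given turn ``angle`` (rad) with straight inlet/outlet extensions.

    The curved part's centerline length is ``bend_radius * angle``.  Wall
    regions are ``inlet_ext``, ``bend`` and ``outlet_ext``.
    """
    if tube_radius <= 0 or bend_radius <= 0:
        raise ParameterError("radii must be positive")
    if bend_radius <= tube_radius:
        raise ParameterError("bend radius must exceed tube radius (self-intersection)")
    if not (0.0 < angle <= math.pi):
        raise ParameterError("bend angle must lie in (0, pi]")
    if resolution < 8:
        raise ParameterError("need at least 8 circumferential segments")
    ext = 4.0 * tube_radius if ext_length is None else ext_length
    ds = min(2.0 * math.pi * tube_radius / resolution, bend_radius * angle / 8.0, ext / 3.0)
    segments = [("straight", ext), ("arc", bend_radius, angle), ("straight", ext)]
    s, pts, tan, seg_of = _sweep_centerline(np.zeros(3), 0.0, segments, ds)
    n = len(s)
    normals = np.stack([tan[:, 2], np.zeros(n), -tan[:, 0]], axis=1)
    binormals = np.tile([0.0, 1.0, 0.0], (n, 1))
    region_names = {0: "inlet_ext", 1: "bend", 2: "outlet_ext"}
    regions = [region_names[int(seg_of[i])] for i in range(n - 1)]
    chart = DuctChart(
        s=s,
        points=pts,
        tangents=tan,
        normals=normals,
        binormals=binormals,
        r0=np.full(n, tube_radius),
        amp=np.zeros(n),
        nlobes=1,
        region_of_interval=regions,
    )
    mesh = _sweep_mesh(chart, n_theta=resolution)
    mesh.validate()
    return mesh


# -- nasal surrogate --------------------------------------------------------


@dataclass
class NasalSurrogateParams:
    """Shape parameters of the bi-directional nasal surrogate.

    Defaults are calibrated so that the labelled dorsal olfactory patches have
    the reference areas (right 330 mm^2, left 337 mm^2) and the total
    wall-to-olfactory area ratio is ~64.  The corrugated (lobed) channel
    cross-section stands in for the turbinate folds that give the real nasal
    cavity its large epithelial surface at a small hydraulic diameter.
    """

    channel_radius_m: float = 0.007
    channel_length_m: float = 0.11
    ubend_radius_m: float = 0.018
    nosepiece_radius_m: float = 0.0045
    nosepiece_length_m: float = 0.018
    nosepiece_angle_deg: float = 45.0
    transition_radius_m: float = 0.012
    valve_ratio: float = 0.5
    valve_length_m: float = 0.012
    corrugation_amplitude: float = 0.52
    corrugation_lobes: int = 12
    olfactory_area_right_mm2: float = 330.0
    olfactory_area_left_mm2: float = 337.0
    n_theta: int = 144
    ds_m: float = 0.0015

    def validate(self) -> None:
        if not (0.0 < self.valve_ratio < 1.0):
            raise ParameterError("valve constriction ratio must lie in (0, 1)")
        if self.ubend_radius_m <= self.channel_radius_m * (1.0 + self.corrugation_amplitude):
            raise ParameterError("U-bend radius must exceed maximum channel radius")
        if not (0.0 <= self.corrugation_amplitude < 0.9):
            raise ParameterError("corrugation amplitude must lie in [0, 0.9)")
        for name in ("channel_radius_m", "channel_length_m", "nosepiece_radius_m",
                     "nosepiece_length_m", "transition_radius_m", "valve_length_m"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.olfactory_area_right_mm2 <= 0 or self.olfactory_area_left_mm2 <= 0:
            raise ParameterError("olfactory target areas must be positive")


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def build_nasal_surrogate(
    params: NasalSurrogateParams | None = None, seed: int = 0
) -> SurfaceMesh:
    """Bi-directional nasal surrogate: inlet nosepiece -> right channel ->
    180-degree U-bend -> left channel -> outlet nosepiece.

    The construction is deterministic for fixed ``(params, seed)``; the seed
    is reserved for optional stochastic surface perturbations (none by
    default) and is recorded for provenance.
    """
    p = params or NasalSurrogateParams()
    p.validate()
    del seed  # deterministic construction; kept for interface stability

    alpha = math.radians(p.nosepiece_angle_deg)
    segments = [
        ("straight", p.nosepiece_length_m),
        ("arc", p.transition_radius_m, alpha),
        ("straight", p.channel_length_m),
        ("arc", p.ubend_radius_m, -math.pi),
        ("straight", p.channel_length_m),
        ("arc", p.transition_radius_m, alpha),
        ("straight", p.nosepiece_length_m),
    ]
    s, pts, tan, seg_of = _sweep_centerline(np.zeros(3), -alpha, segments, p.ds_m)
    n = len(s)
    normals = np.stack([tan[:, 2], np.zeros(n), -tan[:, 0]], axis=1)
    binormals = np.tile([0.0, 1.0, 0.0], (n, 1))

    # segment boundaries in arclength
    seg_len = [
        p.nosepiece_length_m,
        p.transition_radius_m * alpha,
        p.channel_length_m,
        p.ubend_radius_m * math.pi,
        p.channel_length_m,
        p.transition_radius_m * alpha,
        p.nosepiece_length_m,
    ]
    bounds = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = bounds[-1]

    # base radius profile: nosepiece radius blending into channel radius
    blend = 0.010  # m, smooth transition length
    r0 = np.full(n, p.nosepiece_radius_m)
    r0 += (p.channel_radius_m - p.nosepiece_radius_m) * _smoothstep((s - bounds[1]) / blend)
    r0 -= (p.channel_radius_m - p.nosepiece_radius_m) * _smoothstep((s - (bounds[5] - blend)) / blend)

    # valve constrictions: short smooth dips after the right transition and
    # before the left transition
    def dip(center: float) -> np.ndarray:
        x = (s - center) / (0.5 * p.valve_length_m)
        return np.where(np.abs(x) < 1.0, np.cos(0.5 * math.pi * x) ** 2, 0.0)

    s_valve_r = bounds[2] + 0.012 + 0.5 * p.valve_length_m
    s_valve_l = total - (bounds[2] + 0.012 + 0.5 * p.valve_length_m)
    r0 = r0 * (1.0 - (1.0 - p.valve_ratio) * (dip(s_valve_r) + dip(s_valve_l)))

    # corrugation amplitude: zero through vestibule and valve, full in the
    # turbinate channels and the bend
    ramp = 0.012
    a_on = s_valve_r + 0.5 * p.valve_length_m + 0.002
    a_off = s_valve_l - 0.5 * p.valve_length_m - 0.002
    amp = p.corrugation_amplitude * _smoothstep((s - a_on) / ramp) * _smoothstep((a_off - s) / ramp)

    # region labelling per ring interval
    smid = 0.5 * (s[:-1] + s[1:])
    regions = []
    for sm in smid:
        if sm < a_on:
            regions.append("vestibule_R" if abs(sm - s_valve_r) > 0.75 * p.valve_length_m else "valve_R")
        elif sm < bounds[3]:
            regions.append("turbinate_R")
        elif sm < bounds[4]:
            regions.append("nasopharynx")
        elif sm < a_off:
            regions.append("turbinate_L")
        else:
            regions.append("vestibule_L" if abs(sm - s_valve_l) > 0.75 * p.valve_length_m else "valve_L")

    chart = DuctChart(
        s=s,
        points=pts,
        tangents=tan,
        normals=normals,
        binormals=binormals,
        r0=r0,
        amp=amp,
        nlobes=p.corrugation_lobes,
        region_of_interval=regions,
    )
    mesh = _sweep_mesh(chart, n_theta=p.n_theta)
    _carve_olfactory_patches(mesh, chart, p)
    mesh.validate()
    return mesh


def _carve_olfactory_patches(mesh: SurfaceMesh, chart: DuctChart, p: NasalSurrogateParams) -> None:
    """Relabel dorsal U-bend wall triangles as olfactory patches.

    At the U-bend the outward radial direction (azimuth theta = 0 in the sweep
    frame) points dorsally (+z at the apex).  Triangles on each half of the
    bend are accumulated outward from a dorsal seed point until the target
    patch area is reached, which pins the patch areas to the reference values
    up to a single-triangle granularity.
    """
    areas = mesh.triangle_areas()
    seg_len_before_bend = None
    # bend s-window = the nasopharynx region triangles
    naso_id = mesh.patch_id("nasopharynx")
    cand = np.where(mesh.patch_of_triangle == naso_id)[0]
    if len(cand) == 0:
        raise GeometryError("surrogate has no U-bend wall triangles")
    s_lo = mesh.tri_s[cand].min()
    s_hi = mesh.tri_s[cand].max()
    s_apex = 0.5 * (s_lo + s_hi)

    theta = np.mod(mesh.tri_theta[cand] + math.pi, 2.0 * math.pi) - math.pi  # wrap to (-pi, pi]

    for side, target_mm2 in (("R", p.olfactory_area_right_mm2), ("L", p.olfactory_area_left_mm2)):
        if side == "R":
            half = cand[(mesh.tri_s[cand] < s_apex)]
            th = theta[mesh.tri_s[cand] < s_apex]
            s_c = 0.5 * (s_lo + s_apex)
        else:
            half = cand[(mesh.tri_s[cand] >= s_apex)]
            th = theta[mesh.tri_s[cand] >= s_apex]
            s_c = 0.5 * (s_apex + s_hi)
        # elliptical metric around the dorsal seed (theta = 0, s = s_c)
        r_ref = p.channel_radius_m * (1.0 + 0.5 * p.corrugation_amplitude)
        d2 = (th * r_ref) ** 2 + (2.2 * (mesh.tri_s[half] - s_c)) ** 2
        order = half[np.argsort(d2)]
        target = target_mm2 * 1e-6
        csum = np.cumsum(areas[order])
        if csum[-1] < target:
            raise ParameterError(
                f"olfactory target area {target_mm2} mm^2 exceeds available dorsal "
                f"bend wall area {csum[-1] * 1e6:.1f} mm^2"
            )
        k = int(np.searchsorted(csum, target)) + 1
        chosen = order[:k]
        name = f"olfactory_{side}"
        mesh.patch_names.append(name)
        mesh.patch_table[name] = PatchInfo(role="wall", region=name)
        mesh.patch_of_triangle[chosen] = len(mesh.patch_names) - 1
    del seg_len_before_bend


# ---------------------------------------------------------------------------
# Flow grid
# ---------------------------------------------------------------------------


@dataclass
class FlowGrid:
    """Axis-aligned isotropic voxel grid over the fluid domain.

    Fields are stored cell-centered as (nx, ny, nz[, 3]) arrays.  The implicit
    LES filter width is the cell size: ``delta_tilde = V_cell**(1/3) = dx``.
    ``s_cell``/``theta_cell``/``eta_cell`` chart coordinates (arclength,
    azimuth, normalized radius) are filled for swept geometries and are NaN
    outside the fluid.
    """

    origin: np.ndarray  # (3,) corner of cell (0,0,0)
    dx: float
    inside: np.ndarray  # (nx, ny, nz) bool
    velocity: np.ndarray  # (nx, ny, nz, 3) [m/s]
    k_sgs: np.ndarray  # (nx, ny, nz) [m^2/s^2]
    scalar_c: np.ndarray  # (nx, ny, nz) dimensionless
    source: np.ndarray  # (nx, ny, nz, 3) [kg m^-2 s^-2]
    chart: DuctChart | None = None
    s_cell: np.ndarray | None = None
    theta_cell: np.ndarray | None = None
    eta_cell: np.ndarray | None = None
    inlet_mask: np.ndarray | None = None

    @classmethod
    def empty(cls, origin: np.ndarray, dx: float, shape: tuple[int, int, int]) -> "FlowGrid":
        return cls(
            origin=np.asarray(origin, float),
            dx=float(dx),
            inside=np.zeros(shape, bool),
            velocity=np.zeros(shape + (3,)),
            k_sgs=np.zeros(shape),
            scalar_c=np.zeros(shape),
            source=np.zeros(shape + (3,)),
        )

    # -- basic metrics ------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.inside.shape

    @property
    def cell_volume(self) -> float:
        return self.dx**3

    @property
    def delta_tilde(self) -> float:
        return self.cell_volume ** (1.0 / 3.0)

    @property
    def n_inside(self) -> int:
        return int(self.inside.sum())

    @property
    def inside_volume(self) -> float:
        return self.n_inside * self.cell_volume

    def cell_centers_axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        nx, ny, nz = self.shape
        return tuple(
            self.origin[d] + (np.arange(n) + 0.5) * self.dx
            for d, n in zip(range(3), (nx, ny, nz))
        )

    def cell_centers(self) -> np.ndarray:
        """(nx, ny, nz, 3) array of cell-center coordinates."""
        ax = self.cell_centers_axes()
        return np.stack(np.meshgrid(*ax, indexing="ij"), axis=-1)

    @property
    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        hi = self.origin + np.array(self.shape) * self.dx
        return self.origin.copy(), hi

    # -- flat inside-cell indexing (for scalar/kSGS updates) ----------------

    @cached_property
    def inside_flat(self) -> np.ndarray:
        """Flat (raveled) indices of inside cells."""
        return np.flatnonzero(self.inside.ravel())

    @cached_property
    def neighbor_flat(self) -> np.ndarray:
        """(6, n_in) flat indices of the -x,+x,-y,+y,-z,+z neighbors of each
        inside cell; a neighbor outside the fluid is replaced by the cell
        itself (zero-flux wall closure)."""
        nx, ny, nz = self.shape
        idx = np.argwhere(self.inside)
        flat_of = -np.ones(self.shape, dtype=np.int64)
        flat_of[self.inside] = np.ravel_multi_index(idx.T, self.shape)
        self_flat = flat_of[self.inside]
        out = np.empty((6, len(idx)), dtype=np.int64)
        shifts = [(-1, 0, 0), (1, 0, 0), (0, -1, 0), (0, 1, 0), (0, 0, -1), (0, 0, 1)]
        for a, (di, dj, dk) in enumerate(shifts):
            ni = idx + np.array([di, dj, dk])
            ok = (
                (ni[:, 0] >= 0) & (ni[:, 0] < nx)
                & (ni[:, 1] >= 0) & (ni[:, 1] < ny)
                & (ni[:, 2] >= 0) & (ni[:, 2] < nz)
            )
            nf = self_flat.copy()
            sel = np.where(ok)[0]
            cand = flat_of[ni[sel, 0], ni[sel, 1], ni[sel, 2]]
            good = cand >= 0
            nf[sel[good]] = cand[good]
            out[a] = nf
        return out

    def invalidate_caches(self) -> None:
        for name in ("inside_flat", "neighbor_flat"):
            self.__dict__.pop(name, None)


# ---------------------------------------------------------------------------
# Voxelization
# ---------------------------------------------------------------------------


def voxelize(
    mesh: SurfaceMesh,
    dx: float,
    margin_cells: int = 2,
    origin_shift: np.ndarray | None = None,
) -> FlowGrid:
    """Fill a watertight mesh with an isotropic voxel grid.

    Inside/outside is decided per cell center by ray parity along +x with a
    slightly tilted ray (resolves rays through triangle edges).  The grid box
    is the mesh bounding box padded by ``margin_cells`` cells, so no inside
    cell can touch the box boundary.  ``origin_shift`` (fractions of dx,
    each in [-1, 0]) offsets the lattice against the mesh - useful to break
    mesh/lattice alignment in convergence studies.
    """
    if dx <= 0:
        raise ParameterError("dx must be positive")
    if mesh.chart is not None and dx > mesh.chart.min_radius() / 4.0:
        raise ResolutionError(
            f"dx = {dx} too coarse: must be below min channel radius / 4 = "
            f"{mesh.chart.min_radius() / 4.0:.2e} m"
        )
    lo, hi = mesh.bounds
    origin = lo - margin_cells * dx
    if origin_shift is not None:
        origin = origin + np.asarray(origin_shift, float) * dx
    shape = tuple(int(math.ceil((hi[d] - origin[d]) / dx)) + margin_cells for d in range(3))
    grid = FlowGrid.empty(origin, dx, shape)

    inside = _ray_parity_fill(mesh, grid)
    if not inside.any():
        raise ResolutionError("no inside cells found; dx too coarse for this geometry")

    # connectivity: keep the single dominant component, drop tiny speckles
    lab, nlab = ndimage.label(inside)
    if nlab > 1:
        counts = np.bincount(lab.ravel())[1:]
        main = int(np.argmax(counts)) + 1
        frac_dropped = 1.0 - counts[main - 1] / counts.sum()
        if frac_dropped > 0.01:
            raise ResolutionError(
                f"inside cells split into {nlab} components ({frac_dropped:.1%} outside "
                "the main one); refine dx"
            )
        if frac_dropped > 0:
            log.debug("voxelize: dropped %.3f%% speckle cells", 100 * frac_dropped)
        inside = lab == main
    grid.inside = inside
    grid.chart = mesh.chart
    if mesh.chart is not None:
        _assign_chart_coordinates(grid, mesh.chart)
    return grid


def _ray_parity_fill(mesh: SurfaceMesh, grid: FlowGrid) -> np.ndarray:
    """Ray-parity inside test for all cell centers, vectorized per x-row."""
    nx, ny, nz = grid.shape
    xs, ys, zs = grid.cell_centers_axes()
    v = mesh.vertices
    tri = v[mesh.faces]  # (m, 3, 3)

    # small irrational tilt of the ray direction breaks edge/vertex ties
    d = np.array([1.0, 1.3e-7, 2.9e-7])
    d /= np.linalg.norm(d)

    # bin triangles by their (y, z) bbox against row coordinates
    tmin = tri.min(axis=1)
    tmax = tri.max(axis=1)
    pad = grid.dx  # generous: the tilted ray wanders < dx over the box length
    jlo = np.clip(np.searchsorted(ys, tmin[:, 1] - pad), 0, ny)
    jhi = np.clip(np.searchsorted(ys, tmax[:, 1] + pad), 0, ny)
    klo = np.clip(np.searchsorted(zs, tmin[:, 2] - pad), 0, nz)
    khi = np.clip(np.searchsorted(zs, tmax[:, 2] + pad), 0, nz)

    # build (row, triangle) candidate pairs, vectorized over ragged ranges
    njr = np.maximum(jhi - jlo, 0)
    nkr = np.maximum(khi - klo, 0)
    counts = njr * nkr
    total = int(counts.sum())
    if total == 0:
        return np.zeros(grid.shape, bool)
    tris_all = np.repeat(np.arange(len(tri)), counts)
    starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
    offs = np.arange(total) - starts[tris_all]
    jj = jlo[tris_all] + offs // np.maximum(nkr[tris_all], 1)
    kk = klo[tris_all] + offs % np.maximum(nkr[tris_all], 1)
    rows_all = jj * nz + kk

    # ray origins: far left of the box at each row's (y, z)
    x0 = grid.origin[0] - 1.0
    oy = ys[rows_all // nz]
    oz = zs[rows_all % nz]
    orig = np.stack([np.full(len(rows_all), x0), oy, oz], axis=1)

    # Moeller-Trumbore for each (row, tri) pair
    a = tri[tris_all, 0]
    e1 = tri[tris_all, 1] - a
    e2 = tri[tris_all, 2] - a
    pvec = np.cross(d[None, :], e2)
    det = np.einsum("ij,ij->i", e1, pvec)
    ok = np.abs(det) > 1e-300
    inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
    tvec = orig - a
    u = np.einsum("ij,ij->i", tvec, pvec) * inv
    qvec = np.cross(tvec, e1)
    vpar = np.einsum("ij->i", qvec * d[None, :]) * inv
    thit = np.einsum("ij,ij->i", e2, qvec) * inv
    hit = ok & (u >= 0.0) & (vpar >= 0.0) & (u + vpar <= 1.0) & (thit > 0.0)

    rows_hit = rows_all[hit]
    # x-coordinate of each hit along the (almost axis-aligned) ray
    xhit = x0 + thit[hit] * d[0]

    inside = np.zeros((nx, ny * nz), dtype=bool)
    if len(rows_hit):
        order = np.argsort(rows_hit, kind="stable")
        rows_sorted = rows_hit[order]
        x_sorted = xhit[order]
        starts = np.searchsorted(rows_sorted, np.arange(ny * nz))
        ends = np.searchsorted(rows_sorted, np.arange(ny * nz), side="right")
        for row in np.unique(rows_sorted):
            xsr = np.sort(x_sorted[starts[row]:ends[row]])
            # parity: cell center inside iff an odd number of crossings lie left of it
            cnt = np.searchsorted(xsr, xs)
            inside[:, row] = (cnt % 2) == 1
    return inside.reshape(nx, ny, nz)


def _assign_chart_coordinates(grid: FlowGrid, chart: DuctChart) -> None:
    """Compute (s, theta, eta) of every inside cell from the sweep chart."""
    from scipy.spatial import cKDTree

    centers = grid.cell_centers()[grid.inside]
    tree = cKDTree(chart.points)
    _, nearest = tree.query(centers, k=1)
    ns = len(chart.s)
    i0 = np.clip(nearest, 0, ns - 2)
    # refine: project onto the segment [i0, i0+1] (and [i0-1, i0] if behind)
    seg = chart.points[i0 + 1] - chart.points[i0]
    seg_len = np.linalg.norm(seg, axis=1)
    t = np.einsum("ij,ij->i", centers - chart.points[i0], seg) / np.maximum(seg_len**2, 1e-300)
    behind = (t < 0.0) & (i0 > 0)
    i0[behind] -= 1
    seg = chart.points[i0 + 1] - chart.points[i0]
    seg_len = np.linalg.norm(seg, axis=1)
    t = np.einsum("ij,ij->i", centers - chart.points[i0], seg) / np.maximum(seg_len**2, 1e-300)
    t = np.clip(t, 0.0, 1.0)
    s_val = chart.s[i0] + t * seg_len

    P = chart.points[i0] + t[:, None] * seg
    N = chart.normals[i0] * (1 - t[:, None]) + chart.normals[i0 + 1] * t[:, None]
    N /= np.maximum(np.linalg.norm(N, axis=1, keepdims=True), 1e-300)
    B = chart.binormals[i0]
    dvec = centers - P
    xi_n = np.einsum("ij,ij->i", dvec, N)
    xi_b = np.einsum("ij,ij->i", dvec, B)
    rho = np.hypot(xi_n, xi_b)
    theta = np.arctan2(xi_b, xi_n)
    r0 = np.interp(s_val, chart.s, chart.r0)
    amp = np.interp(s_val, chart.s, chart.amp)
    r_wall = r0 * (1.0 + amp * np.cos(chart.nlobes * theta))
    eta = rho / np.maximum(r_wall, 1e-300)

    for name, vals in (("s_cell", s_val), ("theta_cell", theta), ("eta_cell", eta)):
        arr = np.full(grid.shape, np.nan)
        arr[grid.inside] = vals
        setattr(grid, name, arr)
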