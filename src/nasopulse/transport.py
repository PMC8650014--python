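"""Lagrangian parcel transport: drag/gravity kinematics, wall deposition,
injection, adaptive stepping and the two-way momentum-coupling source.

Each computational parcel represents ``weight`` identical physical particles
(parcel method).  Parcel kinematics follow

    dx/dt = u_p,      du_p/dt = (u_s - u_p) / tau_p + g,

with the slip-corrected relaxation time ``tau_p = tau_Stokes / f_d`` and the
Schiller-Naumann drag factor ``f_d(Re_p)``.  Within a sub-step the gas
velocity seen by the parcel is frozen at its start-of-step value, which makes
the ODE linear with constant coefficients; the update uses its exact
(analytic) solution, so the integrator is unconditionally stable and the time
step is limited only by how fast ``u_s`` changes along the trajectory
(Courant criterion).  Parcels stick to the wall on first contact; crossing
the inlet or outlet cap marks them escaped.
"""

from __future__ import annotations

import math
import time as _time
from dataclasses import dataclass, field

import numpy as np

from .config import (
    G_STANDARD,
    MU_AIR,
    NU_AIR,
    RHO_AIR,
    TWO_WAY_VOLUME_FRACTION_THRESHOLD,
    GeometryError,
    NasopulseError,
    ParameterError,
    log,
)
from .flow import Waveform, sample_velocity_many, waveform_factor
from .geometry import FlowGrid, SurfaceMesh

__all__ = [
    "UNBORN",
    "ACTIVE",
    "DEPOSITED",
    "ESCAPED",
    "ParcelEnsemble",
    "CouplingSource",
    "SimulationResult",
    "stokes_relaxation_time",
    "drag_factor",
    "particle_reynolds",
    "advance_kinematics",
    "advance_parcel",
    "detect_wall_hit",
    "WallCollider",
    "inject_parcels",
    "coupling_source",
    "adaptive_dt",
    "run_transport",
]

UNBORN, ACTIVE, DEPOSITED, ESCAPED = 0, 1, 2, 3

#: deposit-patch code for parcels that left the grid bounding box
ESCAPE_BBOX = -2


# ---------------------------------------------------------------------------
# Parcel ensemble (struct of arrays)
# ---------------------------------------------------------------------------


@dataclass
class ParcelEnsemble:
    """State of all parcels; one row per parcel."""

    x: np.ndarray  # (n, 3) position [m]
    u: np.ndarray  # (n, 3) velocity [m/s]
    d: np.ndarray  # (n,) diameter [m]
    rho: np.ndarray  # (n,) material density [kg/m^3]
    weight: np.ndarray  # (n,) physical particles per parcel
    birth_time: np.ndarray  # (n,) [s]
    status: np.ndarray  # (n,) int8
    deposit_patch: np.ndarray  # (n,) int64, -1 = none, ESCAPE_BBOX = left box
    deposit_time: np.ndarray  # (n,) [s], NaN = none

    def __post_init__(self) -> None:
        if np.any(self.d <= 0) or np.any(self.rho <= 0) or np.any(self.weight <= 0):
            raise ParameterError("parcel diameter, density and weight must be positive")

    @property
    def n(self) -> int:
        return len(self.d)

    @property
    def particle_mass(self) -> np.ndarray:
        """Mass of one physical particle per parcel [kg]."""
        return self.rho * (math.pi / 6.0) * self.d**3

    @property
    def mass(self) -> np.ndarray:
        """Physical mass represented by each parcel [kg]."""
        return self.weight * self.particle_mass

    @property
    def total_mass(self) -> float:
        return float(self.mass.sum())

    def mass_where(self, cond: np.ndarray) -> float:
        return float(self.mass[cond].sum())


# ---------------------------------------------------------------------------
# Drag closure
# ---------------------------------------------------------------------------


def stokes_relaxation_time(d_p: float | np.ndarray, rho_p: float | np.ndarray, mu: float = MU_AIR):
    """Stokes relaxation time tau = rho_p d_p^2 / (18 mu)."""
    d_p = np.asarray(d_p, float)
    rho_p = np.asarray(rho_p, float)
    if np.any(d_p <= 0) or np.any(rho_p <= 0) or mu <= 0:
        raise ParameterError("diameter, density and viscosity must be positive")
    return rho_p * d_p**2 / (18.0 * mu)


def drag_factor(re_p: float | np.ndarray) -> float | np.ndarray:
    """Schiller-Naumann drag factor f_d = C_D Re / 24.

    f_d = 1 for Re <= 1; 1 + 0.15 Re^0.678 for 1 < Re <= 1000;
    0.44 Re / 24 beyond (Newton regime).  Monotone non-decreasing, and
    tau_p = tau_Stokes / f_d reduces to the Stokes value at low Re.
    """
    re = np.asarray(re_p, float)
    if np.any(re < 0):
        raise ParameterError("particle Reynolds number must be non-negative")
    fd = np.ones_like(re)
    mid = (re > 1.0) & (re <= 1000.0)
    fd = np.where(mid, 1.0 + 0.15 * re**0.678, fd)
    high = re > 1000.0
    fd = np.where(high, 0.44 * re / 24.0, fd)
    return float(fd) if np.isscalar(re_p) else fd


def particle_reynolds(u_s: np.ndarray, u_p: np.ndarray, d_p, nu: float = NU_AIR):
    """Re_p = |u_s - u_p| d_p / nu."""
    if nu <= 0:
        raise ParameterError("kinematic viscosity must be positive")
    slip = np.linalg.norm(np.atleast_2d(u_s) - np.atleast_2d(u_p), axis=-1)
    re = slip * np.asarray(d_p, float) / nu
    return float(re[0]) if np.asarray(u_s).ndim == 1 else re


# ---------------------------------------------------------------------------
# Analytic sub-step integrator
# ---------------------------------------------------------------------------


def advance_kinematics(
    x: np.ndarray,
    u: np.ndarray,
    u_s: np.ndarray,
    tau: np.ndarray,
    g: np.ndarray,
    dt: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact solution of du/dt = (u_s - u)/tau + g over one sub-step.

    With constant coefficients the velocity relaxes exponentially to the
    drift value u* = u_s + tau g:

        u(dt) = u* + (u0 - u*) exp(-dt/tau)
        x(dt) = x0 + u* dt + tau (u0 - u*) (1 - exp(-dt/tau))

    Vectorized over parcels; tau broadcasts as (n,) or scalar.
    """
    tau = np.asarray(tau, float)
    tcol = tau[..., None] if tau.ndim else tau
    u_star = u_s + tcol * g
    e = np.exp(-dt / tau)
    ecol = e[..., None] if np.ndim(e) else e
    one_m_e = -np.expm1(-dt / tau)
    ocol = one_m_e[..., None] if np.ndim(one_m_e) else one_m_e
    du = u - u_star
    u_new = u_star + du * ecol
    x_new = x + u_star * dt + tcol * du * ocol
    return x_new, u_new


def advance_parcel(x, u, u_s, d_p, rho_p, g, dt, mu: float = MU_AIR, nu: float = NU_AIR):
    """Single-parcel convenience wrapper: evaluates tau_p = tau_St / f_d at the
    sub-step start and applies the analytic update."""
    x = np.asarray(x, float)
    u = np.asarray(u, float)
    u_s = np.asarray(u_s, float)
    re = particle_reynolds(u_s, u, d_p, nu)
    tau = stokes_relaxation_time(d_p, rho_p, mu) / drag_factor(re)
    xn, un = advance_kinematics(x[None], u[None], u_s[None], np.array([tau]), np.asarray(g, float), dt)
    return xn[0], un[0]


# ---------------------------------------------------------------------------
# Wall-hit detection
# ---------------------------------------------------------------------------


def _segment_triangle_hits(x0, x1, tri_a, tri_e1, tri_e2):
    """Moeller-Trumbore for segment/triangle pairs (rowwise).

    Returns (hit mask, fraction t in [0, 1])."""
    d = x1 - x0
    pvec = np.cross(d, tri_e2)
    det = np.einsum("ij,ij->i", tri_e1, pvec)
    ok = np.abs(det) > 1e-300
    inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
    tvec = x0 - tri_a
    u = np.einsum("ij,ij->i", tvec, pvec) * inv
    qvec = np.cross(tvec, tri_e1)
    v = np.einsum("ij,ij->i", d, qvec) * inv
    t = np.einsum("ij,ij->i", tri_e2, qvec) * inv
    eps = 1e-12
    hit = ok & (u >= -eps) & (v >= -eps) & (u + v <= 1.0 + eps) & (t >= 0.0) & (t <= 1.0)
    return hit, t


def detect_wall_hit(x0: np.ndarray, x1: np.ndarray, mesh: SurfaceMesh):
    """Earliest intersection of the segment x0 -> x1 with the mesh.

    Returns (patch name, hit point, fraction) or None.  Ties are broken by
    (fraction, triangle index) so results are deterministic.
    """
    x0 = np.asarray(x0, float)
    x1 = np.asarray(x1, float)
    tri = mesh.vertices[mesh.faces]
    m = len(tri)
    a = tri[:, 0]
    hit, t = _segment_triangle_hits(
        np.broadcast_to(x0, (m, 3)), np.broadcast_to(x1, (m, 3)), a, tri[:, 1] - a, tri[:, 2] - a
    )
    if not hit.any():
        return None
    idx = np.where(hit)[0]
    order = np.lexsort((idx, t[idx]))
    best = idx[order[0]]
    frac = t[best]
    point = x0 + frac * (x1 - x0)
    return mesh.patch_names[int(mesh.patch_of_triangle[best])], point, float(frac)


class WallCollider:
    """Voxel-binned segment/mesh intersection tests for the transport loop.

    Triangles are binned to the voxels their (tight) bounding box overlaps.
    A sub-step segment is tested against the triangles binned to the voxels
    its own bounding box covers - at Courant-limited step lengths that is at
    most a 2x2x2 voxel block, and any voxel containing a potential hit point
    is inside that block, so no crossing can be missed.
    """

    def __init__(self, mesh: SurfaceMesh, grid: FlowGrid):
        self.mesh = mesh
        self.grid = grid
        tri = mesh.vertices[mesh.faces]
        self.tri_a = tri[:, 0].copy()
        self.tri_e1 = tri[:, 1] - tri[:, 0]
        self.tri_e2 = tri[:, 2] - tri[:, 0]
        self.tri_patch = mesh.patch_of_triangle
        nx, ny, nz = grid.shape
        self._hi_clip = np.array([nx - 1, ny - 1, nz - 1])
        lo_idx = np.floor((tri.min(axis=1) - grid.origin) / grid.dx).astype(np.int64)
        hi_idx = np.floor((tri.max(axis=1) - grid.origin) / grid.dx).astype(np.int64)
        lo_idx = np.clip(lo_idx, 0, self._hi_clip)
        hi_idx = np.clip(hi_idx, 0, self._hi_clip)
        span = hi_idx - lo_idx + 1
        counts = span.prod(axis=1)
        total = int(counts.sum())
        tri_of = np.repeat(np.arange(len(tri)), counts)
        starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
        offs = np.arange(total) - starts[tri_of]
        sy = span[tri_of, 1]
        sz = span[tri_of, 2]
        di = offs // (sy * sz)
        dj = (offs // sz) % sy
        dk = offs % sz
        cell = (
            (lo_idx[tri_of, 0] + di) * (ny * nz)
            + (lo_idx[tri_of, 1] + dj) * nz
            + (lo_idx[tri_of, 2] + dk)
        )
        order = np.argsort(cell, kind="stable")
        self._tri_sorted = tri_of[order]
        self._cells_unique, first = np.unique(cell[order], return_index=True)
        self._first = first
        self._count = np.diff(np.append(first, total))
        self.near_wall = np.zeros(nx * ny * nz, bool)
        self.near_wall[self._cells_unique] = True

    def query(self, x0: np.ndarray, x1: np.ndarray):
        """Earliest wall hit per segment.

        Returns (hit mask, patch id, fraction) arrays of length len(x0)."""
        n = len(x0)
        patch = np.full(n, -1, np.int64)
        frac = np.full(n, np.nan)
        g = self.grid
        nx, ny, nz = g.shape
        lo_i = np.floor((np.minimum(x0, x1) - g.origin) / g.dx).astype(np.int64)
        hi_i = np.floor((np.maximum(x0, x1) - g.origin) / g.dx).astype(np.int64)
        lo_i = np.clip(lo_i, 0, self._hi_clip)
        hi_i = np.clip(hi_i, 0, self._hi_clip)

        # candidate voxels: the (at most 2^3) corners of the segment's box
        seg_ids = []
        tri_ids = []
        span = hi_i - lo_i  # 0 or 1 per axis for Courant-limited steps
        for dx_ in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    sel = (dx_ <= span[:, 0]) & (dy <= span[:, 1]) & (dz <= span[:, 2])
                    cells = (
                        np.minimum(lo_i[sel, 0] + dx_, nx - 1) * (ny * nz)
                        + np.minimum(lo_i[sel, 1] + dy, ny - 1) * nz
                        + np.minimum(lo_i[sel, 2] + dz, nz - 1)
                    )
                    rows = np.where(sel)[0]
                    keep = self.near_wall[cells]
                    if not keep.any():
                        continue
                    cells = cells[keep]
                    rows = rows[keep]
                    pos = np.searchsorted(self._cells_unique, cells)
                    cnt = self._count[pos]
                    total_c = int(cnt.sum())
                    if total_c == 0:
                        continue
                    seg_ids.append(np.repeat(rows, cnt))
                    offs = np.arange(total_c) - np.repeat(
                        np.concatenate([[0], np.cumsum(cnt)[:-1]]), cnt
                    )
                    tri_ids.append(self._tri_sorted[np.repeat(self._first[pos], cnt) + offs])
        if not seg_ids:
            return np.zeros(n, bool), patch, frac
        # duplicate (segment, triangle) pairs from adjacent voxels are
        # harmless: the earliest-hit reduction below picks one winner
        seg_all = np.concatenate(seg_ids)
        tri_all = np.concatenate(tri_ids)

        hit, t = _segment_triangle_hits(
            x0[seg_all], x1[seg_all], self.tri_a[tri_all], self.tri_e1[tri_all], self.tri_e2[tri_all]
        )
        if not hit.any():
            return np.zeros(n, bool), patch, frac
        s = seg_all[hit]
        tt = t[hit]
        tris = tri_all[hit]
        # earliest hit per segment, ties by triangle index
        order = np.lexsort((tris, tt, s))
        s, tt, tris = s[order], tt[order], tris[order]
        first_of = np.concatenate([[True], s[1:] != s[:-1]])
        s, tt, tris = s[first_of], tt[first_of], tris[first_of]
        out_hit = np.zeros(n, bool)
        out_hit[s] = True
        patch[s] = self.tri_patch[tris]
        frac[s] = tt
        return out_hit, patch, frac


# ---------------------------------------------------------------------------
# Injection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InjectionSpec:
    diameter: float  # [m]
    density: float = 1000.0  # [kg/m^3]
    n_parcels: int = 10_000
    mass_total: float = 2.5e-6  # [kg]
    duration: float = 0.5  # [s]


def inject_parcels(
    mesh: SurfaceMesh, spec: InjectionSpec, seed: int = 0, rng: np.random.Generator | None = None
) -> ParcelEnsemble:
    """Create the parcel stream: birth times uniform over the injection
    window, positions uniform over the inlet disc, weights set so the total
    physical mass matches ``mass_total`` exactly.

    Initial velocities are zero placeholders; the transport loop assigns the
    instantaneous local gas velocity when each parcel activates.
    """
    if spec.n_parcels < 1:
        raise ParameterError("need at least one parcel")
    if spec.duration <= 0:
        raise ParameterError("injection duration must be positive")
    chart = mesh.chart
    if chart is None:
        raise GeometryError("injection requires a swept geometry (chart present)")
    inlet_names = mesh.patches_with_role("inlet")
    if len(inlet_names) != 1:
        raise GeometryError(f"expected exactly one inlet patch, found {inlet_names}")
    areas = mesh.patch_areas()
    if areas[inlet_names[0]] <= 0:
        raise GeometryError("inlet patch has zero area")

    rng = np.random.default_rng(seed) if rng is None else rng
    n = spec.n_parcels
    birth = np.sort(rng.uniform(0.0, spec.duration, n))
    # uniform over the inlet disc (radius = chart radius at s = 0)
    r_in = chart.r0[0] * (1.0 + chart.amp[0])  # amp is zero at the nosepiece
    radii = r_in * np.sqrt(rng.uniform(0.0, 1.0, n))
    phi = rng.uniform(0.0, 2.0 * math.pi, n)
    P0, T0, N0, B0 = chart.points[0], chart.tangents[0], chart.normals[0], chart.binormals[0]
    offset = 1e-3 * r_in  # start marginally inside the cap plane
    x = (
        P0[None, :]
        + offset * T0[None, :]
        + radii[:, None] * (np.cos(phi)[:, None] * N0 + np.sin(phi)[:, None] * B0)
    )
    particle_mass = spec.density * math.pi / 6.0 * spec.diameter**3
    weight = np.full(n, spec.mass_total / (n * particle_mass))
    return ParcelEnsemble(
        x=x,
        u=np.zeros((n, 3)),
        d=np.full(n, spec.diameter),
        rho=np.full(n, spec.density),
        weight=weight,
        birth_time=birth,
        status=np.full(n, UNBORN, np.int8),
        deposit_patch=np.full(n, -1, np.int64),
        deposit_time=np.full(n, np.nan),
    )


# ---------------------------------------------------------------------------
# Two-way coupling source
# ---------------------------------------------------------------------------


@dataclass
class CouplingSource:
    """Per-cell momentum source and its global force accounting."""

    field: np.ndarray  # (nx, ny, nz, 3) [N/m^3]
    total_parcel_force: np.ndarray  # (3,) sum of omega_p * F_D,p [N]
    n_excluded: int  # parcels outside the grid box

    def newton_residual(self, cell_volume: float) -> float:
        """|sum_cells S V + sum_p omega F_D| / max(|sum_p omega F_D|, eps)."""
        tot = self.field.reshape(-1, 3).sum(axis=0) * cell_volume
        ref = float(np.linalg.norm(self.total_parcel_force))
        return float(np.linalg.norm(tot + self.total_parcel_force)) / max(ref, 1e-300)


def coupling_source(
    grid: FlowGrid,
    x: np.ndarray,
    u_p: np.ndarray,
    u_s: np.ndarray,
    tau: np.ndarray,
    particle_mass: np.ndarray,
    weight: np.ndarray,
    dt: float | None = None,
) -> CouplingSource:
    """Drag-reaction momentum source on the gas, Eq-15 style.

    Each parcel's drag force F_D = m_p (u_s - u_p)/tau_p (per physical
    particle, times the statistical weight) is distributed to the eight
    surrounding cell centers with trilinear kernel weights and divided by the
    cell volume, with opposite sign (Newton's third law):

        S_u[l] = -(1/V_l) sum_p G_l(x_p) omega_p F_D,p .

    ``dt`` is accepted for signature compatibility with time-integrated
    variants but does not enter the instantaneous force density.
    """
    del dt
    n = len(x)
    F = particle_mass[:, None] * (u_s - u_p) / tau[:, None]  # per physical particle
    Fw = weight[:, None] * F
    lo, hi = grid.bounds
    in_box = np.all((x >= lo) & (x <= hi), axis=1)
    n_excl = int(n - in_box.sum())
    if n_excl:
        log.warning("coupling_source: %d parcels outside grid box excluded", n_excl)
    xs = x[in_box]
    Fws = Fw[in_box]
    nx, ny, nz = grid.shape
    ncells = nx * ny * nz
    field = np.zeros((ncells, 3))
    if len(xs):
        f = (xs - grid.origin) / grid.dx - 0.5
        f = np.clip(f, 0.0, np.array([nx - 1, ny - 1, nz - 1], float) - 1e-12)
        i0 = np.maximum(np.minimum(f.astype(np.int64), np.array([nx - 2, ny - 2, nz - 2])), 0)
        w = f - i0
        inv_v = 1.0 / grid.cell_volume
        flats = []
        wts = []
        for dxi in (0, 1):
            wx = w[:, 0] if dxi else 1.0 - w[:, 0]
            for dy in (0, 1):
                wy = w[:, 1] if dy else 1.0 - w[:, 1]
                for dz in (0, 1):
                    wz = w[:, 2] if dz else 1.0 - w[:, 2]
                    flats.append(
                        (i0[:, 0] + dxi) * (ny * nz) + (i0[:, 1] + dy) * nz + (i0[:, 2] + dz)
                    )
                    wts.append(wx * wy * wz * inv_v)
        flat_all = np.concatenate(flats)
        wt_all = np.concatenate(wts)
        # scatter on the compressed set of touched cells only
        uniq, inv = np.unique(flat_all, return_inverse=True)
        for c in range(3):
            field[uniq, c] = -np.bincount(
                inv, weights=wt_all * np.tile(Fws[:, c], 8), minlength=len(uniq)
            )
    field = field.reshape(nx, ny, nz, 3)
    return CouplingSource(field=field, total_parcel_force=Fws.sum(axis=0), n_excluded=n_excl)


# ---------------------------------------------------------------------------
# Time stepping
# ---------------------------------------------------------------------------


def adaptive_dt(
    grid: FlowGrid,
    courant_max: float,
    tau_min: float | None = None,
    dt_max: float = 1e-2,
    velocity: np.ndarray | None = None,
) -> float:
    """Courant-limited time step dt = courant_max dx / max|u|.

    With ``tau_min`` given, additionally capped at tau_min/5 (a conservative
    bound for integrators that are not exact in tau; the analytic sub-step
    integrator used by :func:`run_transport` does not need it).  Zero velocity
    everywhere returns ``dt_max``.
    """
    if not (0.0 < courant_max <= 1.0):
        raise ParameterError("courant_max must lie in (0, 1]")
    vel = grid.velocity if velocity is None else velocity
    umax = float(np.linalg.norm(vel, axis=-1).max())
    dt = dt_max if umax == 0.0 else min(courant_max * grid.dx / umax, dt_max)
    if tau_min is not None:
        dt = min(dt, tau_min / 5.0)
    return dt


# ---------------------------------------------------------------------------
# Transport driver
# ---------------------------------------------------------------------------


@dataclass
class SimulationResult:
    """Outcome of a transport run, sufficient for all deposition metrics."""

    parcels: ParcelEnsemble
    patch_names: list[str]
    patch_table: dict
    injected_mass: float  # [kg]
    t_end: float
    n_steps: int
    dt_nominal: float
    seed: int
    waveform_mode: str
    Q_lpm: float
    diameter: float
    volume_fraction: float
    two_way_engaged: bool
    coupling_newton_residual: float | None = None
    coupling_max_source: float | None = None
    wall_clock_s: float = 0.0

    # -- mass bookkeeping ---------------------------------------------------

    @property
    def deposited_mass(self) -> float:
        p = self.parcels
        return p.mass_where((p.status == DEPOSITED))

    @property
    def escaped_mass(self) -> float:
        return self.parcels.mass_where(self.parcels.status == ESCAPED)

    @property
    def airborne_mass(self) -> float:
        p = self.parcels
        return p.mass_where((p.status == ACTIVE) | (p.status == UNBORN))

    def deposited_mass_by_patch(self) -> dict[str, float]:
        p = self.parcels
        out: dict[str, float] = {name: 0.0 for name in self.patch_names}
        dep = p.status == DEPOSITED
        masses = p.mass
        for pid in np.unique(p.deposit_patch[dep]):
            name = self.patch_names[int(pid)]
            out[name] = float(masses[dep & (p.deposit_patch == pid)].sum())
        return out


def run_transport(
    mesh: SurfaceMesh,
    grid: FlowGrid,
    waveform: Waveform,
    spec: InjectionSpec,
    t_end: float,
    courant_max: float = 0.9,
    seed: int = 0,
    gravity: np.ndarray | tuple = (0.0, 0.0, -G_STANDARD),
    two_way: bool = False,
    apply_feedback: bool = False,
    mu: float = MU_AIR,
    nu: float = NU_AIR,
    rho_gas: float = RHO_AIR,
    apply_tau_cap: bool = False,
    collider: WallCollider | None = None,
) -> SimulationResult:
    """Full parcel-transport loop on a prescribed (quasi-steady) base field.

    The grid's stored velocity is the base field for Q0; at each step it is
    scaled by the instantaneous waveform factor.  Parcels activate at their
    birth time with the instantaneous local gas velocity, advance with the
    analytic drag/gravity sub-step, stick to walls on first contact and
    escape through the inlet/outlet caps.  Two-way coupling computes the
    parcel drag-reaction source field each step (engaged when the injected
    particle volume fraction exceeds 1e-6); with ``apply_feedback`` the
    source additionally perturbs the gas velocity seen by the parcels by
    S dt / rho_gas (the momentum solve itself is out of scope here).
    """
    if t_end < spec.duration:
        raise ParameterError("t_end must cover the injection window")
    t_start = _time.time()
    g = np.asarray(gravity, float)
    base_vel = grid.velocity
    if spec.n_parcels == 0:
        # empty injection: a valid (trivially balanced) run
        parcels = ParcelEnsemble(
            x=np.zeros((0, 3)), u=np.zeros((0, 3)), d=np.zeros(0) + 1e-6,
            rho=np.zeros(0) + 1e3, weight=np.zeros(0) + 1.0,
            birth_time=np.zeros(0), status=np.zeros(0, np.int8),
            deposit_patch=np.zeros(0, np.int64), deposit_time=np.zeros(0),
        )
    else:
        parcels = inject_parcels(mesh, spec, seed=seed)
    coll = WallCollider(mesh, grid) if collider is None else collider

    # particle volume fraction (injected particle volume / fluid volume)
    vol_particles = float((parcels.weight * math.pi / 6.0 * parcels.d**3).sum())
    vol_fraction = vol_particles / max(grid.inside_volume, 1e-300)
    engage = two_way and vol_fraction > TWO_WAY_VOLUME_FRACTION_THRESHOLD
    if two_way and not engage:
        log.warning(
            "two-way coupling requested but volume fraction %.2e is below the "
            "threshold %.0e; proceeding one-way",
            vol_fraction,
            TWO_WAY_VOLUME_FRACTION_THRESHOLD,
        )

    # nominal step: Courant bound against the base field at mean flow; the
    # loop rescales it by the instantaneous waveform factor
    tau_st_min = float(stokes_relaxation_time(spec.diameter, spec.density, mu))
    dt = adaptive_dt(
        grid,
        courant_max,
        tau_min=tau_st_min if apply_tau_cap else None,
        velocity=base_vel,
    )

    tau_st = stokes_relaxation_time(parcels.d, parcels.rho, mu)
    newton_res = None
    max_source = None
    t = 0.0
    n_steps = 0
    status = parcels.status
    dt_wave_cap = math.inf if waveform.mode == "steady" else waveform.period / 40.0
    while t < t_end:
        lam = float(waveform_factor(waveform, t))
        if waveform.mode == "steady":
            dt_step = dt
        else:
            # Courant limit against the instantaneous (scaled) field, never
            # coarser than a fraction of the pulsation period
            dt_try = min(dt / max(lam, 0.2), dt_wave_cap)
            lam_ahead = float(waveform_factor(waveform, t + dt_try))
            dt_step = min(dt / max(lam, lam_ahead, 0.2), dt_wave_cap)
            lam = float(waveform_factor(waveform, t))
        dt_step = min(dt_step, t_end - t)

        # activate newborn parcels with the instantaneous local gas velocity
        newborn = (status == UNBORN) & (parcels.birth_time <= t + dt_step)
        if newborn.any():
            u0, _ = sample_velocity_many(grid, parcels.x[newborn], base_vel)
            parcels.u[newborn] = u0 * lam
            status[newborn] = ACTIVE

        act = status == ACTIVE
        if act.any():
            xa = parcels.x[act]
            ua = parcels.u[act]
            u_s, in_box = sample_velocity_many(grid, xa, base_vel)
            u_s = u_s * lam

            re = np.linalg.norm(u_s - ua, axis=1) * parcels.d[act] / nu
            tau = tau_st[act] / drag_factor(re)

            if engage:
                src = coupling_source(
                    grid, xa, ua, u_s, tau, parcels.particle_mass[act], parcels.weight[act]
                )
                newton_res = src.newton_residual(grid.cell_volume)
                max_source = float(np.abs(src.field).max())
                grid.source = src.field
                if apply_feedback:
                    du, _ = sample_velocity_many(grid, xa, src.field)
                    u_s = u_s + du * dt_step / rho_gas
                    re = np.linalg.norm(u_s - ua, axis=1) * parcels.d[act] / nu
                    tau = tau_st[act] / drag_factor(re)

            x1, u1 = advance_kinematics(xa, ua, u_s, tau, g, dt_step)
            if not (np.isfinite(x1).all() and np.isfinite(u1).all()):
                bad = ~(np.isfinite(x1).all(axis=1) & np.isfinite(u1).all(axis=1))
                raise NasopulseError(
                    f"NaN parcel state at t={t:.6g}: indices {np.where(act)[0][bad][:10]}, "
                    f"x={x1[bad][:3]}, u={u1[bad][:3]}"
                )

            hit, patch_id, frac = coll.query(xa, x1)
            act_idx = np.where(act)[0]
            if hit.any():
                h = np.where(hit)[0]
                roles = np.array(
                    [mesh.patch_table[mesh.patch_names[int(p)]].role for p in patch_id[h]]
                )
                hit_pts = xa[h] + frac[h][:, None] * (x1[h] - xa[h])
                for kind, new_status in (("wall", DEPOSITED), ("cap", ESCAPED)):
                    sel = roles == "wall" if kind == "wall" else roles != "wall"
                    rows = act_idx[h[sel]]
                    status[rows] = new_status
                    parcels.x[rows] = hit_pts[sel]
                    parcels.deposit_time[rows] = t + frac[h[sel]] * dt_step
                    parcels.deposit_patch[rows] = patch_id[h[sel]]

            survivors = ~hit
            rows = act_idx[survivors]
            parcels.x[rows] = x1[survivors]
            parcels.u[rows] = u1[survivors]
            # leaving the bounding box without a cap hit counts as escape
            lo, hi = grid.bounds
            out = ~np.all((x1[survivors] >= lo) & (x1[survivors] <= hi), axis=1)
            if out.any():
                gone = rows[out]
                status[gone] = ESCAPED
                parcels.deposit_patch[gone] = ESCAPE_BBOX
                parcels.deposit_time[gone] = t + dt_step
            del in_box

        t += dt_step
        n_steps += 1
        if not (status == ACTIVE).any() and not (status == UNBORN).any():
            break

    result = SimulationResult(
        parcels=parcels,
        patch_names=list(mesh.patch_names),
        patch_table=dict(mesh.patch_table),
        injected_mass=parcels.total_mass,
        t_end=t,
        n_steps=n_steps,
        dt_nominal=dt,
        seed=seed,
        waveform_mode=waveform.mode,
        Q_lpm=waveform.Q0 / (1e-3 / 60.0),
        diameter=spec.diameter,
        volume_fraction=vol_fraction,
        two_way_engaged=engage,
        coupling_newton_residual=newton_res,
        coupling_max_source=max_source,
        wall_clock_s=_time.time() - t_start,
    )
    log.info(
        "transport: %d parcels, %d steps, dt=%.3g s, deposited %.3g / escaped %.3g / "
        "airborne %.3g mg, %.1f s wall",
        parcels.n,
        n_steps,
        dt,
        result.deposited_mass * 1e6,
        result.escaped_mass * 1e6,
        result.airborne_mass * 1e6,
        result.wall_clock_s,
    )
    return result
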