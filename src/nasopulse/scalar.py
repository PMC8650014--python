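"""Passive-scalar ventilation: transport of the drug-laden air fraction C.

C is 0 in resident air and 1 in inhaled air; its transport

    dC/dt + div(u C) = div( (nu/Sc + nu_sgs/Sc_sgs) grad C )

is integrated explicitly with first-order upwind advection and conservative
central diffusion on the inside cells of the voxel grid (zero-flux walls,
C = 1 held on the inlet cells).  The scheme is monotone under its stability
bound, so C stays in [0, 1] and every region's volume-weighted mean is
non-decreasing in time.  Diffusivity is placed inside the divergence so the
update conserves scalar mass for spatially varying eddy viscosity; for
uniform diffusivity this reduces to the constant-coefficient Laplacian form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import NU_AIR, ParameterError, StabilityError
from .flow import sample_velocity_many
from .geometry import FlowGrid

__all__ = [
    "SCHMIDT_DEFAULT",
    "VentilationReport",
    "scalar_stable_dt",
    "advance_scalar",
    "region_mean_C",
    "iso_volume_fraction",
    "region_flow_fraction",
]

#: laminar and subgrid Schmidt numbers of an air-like tracer
SCHMIDT_DEFAULT = 0.7


def _total_diffusivity(grid: FlowGrid, Sc: float, Sc_sgs: float, nu: float, ck: float = 0.094):
    from .sgs import nu_sgs  # local import to avoid a cycle at module load

    nusgs = nu_sgs(grid.k_sgs, grid.delta_tilde, ck)
    return nu / Sc + nusgs / Sc_sgs


def scalar_stable_dt(
    grid: FlowGrid,
    velocity: np.ndarray | None = None,
    Sc: float = SCHMIDT_DEFAULT,
    Sc_sgs: float = SCHMIDT_DEFAULT,
    nu: float = NU_AIR,
    safety: float = 0.9,
    velocity_scale: float = 1.0,
) -> float:
    """Monotonicity-preserving explicit step for upwind + central diffusion."""
    vel = grid.velocity if velocity is None else velocity
    ins = grid.inside
    usum = abs(velocity_scale) * (np.abs(vel[ins]).sum(axis=1).max() if ins.any() else 0.0)
    D = _total_diffusivity(grid, Sc, Sc_sgs, nu)
    dmax = float(np.max(D[ins])) if ins.any() else float(np.max(D))
    rate = usum / grid.dx + 6.0 * dmax / grid.dx**2
    if rate <= 0:
        return np.inf
    return safety / rate


def advance_scalar(
    grid: FlowGrid,
    dt: float,
    Sc: float = SCHMIDT_DEFAULT,
    Sc_sgs: float = SCHMIDT_DEFAULT,
    nu: float = NU_AIR,
    velocity: np.ndarray | None = None,
    inlet_mask: np.ndarray | None = None,
    velocity_scale: float = 1.0,
    diffusivity: np.ndarray | None = None,
    check_stability: bool = True,
) -> np.ndarray:
    """One explicit step of the C equation; returns the updated field.

    ``velocity_scale`` multiplies the stored velocity (quasi-steady pulsation
    without copying the field).  Raises :class:`StabilityError` when ``dt``
    exceeds the monotone bound.  The inlet cells (``inlet_mask`` or
    ``grid.inlet_mask``) are held at C = 1 before and after the update
    (Dirichlet inflow of drug-laden air).  A precomputed total-diffusivity
    field and ``check_stability=False`` let a driver that already enforces
    the bound (against a static diffusivity) skip the per-step audit.
    """
    if dt <= 0:
        raise ParameterError("dt must be positive")
    if check_stability:
        bound = scalar_stable_dt(grid, velocity, Sc, Sc_sgs, nu, safety=1.0, velocity_scale=velocity_scale)
        if dt > bound:
            raise StabilityError(f"dt={dt:.3e} exceeds the monotone bound {bound:.3e}")
    vel = grid.velocity if velocity is None else velocity
    inlet = grid.inlet_mask if inlet_mask is None else inlet_mask

    flat_c = grid.scalar_c.ravel()
    idx = grid.inside_flat
    nb = grid.neighbor_flat  # (6, n_in); wall neighbors point to self
    if inlet is not None:
        inl_flat = np.flatnonzero(inlet.ravel())
        flat_c[inl_flat] = 1.0

    c = flat_c[idx]
    D = (_total_diffusivity(grid, Sc, Sc_sgs, nu) if diffusivity is None else diffusivity).ravel()
    d_self = D[idx]
    u = vel.reshape(-1, 3)[idx] * velocity_scale
    dx = grid.dx

    dcdt = np.zeros_like(c)
    for ax in range(3):
        c_m = flat_c[nb[2 * ax]]
        c_p = flat_c[nb[2 * ax + 1]]
        ua = u[:, ax]
        dcdt -= np.where(ua > 0, ua * (c - c_m), ua * (c_p - c)) / dx
        d_m = 0.5 * (d_self + D[nb[2 * ax]])
        d_p = 0.5 * (d_self + D[nb[2 * ax + 1]])
        dcdt += (d_p * (c_p - c) - d_m * (c - c_m)) / dx**2

    # flat_c normally views grid.scalar_c: update in place after all gathers
    flat_c[idx] = np.clip(c + dt * dcdt, 0.0, 1.0)
    if inlet is not None:
        flat_c[inl_flat] = 1.0
    grid.scalar_c = flat_c.reshape(grid.shape)  # no-op for the view case
    return grid.scalar_c


class ScalarIntegrator:
    """Precomputed repeated-step driver for :func:`advance_scalar`.

    Caches everything static across steps of a quasi-steady phase (inside
    indexing, neighbor gathers of the diffusivity, the base velocity at the
    inside cells, the inlet cell list) so the per-step work is only the six
    scalar gathers and the update arithmetic.  Produces the same update as
    ``advance_scalar`` with a fixed diffusivity field.
    """

    def __init__(
        self,
        grid: FlowGrid,
        Sc: float = SCHMIDT_DEFAULT,
        Sc_sgs: float = SCHMIDT_DEFAULT,
        nu: float = NU_AIR,
    ):
        self.grid = grid
        self.idx = grid.inside_flat
        self.nb = grid.neighbor_flat
        D = _total_diffusivity(grid, Sc, Sc_sgs, nu).ravel()
        d_self = D[self.idx]
        self.d_faces = [
            (0.5 * (d_self + D[self.nb[2 * ax]]), 0.5 * (d_self + D[self.nb[2 * ax + 1]]))
            for ax in range(3)
        ]
        self.u = grid.velocity.reshape(-1, 3)[self.idx]
        inlet = grid.inlet_mask
        self.inl_flat = None if inlet is None else np.flatnonzero(inlet.ravel())
        self.base_bound = scalar_stable_dt(grid, Sc=Sc, Sc_sgs=Sc_sgs, nu=nu)

    def step(self, dt: float, velocity_scale: float = 1.0) -> None:
        g = self.grid
        flat_c = g.scalar_c.ravel()  # view when contiguous; reshaped back below
        if self.inl_flat is not None:
            flat_c[self.inl_flat] = 1.0
        c = flat_c[self.idx]
        dx = g.dx
        dcdt = np.zeros_like(c)
        for ax in range(3):
            c_m = flat_c[self.nb[2 * ax]]
            c_p = flat_c[self.nb[2 * ax + 1]]
            ua = self.u[:, ax] * velocity_scale
            dcdt -= np.where(ua > 0, ua * (c - c_m), ua * (c_p - c)) / dx
            d_m, d_p = self.d_faces[ax]
            dcdt += (d_p * (c_p - c) - d_m * (c - c_m)) / dx**2
        flat_c[self.idx] = np.clip(c + dt * dcdt, 0.0, 1.0)
        if self.inl_flat is not None:
            flat_c[self.inl_flat] = 1.0
        g.scalar_c = flat_c.reshape(g.shape)


# ---------------------------------------------------------------------------
# Ventilation metrics
# ---------------------------------------------------------------------------


def region_mean_C(grid: FlowGrid, region_mask: np.ndarray) -> float:
    """Volume-weighted mean of C over a cell mask (uniform cells)."""
    n = int(region_mask.sum())
    if n == 0:
        raise ParameterError("region mask is empty")
    return float(grid.scalar_c[region_mask].mean())


def iso_volume_fraction(grid: FlowGrid, region_mask: np.ndarray, threshold: float) -> float:
    """Fraction of the region's volume where C exceeds the threshold."""
    if not (0.0 < threshold < 1.0):
        raise ParameterError("threshold must lie in (0, 1)")
    n = int(region_mask.sum())
    if n == 0:
        raise ParameterError("region mask is empty")
    return float((grid.scalar_c[region_mask] > threshold).mean())


def region_flow_fraction(
    grid: FlowGrid,
    plane_origin: np.ndarray,
    plane_normal: np.ndarray,
    Q: float,
    point_filter=None,
    quad_dx: float | None = None,
    velocity: np.ndarray | None = None,
) -> float:
    """Percentage of the inlet flow crossing an oriented plane section.

    The flux integral over the section is evaluated by midpoint quadrature on
    a regular point lattice (spacing ``quad_dx``, default dx/2) spanning the
    grid box; points outside the fluid, or rejected by ``point_filter(points)``,
    do not contribute.  Returns 100 * flux / Q.
    """
    if Q <= 0:
        raise ParameterError("inlet flow must be positive for a flow fraction")
    n = np.asarray(plane_normal, float)
    n = n / np.linalg.norm(n)
    o = np.asarray(plane_origin, float)
    h = grid.dx / 2.0 if quad_dx is None else quad_dx
    # plane basis
    a = np.array([1.0, 0.0, 0.0])
    if abs(n @ a) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(n, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    lo, hi = grid.bounds
    half_diag = 0.5 * np.linalg.norm(hi - lo)
    r = np.arange(-half_diag, half_diag + h, h)
    P = o + r[:, None, None] * e1 + r[None, :, None] * e2
    pts = P.reshape(-1, 3)
    inb = np.all((pts >= lo) & (pts <= hi), axis=1)
    pts = pts[inb]
    # keep fluid points only
    ijk = np.clip(
        ((pts - grid.origin) / grid.dx).astype(np.int64),
        0,
        np.array(grid.shape) - 1,
    )
    fluid = grid.inside[ijk[:, 0], ijk[:, 1], ijk[:, 2]]
    pts = pts[fluid]
    if point_filter is not None and len(pts):
        pts = pts[point_filter(pts)]
    if len(pts) == 0:
        return 0.0
    u, _ = sample_velocity_many(grid, pts, velocity)
    flux = float((u @ n).sum()) * h * h
    return 100.0 * flux / Q


@dataclass
class VentilationReport:
    """Regional ventilation summary at one evaluation time."""

    time: float
    mean_C: dict[str, float] = field(default_factory=dict)
    iso_fraction_05: dict[str, float] = field(default_factory=dict)
    iso_fraction_099: dict[str, float] = field(default_factory=dict)
    flow_fraction_pct: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "time_s": self.time,
            "mean_C": self.mean_C,
            "iso_volume_fraction_C_gt_0.5": self.iso_fraction_05,
            "iso_volume_fraction_C_gt_0.99": self.iso_fraction_099,
            "flow_fraction_pct": self.flow_fraction_pct,
        }
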