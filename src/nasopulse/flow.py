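"""Prescribed velocity fields, the pulsatile inlet waveform, and field sampling.

The momentum equation is not solved here: velocity fields are prescribed on
the voxel grid (Poiseuille profiles in straight ducts, a duct-following
profile in swept geometries, or user-supplied gridded fields) and pulsation
is applied quasi-steadily, scaling the base field by the instantaneous inlet
waveform.  The waveform is the sinusoidal law

    U(t) = U0 * (1 + sin(2 pi f t)),

whose time average over any whole number of periods is the mean inlet speed
U0; at the default 45 Hz the oscillation period is 22.2 ms.

For the nasal surrogate the base field additionally carries a dorsal
"valve-jet" component downstream of the nasal-valve constriction,
representing the impingement of the post-valve jet on the dorsal wall; its
strength is attenuated in pulsatile mode (oscillation disrupts the jet).
See docs/methods.md for the rationale and limitations of this closure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .config import OutOfDomainError, ParameterError
from .geometry import DuctChart, FlowGrid

__all__ = [
    "Waveform",
    "JetSpec",
    "inlet_velocity",
    "poiseuille_field",
    "duct_following_field",
    "quasi_steady_scale",
    "waveform_factor",
    "sample_velocity",
    "sample_velocity_many",
    "divergence",
    "extend_velocity_into_walls",
]


# ---------------------------------------------------------------------------
# Inlet waveform
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Waveform:
    """Inlet volumetric-flow law: steady, or U0 (1 + sin(2 pi f t)).

    ``U0`` is tied to the mean flow by U0 = Q0 / inlet_area.
    """

    mode: str  # "steady" | "sinusoidal"
    Q0: float  # mean volumetric flow [m^3/s]
    inlet_area: float  # [m^2]
    frequency_Hz: float = 45.0

    def __post_init__(self) -> None:
        if self.mode not in ("steady", "sinusoidal"):
            raise ParameterError(f"unknown waveform mode {self.mode!r}")
        if self.inlet_area <= 0 or self.Q0 < 0:
            raise ParameterError("waveform needs positive inlet area and Q0 >= 0")
        if self.mode == "sinusoidal" and self.frequency_Hz <= 0:
            raise ParameterError("pulsation frequency must be positive")

    @property
    def U0(self) -> float:
        return self.Q0 / self.inlet_area

    @property
    def period(self) -> float:
        if self.mode != "sinusoidal":
            return math.inf
        return 1.0 / self.frequency_Hz


def inlet_velocity(w: Waveform, t: float | np.ndarray) -> float | np.ndarray:
    """Instantaneous inlet speed U(t) in [0, 2 U0]."""
    if w.mode == "steady":
        return w.U0 if np.isscalar(t) else np.full_like(np.asarray(t, float), w.U0)
    return w.U0 * (1.0 + np.sin(2.0 * math.pi * w.frequency_Hz * np.asarray(t)))


def waveform_factor(w: Waveform, t: float | np.ndarray) -> float | np.ndarray:
    """Dimensionless quasi-steady scale U(t)/U0."""
    if w.mode == "steady":
        return 1.0 if np.isscalar(t) else np.ones_like(np.asarray(t, float))
    return 1.0 + np.sin(2.0 * math.pi * w.frequency_Hz * np.asarray(t))


def quasi_steady_scale(base_velocity: np.ndarray, w: Waveform, t: float) -> np.ndarray:
    """Base field scaled by the instantaneous waveform (pure scalar multiple)."""
    return base_velocity * float(waveform_factor(w, t))


# ---------------------------------------------------------------------------
# Prescribed fields
# ---------------------------------------------------------------------------


def poiseuille_field(
    grid: FlowGrid,
    Q: float,
    axis_origin: np.ndarray | None = None,
    axis_dir: np.ndarray | None = None,
    radius: float | None = None,
) -> None:
    """Fully developed laminar profile u(r) = 2 (Q / pi R^2) (1 - (r/R)^2).

    Defaults assume the straight-duct chart (+z axis through the origin with
    the chart radius).  Cells beyond the duct radius get zero velocity.
    """
    if Q < 0:
        raise ParameterError("flow must be non-negative")
    if axis_origin is None or axis_dir is None or radius is None:
        if grid.chart is None:
            raise ParameterError("grid has no chart; pass axis and radius explicitly")
        axis_origin = grid.chart.points[0]
        axis_dir = grid.chart.tangents[0]
        radius = float(grid.chart.r0[0])
    axis_dir = np.asarray(axis_dir, float)
    axis_dir = axis_dir / np.linalg.norm(axis_dir)
    centers = grid.cell_centers()
    rel = centers - np.asarray(axis_origin, float)
    axial = rel @ axis_dir
    radial_vec = rel - axial[..., None] * axis_dir
    r2 = np.einsum("...i,...i->...", radial_vec, radial_vec)
    u_mean = Q / (math.pi * radius**2)
    profile = 2.0 * u_mean * np.clip(1.0 - r2 / radius**2, 0.0, None)
    grid.velocity = profile[..., None] * axis_dir


@dataclass(frozen=True)
class JetSpec:
    """Dorsal valve-jet component of the surrogate base flow.

    ``strength`` is the peak jet speed as a fraction of the mean speed at the
    valve throat; the jet acts over a Gaussian window of width ``s_sigma``
    centered ``s_offset`` downstream of the throat, points along the local
    dorsal frame direction and carries the same parabolic radial profile as
    the axial flow (so the dorsal displacement a parcel picks up while
    traversing the window is nearly independent of its radial position).
    """

    strength: float = 0.01
    s_offset: float = 0.055
    s_sigma: float = 0.03
    pulsatile_attenuation: float = 0.3


def duct_following_field(
    grid: FlowGrid,
    Q: float,
    profile: str = "parabolic",
    jet: JetSpec | None = None,
    jet_scale: float = 1.0,
    valve_s: float | None = None,
) -> None:
    """Velocity that follows the swept duct with conserved volumetric flow.

    At chart coordinates (s, theta, eta) the velocity is directed along the
    duct coordinate line d/ds at fixed (eta, theta),

        u = (f(eta) Q / A(s)) * ( T + eta (dr_wall/ds) rho_hat / h ),
        h = 1 - kappa(s) rho cos(theta),

    with f = 1 (plug) or 2 (1 - eta^2) (parabolic).  The radial term keeps
    streamlines attached to the tapering wall (valve constriction, nosepiece
    blends) and the curvature metric factor h makes streamlines follow bends
    exactly (a tracer released in the duct never drifts into the wall of a
    curve).  Cells outside the fluid are filled by nearest-inside extension
    so near-wall interpolation does not spuriously decelerate parcels.
    """
    chart = grid.chart
    if chart is None or grid.s_cell is None:
        raise ParameterError("duct_following_field needs a chart-voxelized grid")
    if profile not in ("parabolic", "plug"):
        raise ParameterError(f"unknown profile {profile!r}")

    ins = grid.inside
    s = grid.s_cell[ins]
    theta = grid.theta_cell[ins]
    eta = np.clip(grid.eta_cell[ins], 0.0, 1.0)

    A = chart.section_area(s)
    w = Q / A
    if profile == "parabolic":
        w = 2.0 * w * (1.0 - eta**2)

    T = chart.interp(s, chart.tangents)
    N = chart.interp(s, chart.normals)
    B = chart.interp(s, chart.binormals)
    T /= np.maximum(np.linalg.norm(T, axis=1, keepdims=True), 1e-300)

    # wall-slope radial component: dr_wall/ds at the cell's azimuth
    dr0 = np.gradient(chart.r0, chart.s)
    damp = np.gradient(chart.amp, chart.s)
    r0 = np.interp(s, chart.s, chart.r0)
    amp = np.interp(s, chart.s, chart.amp)
    cosN = np.cos(chart.nlobes * theta)
    drds = np.interp(s, chart.s, dr0) * (1.0 + amp * cosN) + np.interp(s, chart.s, damp) * r0 * cosN
    rho_hat = np.cos(theta)[:, None] * N + np.sin(theta)[:, None] * B

    rho = eta * r0 * (1.0 + amp * cosN)
    kappa = np.interp(s, chart.s, chart.curvature)
    h = np.clip(1.0 - kappa * rho * np.cos(theta), 0.25, 4.0)
    u = w[:, None] * (T + (eta * drds / h)[:, None] * rho_hat)

    if jet is not None and jet.strength != 0.0:
        if valve_s is None:
            valve_s = float(chart.s[np.argmin(chart.r0)])
        a_min = float(chart.section_area(np.array([valve_s]))[0])
        w_valve = Q / a_min
        sc = valve_s + jet.s_offset
        g = np.exp(-0.5 * ((s - sc) / jet.s_sigma) ** 2) * (1.0 - eta**2)
        u += (jet.strength * jet_scale * w_valve * g)[:, None] * N

    vel = np.zeros(grid.shape + (3,))
    vel[ins] = u
    grid.velocity = vel
    extend_velocity_into_walls(grid)


def extend_velocity_into_walls(grid: FlowGrid) -> None:
    """Fill outside cells with the value of the nearest inside cell."""
    if grid.inside.all():
        return
    _, idx = ndimage.distance_transform_edt(~grid.inside, return_indices=True)
    grid.velocity = grid.velocity[idx[0], idx[1], idx[2]]


# ---------------------------------------------------------------------------
# Sampling and derivatives
# ---------------------------------------------------------------------------


def sample_velocity_many(
    grid: FlowGrid, x: np.ndarray, velocity: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Trilinear interpolation of the (cell-centered) velocity at points x.

    Returns ``(u, in_box)``; rows with ``in_box == False`` are outside the
    grid bounding box and hold clamped-edge values (the caller decides how to
    treat them - transport marks such parcels escaped).
    """
    vel = grid.velocity if velocity is None else velocity
    x = np.atleast_2d(np.asarray(x, float))
    lo, hi = grid.bounds
    in_box = np.all((x >= lo) & (x <= hi), axis=1)
    f = (x - grid.origin) / grid.dx - 0.5
    nx, ny, nz = grid.shape
    f = np.clip(f, 0.0, np.array([nx - 1, ny - 1, nz - 1], float) - 1e-12)
    i0 = np.minimum(f.astype(np.int64), np.array([nx - 2, ny - 2, nz - 2]))
    i0 = np.maximum(i0, 0)
    w = f - i0
    is_vec = vel.ndim == 4
    vflat = vel.reshape(-1, 3) if is_vec else vel.ravel()
    base = i0[:, 0] * (ny * nz) + i0[:, 1] * nz + i0[:, 2]
    out = np.zeros((len(x), 3) if is_vec else (len(x),))
    for dx_ in (0, 1):
        wx = w[:, 0] if dx_ else 1.0 - w[:, 0]
        for dy in (0, 1):
            wy = w[:, 1] if dy else 1.0 - w[:, 1]
            for dz in (0, 1):
                wz = w[:, 2] if dz else 1.0 - w[:, 2]
                weight = wx * wy * wz
                vals = vflat[base + (dx_ * ny * nz + dy * nz + dz)]
                out += weight[:, None] * vals if is_vec else weight * vals
    return out, in_box


def sample_velocity(grid: FlowGrid, x: np.ndarray) -> np.ndarray:
    """Velocity at a single point; raises OutOfDomainError outside the box."""
    u, ok = sample_velocity_many(grid, np.asarray(x, float)[None, :])
    if not ok[0]:
        raise OutOfDomainError(f"point {x} outside grid bounding box")
    return u[0]


def divergence(grid: FlowGrid, velocity: np.ndarray | None = None) -> np.ndarray:
    """Central-difference divergence (1/s), one-sided at box edges."""
    vel = grid.velocity if velocity is None else velocity
    div = np.zeros(grid.shape)
    for ax in range(3):
        div += np.gradient(vel[..., ax], grid.dx, axis=ax)
    return div
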