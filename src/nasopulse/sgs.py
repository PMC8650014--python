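"""Localized dynamic k-equation subgrid-scale operators and LES quality index.

The closure models unresolved turbulence through an eddy viscosity driven by
the subgrid kinetic energy,

    nu_sgs = Ck * Delta * sqrt(k_sgs),

with ``k_sgs`` advanced by a transport equation (production by resolved
strain, dissipation ~ Ceps k^{3/2}/Delta, eddy diffusion).  The coefficients
Ck and Ceps are computed dynamically from the resolved field with a test
filter of width 2*Delta via the Germano identity, in the spirit of the
localized one-equation dynamic procedure.  All operators act on the full
cell-centered grid arrays with one-sided truncation at the box boundary, so
they double as standalone field diagnostics.

The scale-similarity tensor printed by the source model contracts a scalar
prefactor against the strain tensor; both readings (contract the scalar with
the trace of L, or form a tensor M_ij = M * S_ij) are implemented behind the
``convention`` flag of :func:`dynamic_coeffs`.  The scalar convention is the
default: it is dimensionless and invariant under the joint scaling
(u -> lambda u, k -> lambda^2 k), which the tensor variant is not.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .config import ParameterError, StabilityError

__all__ = [
    "CK_FALLBACK",
    "CEPS_FALLBACK",
    "strain_rate",
    "strain_magnitude",
    "test_filter",
    "germano_L",
    "m_tensor",
    "dynamic_coeffs",
    "nu_sgs",
    "advance_ksgs",
    "les_iq",
    "resolved_tke",
    "iq_report",
]

#: standard one-equation model constants, used where the dynamic denominators
#: degenerate (uniform flow, quiescent cells)
CK_FALLBACK = 0.094
CEPS_FALLBACK = 1.048

#: clipping bounds for the dynamic coefficients (backscatter excluded)
CK_BOUNDS = (0.0, 0.5)
CEPS_BOUNDS = (0.5, 5.0)

_DEN_EPS = 1e-30


# ---------------------------------------------------------------------------
# Differential / filter operators
# ---------------------------------------------------------------------------


def strain_rate(grid, velocity: np.ndarray | None = None) -> np.ndarray:
    """Filtered strain-rate tensor S_ij = (du_i/dx_j + du_j/dx_i)/2.

    Central differences in the interior, one-sided at the box boundary;
    returns an (nx, ny, nz, 3, 3) symmetric array.
    """
    vel = grid.velocity if velocity is None else velocity
    g = np.empty(vel.shape[:3] + (3, 3))
    for i in range(3):
        for j in range(3):
            g[..., i, j] = np.gradient(vel[..., i], grid.dx, axis=j)
    return 0.5 * (g + np.swapaxes(g, -1, -2))


def strain_magnitude(S: np.ndarray) -> np.ndarray:
    """|S| = sqrt(2 S_ij S_ij)."""
    return np.sqrt(2.0 * np.einsum("...ij,...ij->...", S, S))


def test_filter(field: np.ndarray) -> np.ndarray:
    """3x3x3 top-hat average over the first three axes.

    Linear, constant-preserving; at the box boundary the stencil is truncated
    to the available cells (the average is over fewer points, so constants
    are still preserved exactly).
    """
    field = np.asarray(field, float)
    kern = np.ones((3, 3, 3))
    norm = ndimage.correlate(np.ones(field.shape[:3]), kern, mode="constant", cval=0.0)
    if field.ndim == 3:
        num = ndimage.correlate(field, kern, mode="constant", cval=0.0)
        return num / norm
    flat = field.reshape(field.shape[:3] + (-1,))
    out = np.empty_like(flat)
    for c in range(flat.shape[-1]):
        out[..., c] = ndimage.correlate(flat[..., c], kern, mode="constant", cval=0.0) / norm
    return out.reshape(field.shape)


def germano_L(grid, velocity: np.ndarray | None = None) -> np.ndarray:
    """Germano-identity resolved stress L_ij = tf(u_i u_j) - tf(u_i) tf(u_j)."""
    vel = grid.velocity if velocity is None else velocity
    uu = vel[..., :, None] * vel[..., None, :]
    tf_uu = test_filter(uu)
    tf_u = test_filter(vel)
    return tf_uu - tf_u[..., :, None] * tf_u[..., None, :]


def m_tensor(grid, k_sgs: np.ndarray | None = None) -> np.ndarray:
    """Scalar prefactor field of the scale-similarity tensor,

        M = Delta * sqrt(k) * tf(|S|)  -  2 * Dhat * sqrt(tf(k)) * |tf(S)|,

    with test-filter width Dhat = 2 * Delta.  The contraction against strain
    (tensor convention) or against the trace of L (scalar convention) happens
    in :func:`dynamic_coeffs`.
    """
    k = grid.k_sgs if k_sgs is None else k_sgs
    if np.any(k < 0):
        raise ParameterError("k_sgs must be non-negative")
    delta = grid.delta_tilde
    dhat = 2.0 * delta
    S = strain_rate(grid)
    s_mag = strain_magnitude(S)
    s_hat_mag = strain_magnitude(test_filter(S))
    return delta * np.sqrt(k) * test_filter(s_mag) - dhat * np.sqrt(test_filter(k)) * s_hat_mag


def dynamic_coeffs(
    grid,
    k_sgs: np.ndarray | None = None,
    convention: str = "scalar",
    clip: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Dynamic (Ck, Ceps) coefficient fields from the Germano identity.

    The local averages <.> are the 3^3 test-filter stencil average.  Cells
    where the dynamic identity degenerates (vanishing numerator or
    denominator: uniform flow, uniform k, quiescent regions) fall back to the
    standard constants; elsewhere the coefficients are clipped to
    CK_BOUNDS / CEPS_BOUNDS unless ``clip`` is False (raw values, for oracle
    comparison).
    """
    k = grid.k_sgs if k_sgs is None else k_sgs
    if convention not in ("scalar", "tensor"):
        raise ParameterError(f"unknown contraction convention {convention!r}")
    L = germano_L(grid)
    M = m_tensor(grid, k)
    xi = np.einsum("...ii->...", L)

    if convention == "scalar":
        num = test_filter(xi * M)
        den = test_filter(M * M)
    else:
        S = strain_rate(grid)
        Mij = M[..., None, None] * S
        num = test_filter(np.einsum("...ij,...ij->...", L, Mij))
        den = test_filter(np.einsum("...ij,...ij->...", Mij, Mij))
    ok = (np.abs(den) > _DEN_EPS) & (np.abs(num) > _DEN_EPS)
    ck = np.where(ok, num / np.where(ok, den, 1.0), CK_FALLBACK)

    delta = grid.delta_tilde
    dhat = 2.0 * delta
    m = test_filter(k) ** 1.5 / dhat - test_filter(k**1.5 / delta)
    num_e = test_filter(xi * m)
    den_e = test_filter(m * m)
    ok_e = (np.abs(den_e) > _DEN_EPS) & (np.abs(num_e) > _DEN_EPS)
    ceps = np.where(ok_e, num_e / np.where(ok_e, den_e, 1.0), CEPS_FALLBACK)

    if clip:
        ck = np.clip(ck, *CK_BOUNDS)
        ceps = np.clip(ceps, *CEPS_BOUNDS)
    return ck, ceps


def nu_sgs(k_sgs: np.ndarray, delta: float | np.ndarray, ck: float | np.ndarray = CK_FALLBACK) -> np.ndarray:
    """Eddy viscosity nu_sgs = Ck * Delta * sqrt(k_sgs) (>= 0)."""
    k = np.asarray(k_sgs, float)
    if np.any(k < 0):
        raise ParameterError("k_sgs must be non-negative")
    return np.asarray(ck) * np.asarray(delta) * np.sqrt(k)


# ---------------------------------------------------------------------------
# k_sgs transport
# ---------------------------------------------------------------------------


def advance_ksgs(
    grid,
    dt: float,
    ck: float | np.ndarray = CK_FALLBACK,
    ceps: float | np.ndarray = CEPS_FALLBACK,
) -> np.ndarray:
    """One explicit step of the k_sgs transport equation.

    dk/dt + u.grad(k) = nu_sgs * 2 S:S - Ceps k^{3/2}/Delta + div(nu_sgs grad k)

    First-order upwind advection, conservative central diffusion with
    face-averaged eddy viscosity and zero-flux box edges, pointwise
    production/dissipation; the result is clipped at zero and stored back on
    the grid.  Raises StabilityError if dt violates the advective CFL or the
    diffusive bound dt <= dx^2 / (6 max nu_sgs).
    """
    if dt <= 0:
        raise ParameterError("dt must be positive")
    k = grid.k_sgs
    vel = grid.velocity
    dx = grid.dx
    nu = nu_sgs(k, grid.delta_tilde, ck)

    umax = float(np.abs(vel).max())
    if umax > 0 and dt > dx / umax:
        raise StabilityError(f"advective CFL violated: dt={dt} > dx/|u|max={dx / umax:.3e}")
    numax = float(np.max(nu))
    if numax > 0 and dt > dx**2 / (6.0 * numax):
        raise StabilityError(f"diffusive bound violated: dt={dt} > {dx**2 / (6 * numax):.3e}")

    S = strain_rate(grid)
    production = nu * 2.0 * np.einsum("...ij,...ij->...", S, S)
    dissipation = np.asarray(ceps) * k**1.5 / grid.delta_tilde

    adv = np.zeros_like(k)
    diff = np.zeros_like(k)
    for ax in range(3):
        u = vel[..., ax]
        # one-sided differences with edge replication
        k_m = np.concatenate([k.take([0], axis=ax), k], axis=ax)
        bwd = np.diff(k_m, axis=ax) / dx
        k_p = np.concatenate([k, k.take([-1], axis=ax)], axis=ax)
        fwd = np.diff(k_p, axis=ax) / dx
        adv += np.where(u > 0, u * bwd, u * fwd)

        # conservative diffusion with zero-flux edges
        nu_face = 0.5 * (_take_slice(nu, ax, 1, None) + _take_slice(nu, ax, None, -1))
        grad_face = (_take_slice(k, ax, 1, None) - _take_slice(k, ax, None, -1)) / dx
        flux = nu_face * grad_face  # on interior faces
        pad = [(0, 0)] * 3
        pad[ax] = (1, 1)
        flux_pad = np.pad(flux, pad)  # zero-flux at the two edge faces
        diff += np.diff(flux_pad, axis=ax) / dx

    k_new = k + dt * (-adv + production - dissipation + diff)
    grid.k_sgs = np.clip(k_new, 0.0, None)
    return grid.k_sgs


def _take_slice(a: np.ndarray, ax: int, start, stop) -> np.ndarray:
    sl = [slice(None)] * a.ndim
    sl[ax] = slice(start, stop)
    return a[tuple(sl)]


# ---------------------------------------------------------------------------
# Resolution quality
# ---------------------------------------------------------------------------


def les_iq(k_res: np.ndarray, k_sgs: np.ndarray) -> np.ndarray:
    """Resolution index M = k_res / (k_res + k_sgs) in [0, 1].

    Quiescent cells (both energies zero) are defined as fully resolved
    (M = 1): there is nothing left to resolve.
    """
    k_res = np.asarray(k_res, float)
    k_sgs = np.asarray(k_sgs, float)
    if np.any(k_res < 0) or np.any(k_sgs < 0):
        raise ParameterError("kinetic energies must be non-negative")
    tot = k_res + k_sgs
    return np.where(tot > 0, k_res / np.where(tot > 0, tot, 1.0), 1.0)


def resolved_tke(snapshots: list[np.ndarray]) -> np.ndarray:
    """Resolved TKE 0.5 <|u - <u>_t|^2>_t over a window of velocity snapshots."""
    if len(snapshots) < 2:
        raise ParameterError("need at least two snapshots to form fluctuations")
    stack = np.stack(snapshots)
    mean = stack.mean(axis=0)
    fluct = stack - mean
    return 0.5 * np.einsum("t...i,t...i->...", fluct, fluct) / len(snapshots)


def iq_report(M: np.ndarray, inside: np.ndarray | None = None) -> dict:
    """Fractions of (inside) cells meeting the usual resolution bands."""
    vals = M if inside is None else M[inside]
    n = vals.size
    if n == 0:
        raise ParameterError("no cells to report on")
    return {
        "n_cells": int(n),
        "fraction_M_ge_0.8": float(np.mean(vals >= 0.8)),
        "fraction_M_ge_0.99": float(np.mean(vals >= 0.99)),
        "fraction_M_below_0.77": float(np.mean(vals < 0.77)),
        "min_M": float(vals.min()),
    }
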