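"""Waveform, prescribed fields, interpolation and divergence diagnostics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from nasopulse.config import OutOfDomainError, ParameterError
from nasopulse.flow import (
    Waveform,
    divergence,
    duct_following_field,
    inlet_velocity,
    poiseuille_field,
    quasi_steady_scale,
    sample_velocity,
    sample_velocity_many,
)

AREA = math.pi * 0.005**2
Q4 = 4.0 * 1e-3 / 60.0  # 4 L/min in m^3/s


def _wave(mode="sinusoidal", f=45.0):
    return Waveform(mode=mode, Q0=Q4, inlet_area=AREA, frequency_Hz=f)


class TestWaveform:
    def test_sinusoidal_phase_values(self):
        w = _wave()
        T = 1.0 / 45.0
        assert inlet_velocity(w, 0.0) == pytest.approx(w.U0, rel=1e-12)
        assert inlet_velocity(w, T / 4) == pytest.approx(2 * w.U0, rel=1e-12)
        assert inlet_velocity(w, 3 * T / 4) == pytest.approx(0.0, abs=1e-12 * w.U0)

    def test_oscillation_period_at_45_hz(self):
        assert _wave().period * 1e3 == pytest.approx(22.2, abs=0.05)

    def test_range_is_zero_to_twice_mean(self):
        w = _wave()
        t = np.linspace(0, 0.2, 4001)
        u = inlet_velocity(w, t)
        assert u.min() >= -1e-12 and u.max() <= 2 * w.U0 + 1e-12

    @pytest.mark.parametrize("k", [1, 3, 10])
    def test_mean_over_whole_periods_is_U0(self, k):
        w = _wave()
        T = w.period
        val, _ = quad(lambda t: inlet_velocity(w, t), 0.0, k * T, limit=200)
        assert val / (k * T) == pytest.approx(w.U0, rel=1e-10)

    def test_steady_mode_constant(self):
        w = _wave("steady")
        assert inlet_velocity(w, 0.123) == pytest.approx(w.U0, rel=1e-15)

    @given(st.floats(min_value=0.0, max_value=10.0), st.floats(min_value=1.0, max_value=200.0))
    @settings(derandomize=True, max_examples=100, deadline=None)
    def test_speed_stays_in_physical_range(self, t, f):
        w = Waveform(mode="sinusoidal", Q0=Q4, inlet_area=AREA, frequency_Hz=f)
        u = inlet_velocity(w, t)
        assert -1e-12 <= u <= 2 * w.U0 + 1e-12

    def test_invalid_waveforms_raise(self):
        with pytest.raises(ParameterError):
            Waveform(mode="square", Q0=Q4, inlet_area=AREA)
        with pytest.raises(ParameterError):
            Waveform(mode="sinusoidal", Q0=Q4, inlet_area=AREA, frequency_Hz=0.0)


class TestPoiseuille:
    def test_centerline_and_mean_speed(self, duct_grid):
        poiseuille_field(duct_grid, Q4)
        u_center = sample_velocity(duct_grid, np.array([0.0, 0.0, 0.05]))
        u_mean = Q4 / AREA
        assert u_mean == pytest.approx(0.8488, rel=1e-3)  # 4 L/min through R = 5 mm
        assert u_center[2] == pytest.approx(2 * u_mean, rel=0.02)
        assert abs(u_center[0]) < 1e-12 and abs(u_center[1]) < 1e-12

    def test_flux_through_cross_section(self, duct_grid):
        poiseuille_field(duct_grid, Q4)
        flux = duct_grid.velocity[..., 2][duct_grid.inside].sum() * duct_grid.dx**2
        n_slices = len(np.unique(np.argwhere(duct_grid.inside)[:, 2]))
        assert flux / n_slices == pytest.approx(Q4, rel=0.02)

    def test_zero_outside_duct(self, duct_grid):
        poiseuille_field(duct_grid, Q4)
        centers = duct_grid.cell_centers()
        r2 = centers[..., 0] ** 2 + centers[..., 1] ** 2
        outside = r2 > (0.005 * 1.05) ** 2
        assert np.abs(duct_grid.velocity[outside]).max() == 0.0


class TestQuasiSteadyScale:
    def test_t0_equals_base_and_3T4_is_zero(self, duct_grid):
        poiseuille_field(duct_grid, Q4)
        base = duct_grid.velocity
        w = _wave()
        T = w.period
        assert np.array_equal(quasi_steady_scale(base, w, 0.0), base)
        assert np.abs(quasi_steady_scale(base, w, 0.75 * T)).max() < 1e-12

    def test_pointwise_scalar_multiple(self, duct_grid):
        poiseuille_field(duct_grid, Q4)
        base = duct_grid.velocity
        w = _wave()
        scaled = quasi_steady_scale(base, w, 0.013)
        nz = np.abs(base) > 1e-9
        ratios = scaled[nz] / base[nz]
        assert np.ptp(ratios) < 1e-12

    def test_period_average_recovers_base(self, duct_grid):
        poiseuille_field(duct_grid, Q4)
        base = duct_grid.velocity
        w = _wave()
        T = w.period
        n = 4096
        ts = (np.arange(n) + 0.5) * T / n
        mean_fac = np.mean(1.0 + np.sin(2 * math.pi * w.frequency_Hz * ts))
        avg = base * mean_fac
        nz = np.abs(base) > 1e-9
        assert np.max(np.abs(avg[nz] / base[nz] - 1.0)) < 1e-6


class TestSampling:
    def test_cell_center_returns_stored_value(self, duct_grid):
        poiseuille_field(duct_grid, Q4)
        i, j, k = 10, 10, 40
        center = duct_grid.origin + (np.array([i, j, k]) + 0.5) * duct_grid.dx
        u = sample_velocity(duct_grid, center)
        assert u == pytest.approx(duct_grid.velocity[i, j, k], rel=1e-12)

    def test_affine_field_reproduced_exactly(self, duct_grid, rng):
        a = rng.normal(size=3)
        B = rng.normal(size=(3, 3))
        centers = duct_grid.cell_centers()
        duct_grid.velocity = a + centers @ B.T
        lo, hi = duct_grid.bounds
        pts = rng.uniform(lo + duct_grid.dx, hi - duct_grid.dx, size=(50, 3))
        u, ok = sample_velocity_many(duct_grid, pts)
        assert ok.all()
        expect = a + pts @ B.T
        assert np.abs(u - expect).max() < 1e-12 * max(1.0, np.abs(expect).max())

    def test_poiseuille_matches_closed_form_off_grid(self, duct_grid, rng):
        poiseuille_field(duct_grid, Q4)
        r = 0.003 * np.sqrt(rng.uniform(0.1, 0.9, 40))
        phi = rng.uniform(0, 2 * math.pi, 40)
        z = rng.uniform(0.02, 0.08, 40)
        pts = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
        u, _ = sample_velocity_many(duct_grid, pts)
        exact = 2 * (Q4 / AREA) * (1 - (r / 0.005) ** 2)
        # trilinear on a parabola: O(dx^2) curvature error
        assert np.abs(u[:, 2] - exact).max() < 0.02 * exact.max()

    def test_outside_bounding_box_raises(self, duct_grid):
        with pytest.raises(OutOfDomainError):
            sample_velocity(duct_grid, np.array([1.0, 1.0, 1.0]))


class TestDivergence:
    def test_uniform_field_divergence_free(self, duct_grid):
        duct_grid.velocity = np.ones(duct_grid.shape + (3,))
        assert np.abs(divergence(duct_grid)).max() < 1e-12

    def test_rotational_field_divergence_free(self, duct_grid):
        c = duct_grid.cell_centers()
        duct_grid.velocity = np.stack(
            [c[..., 0], -c[..., 1], np.zeros(duct_grid.shape)], axis=-1
        )
        assert np.abs(divergence(duct_grid)).max() < 1e-10

    def test_linear_shear_unit_divergence(self, duct_grid):
        c = duct_grid.cell_centers()
        duct_grid.velocity = np.stack(
            [c[..., 0], np.zeros(duct_grid.shape), np.zeros(duct_grid.shape)], axis=-1
        )
        div = divergence(duct_grid)
        assert np.abs(div - 1.0).max() < 1e-10


class TestDuctFollowingField:
    def test_flux_conserved_through_constriction(self, surrogate_mesh, surrogate_grid):
        duct_following_field(surrogate_grid, Q4, profile="parabolic")
        g = surrogate_grid
        chart = surrogate_mesh.chart
        # flux through planes at three arclengths, via tangential velocity sum
        for s0 in (0.05, 0.15, 0.25):
            sel = g.inside & (np.abs(g.s_cell - s0) < g.dx / 2)
            tangent = chart.interp(np.array([s0]), chart.tangents)[0]
            flux = (g.velocity[sel] @ tangent).sum() * g.dx**2
            assert flux == pytest.approx(Q4, rel=0.25)  # first-order voxel quadrature

    def test_velocity_extends_into_walls(self, surrogate_grid):
        duct_following_field(surrogate_grid, Q4)
        outside_speed = np.linalg.norm(surrogate_grid.velocity[~surrogate_grid.inside], axis=-1)
        assert outside_speed.max() > 0.0  # nearest-inside extension, not zeros
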