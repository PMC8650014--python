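"""Parcel kinematics, drag closure, wall detection, injection and coupling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nasopulse.config import MU_AIR, NU_AIR, ParameterError
from nasopulse.flow import Waveform, duct_following_field
from nasopulse.geometry import PatchInfo, SurfaceMesh
from nasopulse.metrics import mass_balance
from nasopulse.transport import (
    ACTIVE,
    DEPOSITED,
    ESCAPED,
    InjectionSpec,
    adaptive_dt,
    advance_kinematics,
    advance_parcel,
    coupling_source,
    detect_wall_hit,
    drag_factor,
    inject_parcels,
    particle_reynolds,
    run_transport,
    stokes_relaxation_time,
)

Q4 = 4.0e-3 / 60.0


class TestRelaxationTime:
    def test_one_micron_unit_density(self):
        tau = stokes_relaxation_time(1e-6, 1000.0, 1.8e-5)
        assert tau == pytest.approx(3.086e-6, rel=1e-3)

    def test_three_micron(self):
        assert stokes_relaxation_time(3e-6, 1000.0, 1.8e-5) == pytest.approx(2.78e-5, rel=1e-2)

    def test_quadratic_in_diameter(self):
        assert stokes_relaxation_time(2e-6, 1000.0) == pytest.approx(
            4 * stokes_relaxation_time(1e-6, 1000.0), rel=1e-12
        )

    def test_nonpositive_inputs_raise(self):
        with pytest.raises(ParameterError):
            stokes_relaxation_time(-1e-6, 1000.0)


class TestDragFactor:
    @pytest.mark.parametrize(
        "re,expected,rtol",
        [(0.5, 1.0, 1e-12), (1.0, 1.0, 1e-12), (10.0, 1.7146, 1e-4), (2000.0, 36.67, 1e-3)],
    )
    def test_reference_values(self, re, expected, rtol):
        assert drag_factor(re) == pytest.approx(expected, rel=rtol)

    def test_monotone_nondecreasing(self):
        re = np.linspace(0.0, 5000.0, 2000)
        fd = drag_factor(re)
        assert np.all(np.diff(fd) >= -1e-12)
        assert np.all(fd >= 1.0)

    def test_negative_re_raises(self):
        with pytest.raises(ParameterError):
            drag_factor(-1.0)

    @given(st.floats(min_value=0.0, max_value=1e5), st.floats(min_value=0.0, max_value=1e5))
    @settings(derandomize=True, max_examples=100, deadline=None)
    def test_monotone_property(self, re_a, re_b):
        lo, hi = sorted((re_a, re_b))
        assert drag_factor(lo) <= drag_factor(hi) + 1e-12
        assert drag_factor(lo) >= 1.0


class TestParticleReynolds:
    def test_values(self):
        z = np.zeros(3)
        assert particle_reynolds(z, z, 1e-6) == 0.0
        assert particle_reynolds(np.array([1.0, 0, 0]), z, 1e-6, 1.5e-5) == pytest.approx(0.0667, rel=1e-2)
        assert particle_reynolds(np.array([30.0, 0, 0]), z, 10e-6, 1.5e-5) == pytest.approx(20.0, rel=1e-9)


class TestAnalyticIntegrator:
    def test_velocity_decay_in_still_air(self):
        tau = np.array([1e-3])
        u0 = np.array([[2.0, 0.0, 0.0]])
        dt = 3e-3
        _, u1 = advance_kinematics(np.zeros((1, 3)), u0, np.zeros((1, 3)), tau, np.zeros(3), dt)
        assert np.linalg.norm(u1) == pytest.approx(2.0 * math.exp(-dt / tau[0]), rel=1e-12)

    def test_terminal_velocity_one_micron(self):
        """In quiescent air under gravity, speed converges to tau*g within
        0.1 % after 10 tau (1 um unit density: 3.03e-5 m/s)."""
        tau = stokes_relaxation_time(1e-6, 1000.0, 1.8e-5)
        g = np.array([0.0, 0.0, -9.81])
        x = np.zeros((1, 3))
        u = np.zeros((1, 3))
        dt = tau  # 10 steps of one tau each
        for _ in range(10):
            x, u = advance_kinematics(x, u, np.zeros((1, 3)), np.array([tau]), g, dt)
        vt = tau * 9.81
        assert vt == pytest.approx(3.03e-5, rel=2e-3)
        assert np.linalg.norm(u) == pytest.approx(vt, rel=1e-3)

    def test_tracer_limit(self):
        tau = np.array([1e-6])
        u_s = np.array([[1.0, 2.0, 3.0]])
        _, u1 = advance_kinematics(np.zeros((1, 3)), np.zeros((1, 3)), u_s, tau, np.zeros(3), 50e-6)
        assert np.abs(u1 - u_s).max() < 1e-12

    def test_wrapper_reduces_to_stokes_at_low_re(self):
        x, u = advance_parcel(
            np.zeros(3), np.zeros(3), np.array([0.1, 0.0, 0.0]), 1e-6, 1000.0, np.zeros(3), 1e-5
        )
        tau = stokes_relaxation_time(1e-6, 1000.0)
        expected = 0.1 * (1 - math.exp(-1e-5 / tau))
        assert u[0] == pytest.approx(expected, rel=1e-9)


def _two_triangle_mesh():
    """Two parallel unit triangles at z = 0.5 (patch A) and z = 0.8 (patch B)."""
    v = np.array(
        [
            [0, 0, 0.5], [1, 0, 0.5], [0, 1, 0.5],
            [0, 0, 0.8], [1, 0, 0.8], [0, 1, 0.8],
        ],
        float,
    )
    f = np.array([[0, 1, 2], [3, 4, 5]])
    return SurfaceMesh(
        vertices=v,
        faces=f,
        patch_of_triangle=np.array([0, 1]),
        patch_names=["A", "B"],
        patch_table={"A": PatchInfo("wall", "A"), "B": PatchInfo("wall", "B")},
    )


class TestDetectWallHit:
    def test_crossing_hits_centroid_patch(self):
        mesh = _two_triangle_mesh()
        x0 = np.array([0.25, 0.25, 0.0])
        x1 = np.array([0.25, 0.25, 0.6])
        got = detect_wall_hit(x0, x1, mesh)
        assert got is not None
        patch, point, frac = got
        assert patch == "A"
        assert frac == pytest.approx(0.5 / 0.6, rel=1e-12)
        assert point[2] == pytest.approx(0.5, rel=1e-12)

    def test_segment_inside_returns_none(self):
        mesh = _two_triangle_mesh()
        assert detect_wall_hit(np.array([0.2, 0.2, 0.0]), np.array([0.2, 0.2, 0.4]), mesh) is None

    def test_double_crossing_earlier_patch_wins(self):
        mesh = _two_triangle_mesh()
        got = detect_wall_hit(np.array([0.25, 0.25, 0.0]), np.array([0.25, 0.25, 1.0]), mesh)
        assert got is not None and got[0] == "A"
        # reversed direction meets patch B first
        got = detect_wall_hit(np.array([0.25, 0.25, 1.0]), np.array([0.25, 0.25, 0.0]), mesh)
        assert got is not None and got[0] == "B"


class TestInjection:
    def test_total_mass_exact(self, duct_mesh):
        spec = InjectionSpec(diameter=2e-6, n_parcels=777, mass_total=2.5e-6, duration=0.5)
        ens = inject_parcels(duct_mesh, spec, seed=3)
        assert ens.total_mass == pytest.approx(2.5e-6, rel=1e-12)

    def test_same_seed_identical_stream(self, duct_mesh):
        spec = InjectionSpec(diameter=1e-6, n_parcels=100, mass_total=1e-6, duration=0.5)
        a = inject_parcels(duct_mesh, spec, seed=9)
        b = inject_parcels(duct_mesh, spec, seed=9)
        assert np.array_equal(a.x, b.x) and np.array_equal(a.birth_time, b.birth_time)

    def test_birth_times_uniform(self, duct_mesh):
        spec = InjectionSpec(diameter=1e-6, n_parcels=4000, mass_total=1e-6, duration=0.5)
        ens = inject_parcels(duct_mesh, spec, seed=5)
        sigma = 0.5 / math.sqrt(12.0) / math.sqrt(4000)
        assert abs(ens.birth_time.mean() - 0.25) < 3 * sigma
        assert ens.birth_time.min() >= 0.0 and ens.birth_time.max() <= 0.5

    def test_positions_inside_inlet_disc(self, duct_mesh):
        spec = InjectionSpec(diameter=1e-6, n_parcels=500, mass_total=1e-6, duration=0.5)
        ens = inject_parcels(duct_mesh, spec, seed=5)
        r = np.hypot(ens.x[:, 0], ens.x[:, 1])
        assert r.max() <= 0.005 + 1e-12

    def test_bad_specs_raise(self, duct_mesh):
        with pytest.raises(ParameterError):
            inject_parcels(duct_mesh, InjectionSpec(diameter=1e-6, n_parcels=0, duration=0.5))
        with pytest.raises(ParameterError):
            inject_parcels(duct_mesh, InjectionSpec(diameter=1e-6, n_parcels=5, duration=-1.0))


class TestCouplingSource:
    def test_single_parcel_at_cell_center(self, duct_grid):
        i, j, k = 8, 8, 40
        xc = duct_grid.origin + (np.array([i, j, k]) + 0.5) * duct_grid.dx
        src = coupling_source(
            duct_grid,
            xc[None, :],
            np.zeros((1, 3)),
            np.array([[1.0, 0.0, 0.0]]),
            np.array([1e-3]),
            np.array([1e-12]),
            np.array([1e6]),
        )
        nz = np.argwhere(np.abs(src.field[..., 0]) > 0)
        assert len(nz) == 1 and tuple(nz[0]) == (i, j, k)

    def test_zero_slip_gives_zero_field(self, duct_grid, rng):
        x = rng.uniform(duct_grid.origin + 0.01, duct_grid.origin + 0.012, (20, 3))
        u = rng.normal(size=(20, 3))
        src = coupling_source(
            duct_grid, x, u, u.copy(), np.full(20, 1e-3), np.full(20, 1e-12), np.full(20, 1e5)
        )
        assert np.abs(src.field).max() == 0.0

    def test_newton_third_law(self, duct_grid, rng):
        lo, hi = duct_grid.bounds
        x = rng.uniform(lo + 2 * duct_grid.dx, hi - 2 * duct_grid.dx, (200, 3))
        src = coupling_source(
            duct_grid,
            x,
            rng.normal(size=(200, 3)),
            rng.normal(size=(200, 3)),
            rng.uniform(1e-5, 1e-3, 200),
            rng.uniform(1e-13, 1e-11, 200),
            rng.uniform(1e3, 1e7, 200),
        )
        assert src.newton_residual(duct_grid.cell_volume) < 1e-12


class TestAdaptiveDt:
    def test_courant_formula(self, duct_grid):
        vel = np.zeros(duct_grid.shape + (3,))
        vel[..., 2] = 2.0
        assert adaptive_dt(duct_grid, 0.9, velocity=vel) == pytest.approx(
            0.9 * duct_grid.dx / 2.0, rel=1e-12
        )

    def test_tau_cap_for_one_micron(self, duct_grid):
        vel = np.zeros(duct_grid.shape + (3,))
        vel[..., 2] = 0.5
        tau = stokes_relaxation_time(1e-6, 1000.0, 1.8e-5)
        dt = adaptive_dt(duct_grid, 0.9, tau_min=tau, velocity=vel)
        assert dt == pytest.approx(6.17e-7, rel=1e-2)

    def test_zero_velocity_returns_dt_max(self, duct_grid):
        vel = np.zeros(duct_grid.shape + (3,))
        assert adaptive_dt(duct_grid, 0.5, velocity=vel, dt_max=0.02) == 0.02

    def test_bad_courant_raises(self, duct_grid):
        with pytest.raises(ParameterError):
            adaptive_dt(duct_grid, 1.5)


class TestRunTransport:
    def test_empty_injection_is_trivially_balanced(self, short_duct):
        mesh, grid = short_duct
        duct_following_field(grid, Q4, profile="plug")
        w = Waveform(mode="steady", Q0=Q4, inlet_area=math.pi * 0.005**2)
        spec = InjectionSpec(diameter=1e-6, n_parcels=0, mass_total=0.0, duration=0.1)
        res = run_transport(mesh, grid, w, spec, t_end=0.2, seed=0)
        assert res.injected_mass == 0.0
        assert mass_balance(res) == 0.0

    def test_tracers_in_straight_duct_escape(self, short_duct):
        """tau -> 0, no gravity: parcels follow streamlines and exit."""
        mesh, grid = short_duct
        duct_following_field(grid, Q4, profile="plug")
        w = Waveform(mode="steady", Q0=Q4, inlet_area=math.pi * 0.005**2)
        spec = InjectionSpec(diameter=1e-6, n_parcels=400, mass_total=1e-6, duration=0.05)
        res = run_transport(mesh, grid, w, spec, t_end=0.6, seed=2, gravity=(0, 0, 0))
        assert res.escaped_mass / res.injected_mass >= 0.99
        assert res.deposited_mass / res.injected_mass < 0.01
        assert mass_balance(res) < 1e-12

    def test_deterministic_repeat(self, short_duct):
        mesh, grid = short_duct
        duct_following_field(grid, Q4, profile="parabolic")
        w = Waveform(mode="steady", Q0=Q4, inlet_area=math.pi * 0.005**2)
        spec = InjectionSpec(diameter=10e-6, n_parcels=300, mass_total=1e-6, duration=0.05)
        runs = [
            run_transport(mesh, grid, w, spec, t_end=0.4, seed=11)
            for _ in range(2)
        ]
        a, b = (r.parcels for r in runs)
        assert np.array_equal(a.status, b.status)
        assert np.array_equal(a.deposit_patch, b.deposit_patch)
        assert np.array_equal(a.x, b.x)

    def test_mass_balance_with_gravity_deposition(self, short_duct):
        """Heavy particles settle onto the duct wall; the ledger still closes."""
        mesh, grid = short_duct
        duct_following_field(grid, Q4, profile="parabolic")
        w = Waveform(mode="steady", Q0=Q4, inlet_area=math.pi * 0.005**2)
        spec = InjectionSpec(diameter=30e-6, n_parcels=300, mass_total=1e-6, duration=0.05)
        res = run_transport(mesh, grid, w, spec, t_end=0.5, seed=4, gravity=(0, -9.81, 0))
        assert res.deposited_mass > 0.0
        assert mass_balance(res) < 1e-12
        # gravity is -y here: settled parcels sit in the lower half
        dep = res.parcels.status == DEPOSITED
        assert np.mean(res.parcels.x[dep][:, 1] < 0) > 0.9
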