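"""Orchestration: geometry -> flow -> transport -> scalar -> reports.

This module wires the library into the two delivery experiments (steady
versus 45 Hz pulsatile bi-directional flow through the nasal surrogate) and
the bend-validation benchmark, and owns the run-directory layout
(STL/VTK/JSON artifacts plus a manifest).
"""

from __future__ import annotations

import json
import math
import platform
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .config import ConfigError, RunConfig, log
from .flow import JetSpec, Waveform, duct_following_field, waveform_factor
from .geometry import (
    FlowGrid,
    NasalSurrogateParams,
    SurfaceMesh,
    build_bend,
    build_duct,
    build_nasal_surrogate,
    voxelize,
)
from .io import grid_fields_to_vtk, write_patch_json, write_stl, write_vtk_point_cloud, write_vtk_polydata_mesh
from .metrics import DepositionReport, build_report, de_curve, ratio_metrics
from .scalar import (
    VentilationReport,
    advance_scalar,
    iso_volume_fraction,
    region_flow_fraction,
    region_mean_C,
    scalar_stable_dt,
)
from .transport import DEPOSITED, InjectionSpec, SimulationResult, run_transport

__all__ = [
    "build_geometry",
    "prepare_grid",
    "make_waveform",
    "set_base_flow",
    "surrogate_region_masks",
    "run_scalar_phase",
    "run_experiment",
    "compare_runs",
    "validate_bend",
    "ExperimentBundle",
]

#: default dorsal valve-jet closure of the surrogate base flow
DEFAULT_JET = JetSpec()


def build_geometry(cfg: RunConfig) -> SurfaceMesh:
    g = cfg.geometry
    if g.kind == "nasal_surrogate":
        params = NasalSurrogateParams(**g.surrogate_overrides)
        return build_nasal_surrogate(params, seed=cfg.run.seed)
    if g.kind == "duct":
        return build_duct(g.radius_m, g.length_m, g.resolution)
    if g.kind == "bend":
        return build_bend(g.radius_m, g.bend_radius_m, g.bend_angle_rad, g.resolution)
    raise ConfigError(f"unknown geometry kind {g.kind!r}")


def prepare_grid(mesh: SurfaceMesh, dx: float) -> FlowGrid:
    return voxelize(mesh, dx)


def make_waveform(cfg: RunConfig, mesh: SurfaceMesh) -> Waveform:
    inlet_area = math.pi * float(mesh.chart.r0[0]) ** 2
    return Waveform(
        mode="sinusoidal" if cfg.flow.mode == "sinusoidal" else "steady",
        Q0=cfg.flow.mean_flow_m3s,
        inlet_area=inlet_area,
        frequency_Hz=cfg.flow.frequency_Hz,
    )


def set_base_flow(
    grid: FlowGrid,
    mesh: SurfaceMesh,
    Q: float,
    mode: str,
    jet: JetSpec | None = DEFAULT_JET,
    profile: str = "parabolic",
) -> None:
    """Prescribe the base velocity field for mean flow Q.

    For the nasal surrogate the base field carries the dorsal valve-jet
    component; its strength is attenuated in pulsatile mode, representing the
    disruption of the post-valve jet by the flow oscillation (see
    docs/methods.md).  The inlet-cell mask for the scalar boundary condition
    is set here as well.
    """
    is_surrogate = "nasopharynx" in mesh.patch_names
    use_jet = jet if is_surrogate else None
    jet_scale = 1.0
    if use_jet is not None and mode == "sinusoidal":
        jet_scale = use_jet.pulsatile_attenuation
    duct_following_field(grid, Q, profile=profile, jet=use_jet, jet_scale=jet_scale)
    if grid.s_cell is not None:
        s_in = 0.6 * float(mesh.chart.s[1] + 0.004)
        inlet = np.zeros(grid.shape, bool)
        inlet[grid.inside] = grid.s_cell[grid.inside] < max(s_in, 2.5 * grid.dx)
        grid.inlet_mask = inlet


# ---------------------------------------------------------------------------
# Region masks on the surrogate grid
# ---------------------------------------------------------------------------


def surrogate_region_masks(grid: FlowGrid, mesh: SurfaceMesh) -> dict[str, np.ndarray]:
    """Volumetric region masks from the chart coordinates.

    Channel regions are arclength windows (the wall-region labels of the
    sweep); the olfactory regions are the near-wall pockets adjacent to the
    labelled dorsal patches (matching arclength window, azimuth within the
    patch's angular extent, outer half of the radius).
    """
    chart = grid.chart
    if chart is None or grid.s_cell is None:
        raise ConfigError("grid lacks chart coordinates; voxelize a swept mesh")
    ins = grid.inside
    s = grid.s_cell
    interval = np.clip(np.searchsorted(chart.s, s[ins]) - 1, 0, len(chart.region_of_interval) - 1)
    labels = np.array(chart.region_of_interval, dtype=object)[interval]
    masks: dict[str, np.ndarray] = {}
    for name in sorted(set(chart.region_of_interval)):
        m = np.zeros(grid.shape, bool)
        m[ins] = labels == name
        masks[name] = m

    # olfactory pockets from the labelled wall patches
    theta = grid.theta_cell
    eta = grid.eta_cell
    for side in ("R", "L"):
        pname = f"olfactory_{side}"
        if pname not in mesh.patch_names:
            continue
        pid = mesh.patch_id(pname)
        sel = mesh.patch_of_triangle == pid
        s_lo, s_hi = mesh.tri_s[sel].min(), mesh.tri_s[sel].max()
        th = np.mod(mesh.tri_theta[sel] + math.pi, 2 * math.pi) - math.pi
        th_max = float(np.abs(th).max())
        wrapped = np.mod(theta + math.pi, 2 * math.pi) - math.pi
        pocket = (
            ins
            & (s >= s_lo)
            & (s <= s_hi)
            & (np.abs(wrapped) <= th_max)
            & (eta >= 0.5)
        )
        masks[pname] = pocket
        if "nasopharynx" in masks:
            masks["nasopharynx"] &= ~pocket
    return masks


# ---------------------------------------------------------------------------
# Scalar phase
# ---------------------------------------------------------------------------


def run_scalar_phase(
    grid: FlowGrid,
    mesh: SurfaceMesh,
    waveform: Waveform,
    t_end: float,
    Q: float,
    eval_time: float | None = None,
    max_lambda_clamp: float = 0.2,
) -> VentilationReport:
    """Integrate the ventilation tracer to ``t_end`` and summarize regions.

    The velocity is the stored base field scaled quasi-steadily by the
    waveform; the step size tracks the instantaneous stability bound (with
    the waveform factor clamped below by ``max_lambda_clamp`` so steps stay
    bounded through the zero-flow phase).
    """
    from .scalar import ScalarIntegrator

    eval_time = t_end if eval_time is None else eval_time
    stepper = ScalarIntegrator(grid)
    base_bound = stepper.base_bound
    t = 0.0
    while t < eval_time:
        lam = float(waveform_factor(waveform, t))
        lam_eff = max(abs(lam), max_lambda_clamp)
        dt = min(base_bound / lam_eff, eval_time - t)
        if waveform.mode == "sinusoidal":
            dt = min(dt, waveform.period / 30.0)
        stepper.step(dt, velocity_scale=lam)
        t += dt

    masks = surrogate_region_masks(grid, mesh)
    report = VentilationReport(time=eval_time)
    for name, m in masks.items():
        if not m.any():
            continue
        report.mean_C[name] = region_mean_C(grid, m)
        report.iso_fraction_05[name] = iso_volume_fraction(grid, m, 0.5)
        report.iso_fraction_099[name] = iso_volume_fraction(grid, m, 0.99)

    # fractional flow through the olfactory pockets (steady base flow)
    for side in ("R", "L"):
        pname = f"olfactory_{side}"
        if pname not in masks or not masks[pname].any():
            continue
        pocket = masks[pname]
        s_mid = float(np.nanmedian(grid.s_cell[pocket]))
        chart = grid.chart
        origin = chart.interp(np.array([s_mid]), chart.points)[0]
        normal = chart.interp(np.array([s_mid]), chart.tangents)[0]
        pocket_flat = pocket

        def _filter(pts: np.ndarray, _pocket=pocket_flat, _grid=grid) -> np.ndarray:
            ijk = np.clip(
                ((pts - _grid.origin) / _grid.dx).astype(np.int64),
                0,
                np.array(_grid.shape) - 1,
            )
            return _pocket[ijk[:, 0], ijk[:, 1], ijk[:, 2]]

        report.flow_fraction_pct[pname] = region_flow_fraction(
            grid, origin, normal, Q, point_filter=_filter
        )
    return report


# ---------------------------------------------------------------------------
# Experiments
# ---------------------------------------------------------------------------


@dataclass
class ExperimentBundle:
    config: RunConfig
    mesh: SurfaceMesh
    grid: FlowGrid
    result: SimulationResult
    deposition: DepositionReport
    ventilation: VentilationReport | None


def run_experiment(
    cfg: RunConfig,
    outdir: str | Path | None = None,
    with_scalar: bool = True,
    write_fields: bool = False,
    mesh: SurfaceMesh | None = None,
    grid: FlowGrid | None = None,
) -> ExperimentBundle:
    """One full delivery experiment under the given configuration.

    Pass a prebuilt ``mesh``/``grid`` to reuse geometry between runs (the
    grid's fields are reset here).  When ``outdir`` is given the artifacts
    (geometry, reports, parcel cloud, manifest) are written there.
    """
    mesh = build_geometry(cfg) if mesh is None else mesh
    grid = prepare_grid(mesh, cfg.geometry.voxel_dx_m) if grid is None else grid
    grid.scalar_c = np.zeros(grid.shape)
    grid.k_sgs = np.zeros(grid.shape)

    waveform = make_waveform(cfg, mesh)
    Q = cfg.flow.mean_flow_m3s
    set_base_flow(grid, mesh, Q, waveform.mode)

    spec = InjectionSpec(
        diameter=cfg.particle.diameter_um * 1e-6,
        density=cfg.particle.density_kg_m3,
        n_parcels=cfg.particle.n_parcels,
        mass_total=cfg.particle.mass_mg * 1e-6,
        duration=cfg.particle.injection_s,
    )
    result = run_transport(
        mesh,
        grid,
        waveform,
        spec,
        t_end=cfg.run.t_end_s,
        courant_max=cfg.run.courant_max,
        seed=cfg.run.seed,
        two_way=cfg.run.two_way,
    )
    areas = {k: v for k, v in mesh.patch_areas().items()}
    deposition = build_report(result, areas)

    ventilation = None
    if with_scalar and "nasopharynx" in mesh.patch_names:
        ventilation = run_scalar_phase(grid, mesh, waveform, cfg.run.t_end_s, Q)

    if grid.k_sgs.any():
        # subgrid energy present (user-supplied or advanced externally):
        # summarize it; a resolution index additionally needs a resolved-TKE
        # window (sgs.resolved_tke over velocity snapshots)
        ks = grid.k_sgs[grid.inside]
        log.info("k_sgs summary: max %.3e, mean %.3e m^2/s^2", ks.max(), ks.mean())

    log.info(
        "run[%s seed=%d digest=%s]: total DE %.4g%%, mass balance %.2e",
        waveform.mode,
        cfg.run.seed,
        cfg.digest(),
        deposition.de_pct["total"],
        deposition.mass_balance_residual,
    )

    if outdir is not None:
        _write_bundle(Path(outdir), cfg, mesh, grid, result, deposition, ventilation, write_fields)
    return ExperimentBundle(cfg, mesh, grid, result, deposition, ventilation)


def _write_bundle(
    outdir: Path,
    cfg: RunConfig,
    mesh: SurfaceMesh,
    grid: FlowGrid,
    result: SimulationResult,
    deposition: DepositionReport,
    ventilation: VentilationReport | None,
    write_fields: bool,
) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "config.yaml")
    write_stl(mesh, outdir / "surface.stl")
    write_patch_json(mesh, outdir / "patches.json")
    write_vtk_polydata_mesh(mesh, outdir / "surface.vtk")
    deposition.to_csv(outdir / "deposition.csv")
    deposition.to_json(outdir / "deposition.json")
    if ventilation is not None:
        (outdir / "ventilation.json").write_text(json.dumps(ventilation.to_dict(), indent=2))
    dep = result.parcels.status == DEPOSITED
    if dep.any():
        write_vtk_point_cloud(
            result.parcels.x[dep],
            outdir / "deposited_parcels.vtk",
            {
                "diameter_m": result.parcels.d[dep],
                "patch_id": result.parcels.deposit_patch[dep].astype(float),
                "deposit_time_s": result.parcels.deposit_time[dep],
            },
        )
    if write_fields:
        grid_fields_to_vtk(grid, outdir / "fields.vtk")
    manifest = {
        "package_version": __version__,
        "python": platform.python_version(),
        "config_digest": cfg.digest(),
        "seed": cfg.run.seed,
        "mass_balance_residual": deposition.mass_balance_residual,
        "two_way_engaged": result.two_way_engaged,
        "volume_fraction": result.volume_fraction,
        "n_steps": result.n_steps,
        "outputs": sorted(p.name for p in outdir.iterdir()),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def compare_runs(a: DepositionReport, b: DepositionReport, path: str | Path | None = None) -> dict:
    table = ratio_metrics(a, b)
    if path is not None:
        Path(path).write_text(json.dumps(table, indent=2, sort_keys=True))
    return table


def validate_bend(
    diameters_um=(1.0, 3.0, 5.0, 10.0, 20.0),
    Q_lpm: float = 15.0,
    tube_radius: float = 0.0025,
    bend_radius: float = 0.0125,
    seed: int = 0,
    n_parcels: int = 2000,
    resolution: int = 48,
    dx: float | None = None,
):
    """DE-vs-impaction-parameter sweep on the 90-degree bend benchmark."""
    mesh = build_bend(tube_radius, bend_radius, math.pi / 2, resolution)
    grid = voxelize(mesh, tube_radius / 8.0 if dx is None else dx)
    return de_curve(mesh, grid, sorted(diameters_um), Q_lpm, seed=seed, n_parcels=n_parcels)
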