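"""Deposition endpoints: regional deposition efficiency (DE), surface dose
per area, right/left and steady/pulsatile ratio tables, impaction-parameter
curves and mass-balance audits.

Conventions: DE is a percentage of the injected mass; dose per area is
reported in ng/mm^2 (100 % drug loading assumed); the impaction parameter is
IP = d^2 Q in um^2 L/min, the classical correlating variable of nasal
deposition.  Ratios are printed to three significant figures; a division by
zero yields an infinity marker rather than an error.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import NasopulseError, ParameterError
from .transport import DEPOSITED, SimulationResult

__all__ = [
    "DepositionReport",
    "deposition_efficiency",
    "dose_per_area",
    "ratio_metrics",
    "impaction_parameter",
    "de_curve",
    "mass_balance",
    "build_report",
    "round_sig",
]


def round_sig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures (report display convention)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


# ---------------------------------------------------------------------------
# Core operations
# ---------------------------------------------------------------------------


def deposition_efficiency(
    result: SimulationResult, partition: dict[str, list[str]] | None = None
) -> dict[str, float]:
    """DE per region: 100 x deposited mass in the region / injected mass.

    ``partition`` maps region names to lists of wall patch names; by default
    every wall patch forms its own region (patches already carry their
    anatomical region tags).  The returned table additionally holds
    ``total`` over all wall patches.
    """
    if result.injected_mass <= 0:
        raise ParameterError("injected mass is zero; DE undefined")
    by_patch = result.deposited_mass_by_patch()
    if partition is None:
        partition = {
            name: [name]
            for name, info in result.patch_table.items()
            if info.role == "wall"
        }
    de = {
        region: 100.0 * sum(by_patch.get(p, 0.0) for p in patches) / result.injected_mass
        for region, patches in partition.items()
    }
    wall_patches = [n for n, info in result.patch_table.items() if info.role == "wall"]
    de["total"] = 100.0 * sum(by_patch.get(p, 0.0) for p in wall_patches) / result.injected_mass
    return de


def dose_per_area(
    result: SimulationResult, patch_areas_m2: dict[str, float]
) -> dict[str, float]:
    """Deposited mass per patch area in ng/mm^2."""
    by_patch = result.deposited_mass_by_patch()
    out = {}
    for patch, area in patch_areas_m2.items():
        if result.patch_table[patch].role != "wall":
            continue
        if area <= 0:
            raise ParameterError(f"patch {patch} has non-positive area")
        mass_ng = by_patch.get(patch, 0.0) * 1e12  # kg -> ng
        area_mm2 = area * 1e6
        out[patch] = mass_ng / area_mm2
    return out


def _safe_ratio(a: float, b: float) -> float:
    if b == 0.0:
        return math.inf if a > 0 else (math.nan if a == 0 else -math.inf)
    return a / b


def _side_sums(de: dict[str, float]) -> tuple[float, float]:
    right = sum(v for k, v in de.items() if k.endswith("_R"))
    left = sum(v for k, v in de.items() if k.endswith("_L"))
    return right, left


def ratio_metrics(report_a: "DepositionReport", report_b: "DepositionReport") -> dict:
    """Right/left ratios per report and A/B (e.g. steady/pulsatile) fold
    changes per region.  Division by zero produces an infinity marker."""
    if set(report_a.de_pct) != set(report_b.de_pct):
        raise NasopulseError("reports use different region partitions")
    ra, la = _side_sums(report_a.de_pct)
    rb, lb = _side_sums(report_b.de_pct)
    out = {
        "right_left_cavity_DE_ratio": {
            "a": _safe_ratio(ra, la),
            "b": _safe_ratio(rb, lb),
        },
        "right_left_olfactory_DE_ratio": {
            "a": _safe_ratio(report_a.de_pct.get("olfactory_R", 0.0), report_a.de_pct.get("olfactory_L", 0.0)),
            "b": _safe_ratio(report_b.de_pct.get("olfactory_R", 0.0), report_b.de_pct.get("olfactory_L", 0.0)),
        },
        "fold_change_a_over_b": {
            region: _safe_ratio(report_a.de_pct[region], report_b.de_pct[region])
            for region in report_a.de_pct
        },
        "dose_fold_change_a_over_b": {
            patch: _safe_ratio(report_a.dose_ng_mm2.get(patch, 0.0), report_b.dose_ng_mm2.get(patch, 0.0))
            for patch in report_a.dose_ng_mm2
        },
    }
    return out


def impaction_parameter(d_um: float, Q_lpm: float) -> float:
    """IP = d^2 Q [um^2 L/min]."""
    if d_um <= 0 or Q_lpm <= 0:
        raise ParameterError("diameter and flow must be positive")
    return d_um**2 * Q_lpm


def mass_balance(result: SimulationResult) -> float:
    """|injected - deposited - escaped - airborne| / injected (0 if empty)."""
    if result.injected_mass == 0:
        return 0.0
    resid = result.injected_mass - result.deposited_mass - result.escaped_mass - result.airborne_mass
    return abs(resid) / result.injected_mass


# ---------------------------------------------------------------------------
# DE-vs-IP sweeps
# ---------------------------------------------------------------------------


def de_curve(
    mesh,
    grid,
    diameters_um: list[float],
    Q_lpm: float,
    seed: int = 0,
    n_parcels: int = 2000,
    t_end: float | None = None,
    gravity=(0.0, 0.0, -9.81),
    profile: str = "parabolic",
) -> pd.DataFrame:
    """Total DE versus impaction parameter over a diameter sweep.

    One steady-flow simulation per diameter at fixed flow and seed; DE is
    expected to grow monotonically with IP = d^2 Q on impaction-dominated
    geometries (bends, the nasal surrogate).
    """
    from .config import lpm_to_m3s
    from .flow import Waveform, duct_following_field
    from .transport import InjectionSpec, WallCollider, run_transport

    if list(diameters_um) != sorted(diameters_um):
        raise ParameterError("diameters must be sorted ascending")
    Q = lpm_to_m3s(Q_lpm)
    duct_following_field(grid, Q, profile=profile)
    inlet_area = math.pi * float(mesh.chart.r0[0]) ** 2
    w = Waveform(mode="steady", Q0=Q, inlet_area=inlet_area)
    injection_s = 0.02
    if t_end is None:
        # injection window plus a generous transit allowance at the mean speed
        t_end = injection_s + 5.0 * mesh.chart.length / (
            Q / mesh.chart.section_area(np.array([0.0]))[0]
        )
    collider = WallCollider(mesh, grid)
    rows = []
    for d_um in diameters_um:
        spec = InjectionSpec(
            diameter=d_um * 1e-6,
            n_parcels=n_parcels,
            mass_total=2.5e-6,
            duration=injection_s,
        )
        res = run_transport(
            mesh, grid, w, spec, t_end=t_end, seed=seed, gravity=gravity, collider=collider
        )
        de = deposition_efficiency(res)
        rows.append(
            {
                "diameter_um": d_um,
                "IP_um2_lpm": impaction_parameter(d_um, Q_lpm),
                "DE_total_pct": de["total"],
                "escaped_pct": 100.0 * res.escaped_mass / res.injected_mass,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Report container
# ---------------------------------------------------------------------------


@dataclass
class DepositionReport:
    """Per-region deposition summary of one run."""

    injected_mg: float
    deposited_mg: dict[str, float]  # per region
    de_pct: dict[str, float]  # per region (+ "total")
    dose_ng_mm2: dict[str, float]  # per wall patch
    escaped_mg: float
    airborne_mg: float
    mass_balance_residual: float
    impaction_parameter: float
    waveform_mode: str
    seed: int

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for region, de in self.de_pct.items():
            rows.append(
                {
                    "region": region,
                    "deposited_mg": self.deposited_mg.get(region, float("nan")),
                    "DE_pct": de,
                    "dose_ng_per_mm2": self.dose_ng_mm2.get(region, float("nan")),
                }
            )
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.10g")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "injected_mg": self.injected_mg,
            "deposited_mg": self.deposited_mg,
            "DE_pct": self.de_pct,
            "dose_ng_per_mm2": self.dose_ng_mm2,
            "escaped_mg": self.escaped_mg,
            "airborne_mg": self.airborne_mg,
            "mass_balance_residual": self.mass_balance_residual,
            "impaction_parameter_um2_lpm": self.impaction_parameter,
            "waveform_mode": self.waveform_mode,
            "seed": self.seed,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def build_report(result: SimulationResult, patch_areas_m2: dict[str, float]) -> DepositionReport:
    """Assemble the full deposition report for one completed run."""
    de = deposition_efficiency(result)
    by_patch = result.deposited_mass_by_patch()
    deposited_mg = {
        region: by_patch.get(region, 0.0) * 1e6 for region in de if region != "total"
    }
    return DepositionReport(
        injected_mg=result.injected_mass * 1e6,
        deposited_mg=deposited_mg,
        de_pct=de,
        dose_ng_mm2=dose_per_area(result, patch_areas_m2),
        escaped_mg=result.escaped_mass * 1e6,
        airborne_mg=result.airborne_mass * 1e6,
        mass_balance_residual=mass_balance(result),
        impaction_parameter=impaction_parameter(result.diameter * 1e6, result.Q_lpm),
        waveform_mode=result.waveform_mode,
        seed=result.seed,
    )
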