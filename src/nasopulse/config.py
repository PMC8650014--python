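"""Run configuration, physical constants, errors and logging.

All internal quantities are SI (metres, seconds, kilograms); reports convert
to the conventional units of nasal dosimetry (L/min, µm, mg, ng/mm²).
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

log = logging.getLogger("nasopulse")

# ---------------------------------------------------------------------------
# Physical constants (room-temperature air; configurable per run)
# ---------------------------------------------------------------------------

#: kinematic viscosity of air [m^2/s]
NU_AIR = 1.5e-5
#: dynamic viscosity of air [Pa s]
MU_AIR = 1.8e-5
#: density of air [kg/m^3]
RHO_AIR = 1.2
#: gravitational acceleration magnitude [m/s^2]
G_STANDARD = 9.81

#: particle volume fraction above which two-way momentum coupling is engaged
TWO_WAY_VOLUME_FRACTION_THRESHOLD = 1e-6

L_PER_MIN = 1e-3 / 60.0  # m^3/s per L/min


def lpm_to_m3s(q_lpm: float) -> float:
    """Convert a volumetric flow from L/min to m^3/s."""
    return q_lpm * L_PER_MIN


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------


class NasopulseError(Exception):
    """Base class for package errors."""


class ParameterError(NasopulseError):
    """A geometric or physical parameter is out of its admissible range."""


class ResolutionError(NasopulseError):
    """A grid is too coarse for the geometry it is asked to resolve."""


class StabilityError(NasopulseError):
    """An explicit time step violates its stability bound."""


class OutOfDomainError(NasopulseError):
    """A sample point lies outside the grid bounding box."""


class GeometryError(NasopulseError):
    """A mesh fails a structural requirement (watertightness, empty patch...)."""


class ConfigError(NasopulseError):
    """A run configuration is malformed (unknown keys, bad values)."""


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class GeometrySpec:
    """Which synthetic geometry to build and at what scale."""

    kind: str = "nasal_surrogate"  # nasal_surrogate | duct | bend
    # duct / bend parameters (metres, radians)
    radius_m: float = 0.005
    length_m: float = 0.1
    bend_radius_m: float = 0.0125
    bend_angle_rad: float = math.pi / 2
    resolution: int = 64
    # surrogate resolution knobs (detailed shape parameters live with the builder)
    surrogate_overrides: dict = field(default_factory=dict)
    voxel_dx_m: float = 8e-4


@dataclass
class FlowSpec:
    mean_L_per_min: float = 4.0
    mode: str = "steady"  # steady | sinusoidal
    frequency_Hz: float = 45.0

    @property
    def mean_flow_m3s(self) -> float:
        return lpm_to_m3s(self.mean_L_per_min)


@dataclass
class ParticleSpec:
    diameter_um: float = 1.0
    density_kg_m3: float = 1000.0
    n_parcels: int = 10_000
    mass_mg: float = 2.5
    injection_s: float = 0.5


@dataclass
class RunSpec:
    t_end_s: float = 1.98
    courant_max: float = 0.9
    seed: int = 0
    two_way: bool = True


@dataclass
class RunConfig:
    """Complete description of one delivery experiment.

    The defaults reproduce the reference setup: 1 µm aerosol, 4 L/min mean
    bi-directional flow, 45 Hz pulsation when ``flow.mode == "sinusoidal"``,
    2.5 mg injected over 0.5 s, simulated to 1.98 s.
    """

    geometry: GeometrySpec = field(default_factory=GeometrySpec)
    flow: FlowSpec = field(default_factory=FlowSpec)
    particle: ParticleSpec = field(default_factory=ParticleSpec)
    run: RunSpec = field(default_factory=RunSpec)
    output_dir: str = "runs/run0"

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        kwargs: dict[str, Any] = {}
        sections = {
            "geometry": GeometrySpec,
            "flow": FlowSpec,
            "particle": ParticleSpec,
            "run": RunSpec,
        }
        for key, typ in sections.items():
            if key in d:
                sub = d.pop(key)
                _check_keys(sub, typ, key)
                kwargs[key] = typ(**sub)
        if "output_dir" in d:
            kwargs["output_dir"] = d.pop("output_dir")
        if d:
            raise ConfigError(f"unknown config keys: {sorted(d)}")
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} does not hold a mapping")
        return cls.from_dict(data)

    def digest(self) -> str:
        """Short stable hash of the configuration, logged with every run."""
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]


def _check_keys(sub: dict, typ: type, section: str) -> None:
    if not isinstance(sub, dict):
        raise ConfigError(f"config section '{section}' must be a mapping")
    allowed = {f.name for f in dataclasses.fields(typ)}
    unknown = set(sub) - allowed
    if unknown:
        raise ConfigError(f"unknown keys in '{section}': {sorted(unknown)}")


def setup_logging(level: int = logging.INFO) -> None:
    """Attach a console handler if the package logger has none."""
    if not log.handlers:
        h = logging.StreamHandler()
        h.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
        log.addHandler(h)
    log.setLevel(level)
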