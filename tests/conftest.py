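"""Shared fixtures: geometries and grids are built once per session."""

import math

import numpy as np
import pytest

from nasopulse.geometry import (
    build_bend,
    build_duct,
    build_nasal_surrogate,
    voxelize,
)


@pytest.fixture(scope="session")
def duct_mesh():
    return build_duct(radius=0.005, length=0.1, resolution=64)


@pytest.fixture(scope="session")
def duct_grid(duct_mesh):
    return voxelize(duct_mesh, 0.000625)  # dx = R/8


@pytest.fixture(scope="session")
def short_duct():
    """Small duct + grid for fast transport tests."""
    mesh = build_duct(radius=0.005, length=0.05, resolution=48)
    grid = voxelize(mesh, 0.000625)
    return mesh, grid


@pytest.fixture(scope="session")
def bend_mesh():
    return build_bend(tube_radius=0.0025, bend_radius=0.0125, angle=math.pi / 2, resolution=48)


@pytest.fixture(scope="session")
def bend_grid(bend_mesh):
    return voxelize(bend_mesh, 0.0025 / 8.0)


@pytest.fixture(scope="session")
def surrogate_mesh():
    return build_nasal_surrogate()


@pytest.fixture(scope="session")
def surrogate_grid(surrogate_mesh):
    return voxelize(surrogate_mesh, 0.0008)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
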