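"""Shared fixtures: analytic meshes, voxel phantoms, and small cohorts.

Expensive geometry (voxel sphere extraction, curvature fields, cohorts) is
session-scoped; everything is generated programmatically so the repository
carries no data files.
"""

from __future__ import annotations

import numpy as np
import pytest

from gaussmap.analytic import cylinder, icosphere, torus
from gaussmap.curvature import compute_curvature
from gaussmap.mask_io import VoxelMask
from gaussmap.phantoms import make_cohort
from gaussmap.surface import extract_surface


def voxel_sphere_mask(radius: float, spacing: float = 1.0) -> VoxelMask:
    """Digitized solid sphere on an isotropic grid."""
    n = int(np.ceil(2 * radius / spacing)) + 9
    c = (n - 1) / 2
    idx = np.indices((n, n, n))
    d2 = ((idx - c) ** 2).sum(axis=0) * spacing ** 2
    grid = (d2 <= radius ** 2).astype(np.uint8)
    return VoxelMask(grid=grid, affine=np.diag([spacing] * 3 + [1.0]))


@pytest.fixture(scope="session")
def unit_icosphere():
    return icosphere(radius=1.0, subdivisions=4)


@pytest.fixture(scope="session")
def unit_icosphere_field(unit_icosphere):
    return compute_curvature(unit_icosphere)


@pytest.fixture(scope="session")
def sphere20_mesh():
    """Smoothed marching-cubes surface of a radius-20-voxel sphere."""
    return extract_surface(voxel_sphere_mask(20.0))


@pytest.fixture(scope="session")
def sphere20_field(sphere20_mesh):
    return compute_curvature(sphere20_mesh)


@pytest.fixture(scope="session")
def cylinder_mesh():
    return cylinder(radius=2.0, height=10.0)


@pytest.fixture(scope="session")
def torus_mesh():
    return torus(major_radius=10.0, minor_radius=3.0)


@pytest.fixture(scope="session")
def tiny_cohort(tmp_path_factory):
    """5 subjects/class at 1.5 mm voxels: fast, for plumbing tests."""
    out = tmp_path_factory.mktemp("tiny_cohort")
    manifest = make_cohort(out, n_per_class=5, seed=9, spacing=(1.5, 1.5, 1.5))
    return manifest


@pytest.fixture(scope="session")
def default_cohort(tmp_path_factory):
    """The default phantom cohort: 20 subjects/class at 1 mm voxels."""
    out = tmp_path_factory.mktemp("default_cohort")
    return make_cohort(out, n_per_class=20, seed=42)
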