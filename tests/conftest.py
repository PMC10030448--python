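"""Shared fixtures: analytic shapes on 1 mm grids and small phantoms.

Expensive phantom/cohort fixtures are session-scoped so registration and
pipeline tests share them.
"""

from __future__ import annotations

import numpy as np
import pytest

from corseg import (AffineParams, BinaryMask, DeformationSpec, DemonsParams, PhantomSpec,
                    PipelineConfig, RegistrationConfig, StructureGuidedParams, VolumeGrid,
                    generate_atlas_cohort, generate_phantom)


def make_grid(shape=(64, 64, 64), spacing=(1.0, 1.0, 1.0)) -> VolumeGrid:
    return VolumeGrid(np.zeros(shape, dtype=np.uint8), spacing=np.asarray(spacing))


def world_axes(grid: VolumeGrid):
    ax = [grid.origin[a] + grid.spacing[a] * np.arange(grid.shape[a]) for a in range(3)]
    return np.meshgrid(*ax, indexing="ij")


def ellipsoid(grid: VolumeGrid, centre, radii) -> BinaryMask:
    X, Y, Z = world_axes(grid)
    c, r = np.asarray(centre, float), np.asarray(radii, float)
    lvl = ((X - c[0]) / r[0]) ** 2 + ((Y - c[1]) / r[1]) ** 2 + ((Z - c[2]) / r[2]) ** 2
    return BinaryMask.from_array(lvl < 1.0, grid)


def sphere(grid: VolumeGrid, centre, radius) -> BinaryMask:
    return ellipsoid(grid, centre, (radius, radius, radius))


def box(grid: VolumeGrid, lo, hi) -> BinaryMask:
    X, Y, Z = world_axes(grid)
    m = ((X >= lo[0]) & (X < hi[0]) & (Y >= lo[1]) & (Y < hi[1])
         & (Z >= lo[2]) & (Z < hi[2]))
    return BinaryMask.from_array(m, grid)


@pytest.fixture(scope="session")
def grid_1mm() -> VolumeGrid:
    return make_grid((64, 64, 64), (1.0, 1.0, 1.0))


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """Coarse phantom used by registration/pipeline tests."""
    return PhantomSpec(shape=(64, 64, 48), spacing=(3.0, 3.0, 3.0), seed=2)


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return generate_phantom(small_spec)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return generate_atlas_cohort(small_spec, 3, DeformationSpec(seed=7, max_displacement_mm=6.0))


@pytest.fixture(scope="session")
def fast_config() -> PipelineConfig:
    """Reduced multi-resolution schedules for coarse test phantoms."""
    return PipelineConfig(registration=RegistrationConfig(
        affine=AffineParams(shrink_factors=(8, 4)),
        structure_guided=StructureGuidedParams(level_voxel_sizes_mm=(16.0, 8.0),
                                               max_iterations_per_level=30),
        demons=DemonsParams(level_voxel_sizes_mm=(6.0, 4.0), iterations_per_level=(30, 20)),
    ))
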