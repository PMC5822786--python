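"""Shared fixtures: analytic solids rasterized to binary volumes."""

from __future__ import annotations

import numpy as np
import pytest

from amyshape.surface import BinaryVolume


def rasterize(indicator, half_extent: float, voxel_size: float = 1.0) -> BinaryVolume:
    """Digitize ``indicator(x, y, z) -> bool`` on a centred cubic grid."""
    half = int(np.ceil(half_extent / voxel_size))
    c = (np.arange(2 * half + 1) - half) * voxel_size
    x, y, z = np.meshgrid(c, c, c, indexing="ij")
    grid = indicator(x, y, z).astype(np.uint8)
    affine = np.diag([voxel_size] * 3 + [1.0])
    affine[:3, 3] = -half * voxel_size
    return BinaryVolume(grid=grid, affine=affine, side="left")


@pytest.fixture(scope="session")
def sphere_volume_fine() -> BinaryVolume:
    """Sphere of radius 10 mm at 0.25 mm voxels (radial accuracy checks)."""
    return rasterize(lambda x, y, z: x**2 + y**2 + z**2 <= 100.0, 11.0, 0.25)


@pytest.fixture(scope="session")
def sphere_volume_1mm() -> BinaryVolume:
    return rasterize(lambda x, y, z: x**2 + y**2 + z**2 <= 100.0, 12.0, 1.0)


@pytest.fixture(scope="session")
def ellipsoid_volume() -> BinaryVolume:
    """Ellipsoid with semi-axes (12, 8, 6) mm at 0.5 mm voxels."""
    return rasterize(
        lambda x, y, z: (x / 12) ** 2 + (y / 8) ** 2 + (z / 6) ** 2 <= 1.0, 13.0, 0.5
    )


@pytest.fixture(scope="session")
def directions_1000():
    from amyshape.radial import make_directions

    return make_directions(1000)
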