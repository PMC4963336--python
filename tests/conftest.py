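import numpy as np
import pytest

from bonetrack import EllipsoidVOI, GridGeometry
from bonetrack.phantom import default_phantom
from bonetrack.quant import AcquisitionMeta


@pytest.fixture
def small_grid() -> GridGeometry:
    """16^3 isotropic 2.4 mm grid for brute-force-verifiable tests."""
    return GridGeometry((16, 16, 16), (2.4, 2.4, 2.4))


@pytest.fixture
def simple_meta() -> AcquisitionMeta:
    """Unit-friendly acquisition: no residual, acquisition at injection time."""
    return AcquisitionMeta(
        prepared_activity_mbq=500.0,
        t_prepared_min=0.0,
        residual_activity_mbq=0.0,
        t_residual_min=0.0,
        t_injection_min=0.0,
        t_acquisition_start_min=0.0,
        body_weight_kg=70.0,
        calibration_cps_per_kbq=10.0,
        dwell_time_s=15.0,
    )


@pytest.fixture
def three_lesion_phantom():
    """Default subject with one truly progressive/stable/regressive lesion."""
    return default_phantom(3, (0.5, 0.0, -0.5))


def brute_force_ellipsoid_count(voi: EllipsoidVOI, grid: GridGeometry) -> int:
    """Exhaustive voxel-centre membership count (independent of voi_mask)."""
    count = 0
    for i in range(grid.shape[0]):
        for j in range(grid.shape[1]):
            for k in range(grid.shape[2]):
                x = grid.origin[0] + grid.spacing[0] * i
                y = grid.origin[1] + grid.spacing[1] * j
                z = grid.origin[2] + grid.spacing[2] * k
                q = (
                    ((x - voi.center[0]) / voi.semi_axes[0]) ** 2
                    + ((y - voi.center[1]) / voi.semi_axes[1]) ** 2
                    + ((z - voi.center[2]) / voi.semi_axes[2]) ** 2
                )
                count += q <= 1.0
    return count


def brute_force_sphere_voxels(center_mm, radius_mm, grid: GridGeometry):
    """Exhaustive list of voxel indices whose centres lie in a sphere."""
    out = []
    for i in range(grid.shape[0]):
        for j in range(grid.shape[1]):
            for k in range(grid.shape[2]):
                x = grid.origin[0] + grid.spacing[0] * i
                y = grid.origin[1] + grid.spacing[1] * j
                z = grid.origin[2] + grid.spacing[2] * k
                d2 = (x - center_mm[0]) ** 2 + (y - center_mm[1]) ** 2 + (z - center_mm[2]) ** 2
                if d2 <= radius_mm**2:
                    out.append((i, j, k))
    return out
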