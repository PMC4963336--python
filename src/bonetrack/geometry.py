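"""Voxel-grid geometry and ellipsoidal volumes of interest.

World coordinates are millimetres. A grid is axis-aligned: the centre of
voxel index (i, j, k) sits at ``origin + spacing * (i, j, k)``. Arrays are
stored with shape ``(nx, ny, nz)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class GridGeometry:
    """Axis-aligned voxel grid: shape in voxels, spacing and origin in mm."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("shape, spacing and origin must have 3 entries")
        if any(int(n) < 1 or int(n) != n for n in self.shape):
            raise ValueError(f"all shape entries must be integers >= 1, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"all spacings must be > 0 mm, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres (1 mL = 1000 mm^3)."""
        sx, sy, sz = self.spacing
        return sx * sy * sz / 1000.0

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world-mm affine (diagonal spacing + origin)."""
        aff = np.diag([*self.spacing, 1.0])
        aff[:3, 3] = self.origin
        return aff

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World-mm coordinates of voxel centres, as three broadcastable axes."""
        axes = [
            self.origin[d] + self.spacing[d] * np.arange(self.shape[d])
            for d in range(3)
        ]
        return (
            axes[0][:, None, None],
            axes[1][None, :, None],
            axes[2][None, None, :],
        )

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """World-mm extent of the grid (outer edges of border voxels)."""
        lo = np.asarray(self.origin) - 0.5 * np.asarray(self.spacing)
        hi = lo + np.asarray(self.spacing) * np.asarray(self.shape)
        return lo, hi


@dataclass(frozen=True)
class EllipsoidVOI:
    """Axis-aligned ellipsoidal volume of interest in world mm.

    ``label`` distinguishes metastatic lesions from the healthy-vertebra
    reference region whose SUV_mean normalises uptake ratios; ``region`` is a
    free anatomical tag (skull, rib, lumbar spine, ...).
    """

    voi_id: str
    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    label: str = "lesion"
    region: str = ""

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semi_axes):
            raise ValueError(f"VOI {self.voi_id!r}: semi-axes must be > 0 mm")
        if self.label not in ("lesion", "reference"):
            raise ValueError(f"VOI {self.voi_id!r}: label must be 'lesion' or 'reference'")
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))
        object.__setattr__(self, "semi_axes", tuple(float(a) for a in self.semi_axes))

    def inside_grid(self, grid: GridGeometry) -> bool:
        """Whether the ellipsoid's bounding box lies fully inside the grid."""
        lo, hi = grid.bounds()
        c = np.asarray(self.center)
        a = np.asarray(self.semi_axes)
        return bool(np.all(c - a >= lo) and np.all(c + a <= hi))


def voi_mask(voi: EllipsoidVOI, grid: GridGeometry) -> np.ndarray:
    """Boolean mask of voxels whose centres fall inside the ellipsoid.

    Membership is sum(((x_i - c_i) / a_i)^2) <= 1 evaluated at voxel centres
    in world mm; no partial-volume weighting.

    Raises ``ValueError`` if no voxel centre is inside the VOI.
    """
    x, y, z = grid.voxel_centers()
    cx, cy, cz = voi.center
    ax, ay, az = voi.semi_axes
    q = ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2
    mask = q <= 1.0
    if not mask.any():
        raise ValueError(f"VOI {voi.voi_id!r} contains no voxel centers")
    return mask


def sphere_mask(
    center_mm: tuple[float, float, float], radius_mm: float, grid: GridGeometry
) -> np.ndarray:
    """Boolean mask of voxel centres within ``radius_mm`` of a world point."""
    x, y, z = grid.voxel_centers()
    d2 = (x - center_mm[0]) ** 2 + (y - center_mm[1]) ** 2 + (z - center_mm[2]) ** 2
    return d2 <= radius_mm**2
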