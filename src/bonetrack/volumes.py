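"""Typed voxel volumes (counts, activity concentration, SUV) with NIfTI I/O."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .geometry import GridGeometry

UNITS = ("counts", "kBq/mL", "SUV")


@dataclass
class VoxelVolume:
    """A 3-D voxel grid with a physical unit tag.

    ``unit`` is one of ``counts`` (detected events per voxel over the
    acquisition), ``kBq/mL`` (activity concentration, referenced to injection
    time unless stated otherwise), or ``SUV`` (dimensionless uptake).
    """

    data: np.ndarray
    grid: GridGeometry
    unit: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != tuple(self.grid.shape):
            raise ValueError(
                f"data shape {self.data.shape} != grid shape {self.grid.shape}"
            )
        if self.unit not in UNITS:
            raise ValueError(f"unit must be one of {UNITS}, got {self.unit!r}")
        if np.any(self.data < 0):
            raise ValueError(f"{self.unit} volume contains negative voxels")

    def with_data(self, data: np.ndarray, unit: str | None = None) -> "VoxelVolume":
        return VoxelVolume(data, self.grid, unit if unit is not None else self.unit)


def count_volume(data: np.ndarray, grid: GridGeometry) -> VoxelVolume:
    return VoxelVolume(data, grid, "counts")


def concentration_volume(data: np.ndarray, grid: GridGeometry) -> VoxelVolume:
    return VoxelVolume(data, grid, "kBq/mL")


def suv_volume(data: np.ndarray, grid: GridGeometry) -> VoxelVolume:
    return VoxelVolume(data, grid, "SUV")


def write_nifti(volume: VoxelVolume, path: str | Path) -> None:
    """Write a volume as NIfTI; spacing and origin go into the affine."""
    img = nib.Nifti1Image(volume.data.astype(np.float64), volume.grid.affine)
    img.header.set_xyzt_units(xyz="mm")
    # stash the unit tag in the (free-text) description field
    img.header["descrip"] = volume.unit.encode()
    nib.save(img, str(path))


def read_nifti(path: str | Path, unit: str | None = None) -> VoxelVolume:
    """Read a NIfTI volume written by :func:`write_nifti`.

    The grid is recovered from the affine, which must be axis-aligned
    (diagonal with positive spacing). ``unit`` overrides the tag stored in
    the header description.
    """
    img = nib.load(str(path))
    aff = img.affine
    off_diag = aff[:3, :3] - np.diag(np.diag(aff[:3, :3]))
    if np.any(np.abs(off_diag) > 1e-9):
        raise ValueError(f"{path}: affine is not axis-aligned")
    spacing = np.diag(aff[:3, :3])
    if np.any(spacing <= 0):
        raise ValueError(f"{path}: non-positive voxel spacing in affine")
    data = np.asarray(img.dataobj, dtype=float)
    grid = GridGeometry(tuple(data.shape), tuple(spacing), tuple(aff[:3, 3]))
    if unit is None:
        raw = img.header["descrip"].item()
        unit = raw.decode() if isinstance(raw, bytes) else str(raw)
        if unit not in UNITS:
            raise ValueError(
                f"{path}: no unit tag in header; pass unit= explicitly"
            )
    return VoxelVolume(data, grid, unit)
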