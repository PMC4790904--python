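"""Voxel grids, scalar maps and binary masks.

Every volume in the package lives on a :class:`VolumeGrid`: a regular 3-D
lattice with a fixed voxel size (mm per axis) and the mm coordinate of the
center of voxel ``(0, 0, 0)``.  The grid owns the voxel-index <-> mm mapping
and the NIfTI affine, so maps and masks only carry a data array plus a
reference to their grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VolumeGrid", "ScalarMap", "ROIMask", "GridMismatchError"]


class GridMismatchError(ValueError):
    """Two volumes that must share a grid do not."""


@dataclass(frozen=True)
class VolumeGrid:
    """A common-space voxel lattice.

    Parameters
    ----------
    shape : tuple of int
        Voxels per axis; all entries >= 1.
    voxel_size : tuple of float
        mm per axis; all entries > 0.  Default 3 mm isotropic, the standard
        normalized-space resolution for task fMRI.
    origin_mm : tuple of float
        mm coordinates of the center of voxel ``(0, 0, 0)``.
    """

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float] = (3.0, 3.0, 3.0)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "voxel_size", tuple(float(v) for v in self.voxel_size))
        object.__setattr__(self, "origin_mm", tuple(float(v) for v in self.origin_mm))
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise ValueError(f"shape must be 3 positive integers, got {self.shape}")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel sizes must be > 0, got {self.voxel_size}")

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> mm affine (diagonal, NIfTI convention)."""
        aff = np.diag(list(self.voxel_size) + [1.0])
        aff[:3, 3] = self.origin_mm
        return aff

    def ijk_to_mm(self, ijk) -> np.ndarray:
        ijk = np.asarray(ijk, dtype=float)
        return ijk * np.asarray(self.voxel_size) + np.asarray(self.origin_mm)

    def mm_to_ijk(self, mm, round: bool = False) -> np.ndarray:
        mm = np.asarray(mm, dtype=float)
        ijk = (mm - np.asarray(self.origin_mm)) / np.asarray(self.voxel_size)
        if round:
            ijk = np.rint(ijk).astype(int)
        return ijk

    def clip_ijk(self, ijk) -> np.ndarray:
        """Clip an integer voxel index into the grid (used for jittered peaks)."""
        ijk = np.asarray(ijk, dtype=int)
        return np.clip(ijk, 0, np.asarray(self.shape) - 1)

    def contains_mm(self, mm) -> bool:
        """True if ``mm`` rounds to a voxel inside the grid."""
        ijk = self.mm_to_ijk(mm, round=True)
        return bool(np.all(ijk >= 0) and np.all(ijk < np.asarray(self.shape)))

    def voxel_centers_mm(self) -> np.ndarray:
        """(nx, ny, nz, 3) array of voxel-center mm coordinates."""
        axes = [
            np.arange(n) * v + o
            for n, v, o in zip(self.shape, self.voxel_size, self.origin_mm)
        ]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        return np.stack([gx, gy, gz], axis=-1)

    @classmethod
    def from_affine(cls, affine: np.ndarray, shape) -> "VolumeGrid":
        """Build a grid from a diagonal NIfTI affine."""
        affine = np.asarray(affine, dtype=float)
        rot = affine[:3, :3]
        if not np.allclose(rot, np.diag(np.diag(rot))):
            raise ValueError("only axis-aligned (diagonal) affines are supported")
        return cls(
            shape=tuple(shape[:3]),
            voxel_size=tuple(np.abs(np.diag(rot))),
            origin_mm=tuple(affine[:3, 3]),
        )


def _check_shape(grid: VolumeGrid, data: np.ndarray) -> None:
    if tuple(data.shape[:3]) != grid.shape:
        raise GridMismatchError(
            f"data shape {data.shape[:3]} does not match grid shape {grid.shape}"
        )


@dataclass
class ScalarMap:
    """One floating-point value per voxel; NaN marks missing."""

    grid: VolumeGrid
    data: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        _check_shape(self.grid, self.data)

    def same_grid(self, other) -> bool:
        return self.grid == other.grid


@dataclass
class ROIMask:
    """A boolean voxel set on a grid.

    ``allow_empty`` flags masks that are legitimately empty (e.g. a
    thresholding result); constructing an empty mask without the flag raises.
    """

    grid: VolumeGrid
    data: np.ndarray = field(repr=False)
    allow_empty: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        _check_shape(self.grid, self.data)
        if not self.allow_empty and not self.data.any():
            raise ValueError("ROI mask is empty (pass allow_empty=True if intended)")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def is_empty(self) -> bool:
        return not self.data.any()

    def indices(self) -> np.ndarray:
        """(n, 3) voxel indices of member voxels, in C (lexicographic) order."""
        return np.argwhere(self.data)

    def intersect(self, other: "ROIMask") -> "ROIMask":
        if self.grid != other.grid:
            raise GridMismatchError("cannot intersect masks on different grids")
        return ROIMask(self.grid, self.data & other.data, allow_empty=True)
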