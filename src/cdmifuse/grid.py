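"""Sampling grids and volumes.

All volumes in this package are plain ``numpy`` arrays in ``(x, y, z)`` axis
order, paired with a :class:`GridSpec` that places them in a world coordinate
frame measured in millimetres.  Only axis-aligned (diagonal-affine) grids are
supported: every image this package produces or consumes lives on such a grid,
and the NIfTI affines written by :mod:`cdmifuse.nifti` are diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = ["GridSpec", "Volume", "ValidationError", "GeometryError"]


class ValidationError(ValueError):
    """Raised when inputs violate a documented contract."""


class GeometryError(ValidationError):
    """Raised when an object does not fit the grid it is built on."""


def _triple(v, name, cast):
    t = tuple(cast(x) for x in v)
    if len(t) != 3:
        raise ValidationError(f"{name} must have 3 components, got {v!r}")
    return t


@dataclass(frozen=True)
class GridSpec:
    """A regular 3D sampling grid.

    Parameters
    ----------
    shape
        Number of voxels along (x, y, z); each component must be >= 8.
    spacing
        Voxel size in mm along each axis (> 0).  For clinical-style DWI
        sampling the spacing along ``slice_axis`` is the slice *distance*
        (centre-to-centre); the slice *thickness* is a property of the
        acquisition, not of the grid.
    origin
        World coordinate (mm) of voxel index (0, 0, 0).
    phase_encode_axis
        Axis along which EPI susceptibility distortion acts (default y).
    slice_axis
        Through-plane axis of 2D-acquired stacks (default z).
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    phase_encode_axis: int = 1
    slice_axis: int = 2

    def __post_init__(self):
        object.__setattr__(self, "shape", _triple(self.shape, "shape", int))
        object.__setattr__(self, "spacing", _triple(self.spacing, "spacing", float))
        object.__setattr__(self, "origin", _triple(self.origin, "origin", float))
        if any(s < 8 for s in self.shape):
            raise ValidationError(f"grid shape components must be >= 8, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValidationError(f"grid spacing must be positive, got {self.spacing}")
        for ax in (self.phase_encode_axis, self.slice_axis):
            if ax not in (0, 1, 2):
                raise ValidationError("axes must be in {0, 1, 2}")
        if self.phase_encode_axis == self.slice_axis:
            raise ValidationError("phase_encode_axis and slice_axis must be distinct")

    # ------------------------------------------------------------------ #
    @classmethod
    def centered(
        cls,
        shape: Sequence[int],
        spacing: Sequence[float],
        phase_encode_axis: int = 1,
        slice_axis: int = 2,
    ) -> "GridSpec":
        """Grid whose world origin sits at the centre of the field of view."""
        shape = _triple(shape, "shape", int)
        spacing = _triple(spacing, "spacing", float)
        origin = tuple(-(n - 1) * h / 2.0 for n, h in zip(shape, spacing))
        return cls(shape, spacing, origin, phase_encode_axis, slice_axis)

    # ------------------------------------------------------------------ #
    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world-mm affine (diagonal)."""
        A = np.eye(4)
        A[0, 0], A[1, 1], A[2, 2] = self.spacing
        A[:3, 3] = self.origin
        return A

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    @property
    def extent(self) -> tuple[float, float, float]:
        """Physical field-of-view size in mm (shape * spacing)."""
        return tuple(n * h for n, h in zip(self.shape, self.spacing))

    @property
    def center(self) -> np.ndarray:
        """World coordinate of the centre of the field of view."""
        return np.asarray(self.origin) + (np.asarray(self.shape) - 1) * np.asarray(self.spacing) / 2.0

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centres along one axis."""
        return self.origin[axis] + np.arange(self.shape[axis]) * self.spacing[axis]

    def world_mesh(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Sparse (broadcastable) meshgrid of world coordinates."""
        return np.meshgrid(*(self.axis_coords(a) for a in range(3)), indexing="ij", sparse=True)

    def world_to_voxel(self, pts: np.ndarray) -> np.ndarray:
        """Map world coordinates (..., 3) to fractional voxel indices."""
        return (np.asarray(pts, float) - np.asarray(self.origin)) / np.asarray(self.spacing)

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        return np.asarray(idx, float) * np.asarray(self.spacing) + np.asarray(self.origin)

    def with_shape(self, shape) -> "GridSpec":
        return replace(self, shape=_triple(shape, "shape", int))

    def compatible_with(self, other: "GridSpec", atol: float = 1e-6) -> bool:
        """Same sampling lattice (shape, spacing and origin)."""
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )


@dataclass
class Volume:
    """A scalar volume bound to its grid."""

    data: np.ndarray
    grid: GridSpec

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.shape != tuple(self.grid.shape):
            raise ValidationError(
                f"volume shape {self.data.shape} does not match grid shape {self.grid.shape}"
            )

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.grid)
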