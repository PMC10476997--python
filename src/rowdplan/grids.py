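"""Axis-aligned 3-D scalar fields (dose, LET_d, pO2, masks).

A :class:`VoxelGrid` stores a scalar value per voxel on a regular grid.
Coordinates are in millimetres, axis convention RAS, with ``origin`` at the
centre of the first voxel. All grids participating in one calculation must be
aligned (same dims, spacing and origin); misalignment raises
:class:`~rowdplan.errors.AlignmentError` rather than silently resampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AlignmentError, ConfigurationError

__all__ = ["VoxelGrid"]


@dataclass
class VoxelGrid:
    """A 3-D scalar field on a regular axis-aligned grid.

    Parameters
    ----------
    values
        Array of shape ``(nx, ny, nz)``.
    spacing
        Voxel size per axis in mm, all strictly positive.
    origin
        World coordinate (mm) of the centre of voxel ``(0, 0, 0)``.
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ConfigurationError(f"grid values must be 3-D, got ndim={self.values.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or len(self.origin) != 3:
            raise ConfigurationError("spacing and origin must have three components")
        if any(s <= 0 for s in self.spacing):
            raise ConfigurationError(f"spacing must be positive, got {self.spacing}")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        return int(self.values.size)

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates (mm) of voxel centres along one axis."""
        n = self.dims[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)

    def like(self, values: np.ndarray) -> "VoxelGrid":
        """A new grid with the same geometry and the given values."""
        values = np.asarray(values)
        if values.shape != self.values.shape:
            values = values.reshape(self.values.shape)
        return VoxelGrid(values, self.spacing, self.origin)

    def same_geometry(self, other: "VoxelGrid") -> bool:
        return (
            self.dims == other.dims
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def assert_aligned(self, *others: "VoxelGrid") -> None:
        for other in others:
            if not self.same_geometry(other):
                raise AlignmentError(
                    f"grids are not aligned: {self.dims}/{self.spacing}/{self.origin} vs "
                    f"{other.dims}/{other.spacing}/{other.origin}"
                )

    def flat(self) -> np.ndarray:
        """Values flattened in C order (the voxel index used by influence data)."""
        return self.values.reshape(-1)
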