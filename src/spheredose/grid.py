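"""Voxel-grid geometry and the shared volumetric container.

Conventions, used everywhere in the package:

* indices are 0-based, ``(i, j, k)`` maps to world coordinates (mm) via
  ``world = index * spacing + origin``, i.e. the origin is the world
  coordinate of the *center* of voxel ``(0, 0, 0)``;
* each voxel owns the half-open cube
  ``[center - spacing/2, center + spacing/2)`` along every axis;
* physical units are fixed at the interface: lengths in mm, activities in
  GBq, absorbed dose in Gy, times in hours.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

#: unit tags a Volume may carry
VALID_UNITS = ("intensity", "gbq", "gy", "label", "decays")


@dataclass(frozen=True)
class VoxelGrid:
    """Geometry of a regular 3-D voxel grid (shape, spacing, origin; mm)."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        shape = tuple(int(s) for s in self.shape)
        spacing = tuple(float(s) for s in self.spacing)
        origin = tuple(float(o) for o in self.origin)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise ValueError(f"shape must be 3 positive integers, got {self.shape}")
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be 3 positive lengths (mm), got {self.spacing}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    # -- derived geometry ------------------------------------------------
    @property
    def isotropic(self) -> bool:
        s = self.spacing
        return abs(s[0] - s[1]) < 1e-9 and abs(s[1] - s[2]) < 1e-9

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def voxel_mass_kg(self, density_g_per_ml: float) -> float:
        """Mass of one voxel for a uniform medium (1 mm^3 == 1e-3 mL)."""
        return self.voxel_volume_mm3 * 1e-3 * density_g_per_ml * 1e-3

    def world_to_index(self, xyz_mm: np.ndarray) -> np.ndarray:
        """Fractional (float) voxel indices of world points, shape (..., 3)."""
        xyz = np.asarray(xyz_mm, dtype=float)
        return (xyz - np.asarray(self.origin)) / np.asarray(self.spacing)

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        return np.asarray(idx, dtype=float) * np.asarray(self.spacing) + np.asarray(self.origin)

    def voxel_of(self, xyz_mm: np.ndarray) -> np.ndarray:
        """Integer voxel owning each world point (half-open ownership)."""
        return np.floor(self.world_to_index(xyz_mm) + 0.5).astype(np.int64)

    def contains(self, xyz_mm: np.ndarray) -> np.ndarray:
        """Whether each world point falls inside some voxel of the grid."""
        v = self.voxel_of(xyz_mm)
        shape = np.asarray(self.shape)
        return np.all((v >= 0) & (v < shape), axis=-1)

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centers along one axis."""
        return np.arange(self.shape[axis]) * self.spacing[axis] + self.origin[axis]


@dataclass
class Volume:
    """A 3-D scalar field (intensity, activity, dose or labels) on a grid."""

    grid: VoxelGrid
    data: np.ndarray
    unit: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.shape != tuple(self.grid.shape):
            raise ValueError(
                f"data shape {self.data.shape} does not match grid shape {self.grid.shape}"
            )
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unknown unit tag {self.unit!r}; expected one of {VALID_UNITS}")
        if self.unit == "label" and not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("label volumes must be integer-valued")

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.grid.spacing

    def copy_with(self, data: np.ndarray, unit: str | None = None, **prov) -> "Volume":
        p = dict(self.provenance)
        p.update(prov)
        return Volume(self.grid, data, unit or self.unit, p)


def make_grid(shape: Iterable[int], spacing_mm: float | Iterable[float],
              origin_mm: Iterable[float] = (0.0, 0.0, 0.0)) -> VoxelGrid:
    """Convenience constructor accepting a scalar isotropic spacing."""
    if np.isscalar(spacing_mm):
        spacing = (float(spacing_mm),) * 3
    else:
        spacing = tuple(float(s) for s in spacing_mm)
    return VoxelGrid(tuple(int(s) for s in shape), spacing, tuple(float(o) for o in origin_mm))
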