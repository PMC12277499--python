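"""Voxel lattices and regions in patient space.

All geometry lives in the DICOM patient coordinate system (LPS, millimetres).
Array values are indexed ``[i, j, k]`` along the grid axes, i.e. ``values.shape
== grid.dims == (nx, ny, nz)``; the physical position of a voxel *center* is

    p = origin + D @ (spacing * index)

with ``D`` the 3x3 direction-cosine matrix whose columns are the axis
directions (identity for an axis-aligned scan).  Voxel indices are 0-based.
Two volumes share a grid iff every grid field compares equal by value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VolumeGrid",
    "ScalarVolume",
    "BinaryMask",
    "SphericalVoi",
    "RigidTransform",
    "grids_equal",
]


def grids_equal(a: "VolumeGrid", b: "VolumeGrid", tol: float = 1e-6) -> bool:
    """Value equality of two grids, tolerating float round-trip error ≤ ``tol`` mm."""
    return (
        a.dims == b.dims
        and np.allclose(a.spacing, b.spacing, atol=tol)
        and np.allclose(a.origin, b.origin, atol=tol)
        and np.allclose(a.orientation, b.orientation, atol=tol)
    )


@dataclass(frozen=True)
class VolumeGrid:
    """Geometry of a 3D voxel lattice: counts, spacing, origin, orientation."""

    dims: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    #: row-major flattening of the direction matrix D (columns = axis directions)
    orientation: tuple[float, ...] = (1.0, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        if len(self.dims) != 3 or any(int(d) <= 0 for d in self.dims):
            raise ValueError(f"dims must be three positive integers, got {self.dims}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive on all axes, got {self.spacing}")
        D = self.direction
        if not np.allclose(D.T @ D, np.eye(3), atol=1e-6):
            raise ValueError("orientation direction cosines are not orthonormal")
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        object.__setattr__(self, "orientation", tuple(float(o) for o in self.orientation))

    @property
    def direction(self) -> np.ndarray:
        return np.asarray(self.orientation, dtype=float).reshape(3, 3)

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres (1 mL = 1000 mm^3)."""
        return float(np.prod(self.spacing)) / 1000.0

    def index_to_physical(self, index: np.ndarray) -> np.ndarray:
        """Map (continuous) voxel indices, shape (..., 3), to patient-space mm."""
        idx = np.asarray(index, dtype=float)
        return np.asarray(self.origin) + (idx * np.asarray(self.spacing)) @ self.direction.T

    def physical_to_index(self, point: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`index_to_physical`; returns continuous indices."""
        p = np.asarray(point, dtype=float) - np.asarray(self.origin)
        return (p @ self.direction) / np.asarray(self.spacing)

    def voxel_centers(self) -> np.ndarray:
        """Physical centers of every voxel, shape ``dims + (3,)``."""
        idx = np.stack(
            np.meshgrid(*(np.arange(n) for n in self.dims), indexing="ij"), axis=-1
        )
        return self.index_to_physical(idx)

    def extent_corners(self) -> np.ndarray:
        """Physical coordinates of the 8 outer corners of the voxel lattice."""
        lo = np.full(3, -0.5)
        hi = np.asarray(self.dims) - 0.5
        corners = np.array(
            [[a, b, c] for a in (lo[0], hi[0]) for b in (lo[1], hi[1]) for c in (lo[2], hi[2])]
        )
        return self.index_to_physical(corners)

    def contains_point(self, point: np.ndarray) -> bool:
        """Whether a patient-space point falls inside the voxel lattice extent."""
        idx = self.physical_to_index(point)
        return bool(np.all(idx >= -0.5) and np.all(idx <= np.asarray(self.dims) - 0.5))


def _check_shape(values: np.ndarray, grid: VolumeGrid) -> None:
    if tuple(values.shape) != grid.dims:
        raise ValueError(f"values shape {values.shape} does not match grid dims {grid.dims}")


@dataclass
class ScalarVolume:
    """A scalar field on a :class:`VolumeGrid` (raw PET counts, HU, or SUV)."""

    grid: VolumeGrid
    values: np.ndarray
    modality: str = "CT"  # one of {"CT", "PET", "SUV"}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        _check_shape(self.values, self.grid)
        if self.modality not in ("CT", "PET", "SUV"):
            raise ValueError(f"unknown modality {self.modality!r}")


#: A volume whose stored values are body-weight SUV (modality "SUV").
SuvVolume = ScalarVolume


@dataclass
class BinaryMask:
    """A boolean region (organ or lesion) on a grid."""

    grid: VolumeGrid
    voxels: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        _check_shape(self.voxels, self.grid)

    @property
    def voxel_count(self) -> int:
        return int(self.voxels.sum())

    @property
    def volume_ml(self) -> float:
        return self.voxel_count * self.grid.voxel_volume_ml


@dataclass(frozen=True)
class SphericalVoi:
    """Fixed-radius spherical volume of interest; default radius 12 mm (1.2 cm)."""

    center: tuple[float, float, float]
    radius: float = 12.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("sphere radius must be positive")


@dataclass(frozen=True)
class RigidTransform:
    """Rigid map ``p -> R p + t`` in patient space (mm)."""

    rotation: tuple[float, ...] = (1.0, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 1.0)
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        R = self.matrix
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-6):
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation determinant must be +1 (no reflection)")

    @property
    def matrix(self) -> np.ndarray:
        return np.asarray(self.rotation, dtype=float).reshape(3, 3)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.matrix.T + np.asarray(self.translation)
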