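"""Organ-level SUV statistics: whole-organ masks and fixed spherical VOIs.

Two ways of summarizing organ uptake are supported side by side: statistics
over the full organ contour, and statistics over a fixed-radius (default
1.2 cm) sphere placed at the organ centroid — the single-VOI reading common
in clinical workstations.  On organs with focal uptake the two deliberately
disagree; quantifying that gap is the point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .grids import BinaryMask, ScalarVolume, SphericalVoi, VolumeGrid, grids_equal

__all__ = ["RoiStatistics", "mask_centroid", "sphere_voi_mask", "roi_statistics"]


@dataclass(frozen=True)
class RoiStatistics:
    """Summary of SUV over one region."""

    suv_max: float
    suv_mean: float
    max_index: tuple[int, int, int]  # voxel index of the max (lowest linear index on ties)
    max_location_mm: tuple[float, float, float]
    voxel_count: int
    volume_ml: float


def mask_centroid(mask: BinaryMask) -> np.ndarray:
    """Unweighted mean of member-voxel center coordinates (patient-space mm).

    For concave organs the centroid may fall outside the mask; callers that
    place a VOI there get exactly that placement (no snapping).
    """
    if mask.voxel_count == 0:
        raise ValueError(f"mask {mask.label!r} is empty; centroid undefined")
    idx = np.argwhere(mask.voxels)
    return mask.grid.index_to_physical(idx).mean(axis=0)


def sphere_voi_mask(grid: VolumeGrid, voi: SphericalVoi) -> BinaryMask:
    """Rasterize a spherical VOI: voxel included iff its center is within radius."""
    if not grid.contains_point(voi.center):
        raise ValueError(f"sphere center {voi.center} lies outside the grid extent")
    # bounding box in index space to avoid materializing full-volume distances
    center_idx = grid.physical_to_index(voi.center)
    pad = voi.radius / np.asarray(grid.spacing) + 1.0
    lo = np.maximum(np.floor(center_idx - pad).astype(int), 0)
    hi = np.minimum(np.ceil(center_idx + pad).astype(int) + 1, np.asarray(grid.dims))
    voxels = np.zeros(grid.dims, dtype=bool)
    sub_idx = np.stack(
        np.meshgrid(*(np.arange(l, h) for l, h in zip(lo, hi)), indexing="ij"), axis=-1
    )
    centers = grid.index_to_physical(sub_idx)
    dist2 = ((centers - np.asarray(voi.center)) ** 2).sum(axis=-1)
    voxels[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = dist2 <= voi.radius**2
    return BinaryMask(grid=grid, voxels=voxels, label=f"sphere_r{voi.radius:g}mm")


def roi_statistics(suv: ScalarVolume, mask: BinaryMask) -> RoiStatistics:
    """SUVmax / SUVmean over the member voxels of ``mask``.

    The max location reports the first occurrence in C order of the (x, y, z)
    lattice, i.e. the lowest linear index on ties.
    """
    if not grids_equal(suv.grid, mask.grid):
        raise ValueError("SUV volume and mask are on different grids; resample first")
    flat_idx = np.flatnonzero(mask.voxels.reshape(-1))
    if flat_idx.size == 0:
        raise ValueError(f"mask {mask.label!r} is empty")
    vals = suv.values.reshape(-1)[flat_idx]
    j = int(np.argmax(vals))
    max_lin = int(flat_idx[j])
    max_index = tuple(int(i) for i in np.unravel_index(max_lin, suv.grid.dims))
    if vals.max() < 0:
        warnings.warn("all SUV values in the region are negative", stacklevel=2)
    return RoiStatistics(
        suv_max=float(vals[j]),
        suv_mean=float(vals.mean()),
        max_index=max_index,  # type: ignore[arg-type]
        max_location_mm=tuple(suv.grid.index_to_physical(np.asarray(max_index))),
        voxel_count=int(flat_idx.size),
        volume_ml=float(flat_idx.size) * suv.grid.voxel_volume_ml,
    )
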