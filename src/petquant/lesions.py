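"""Tumor delineation at fractional-SUVmax thresholds, TLG, cumulative SUV
histograms.

A lesion is delineated inside a (registered) organ mask as every voxel whose
SUV is at least ``fraction`` times the organ's SUVmax (threshold inclusive,
so the maximum voxel always belongs to the lesion).  Total lesion glycolysis
is the per-voxel sum of SUV times voxel volume, identically equal to
SUVmean x volume.  The cumulative SUV histogram reports, for a ladder of
thresholds, the fraction of the region's volume at or above each threshold;
hot focal lesions produce a convex-downward curve, homogeneous low-uptake
tissue a convex-upward one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grids import BinaryMask, ScalarVolume, grids_equal

__all__ = [
    "LesionSegmentation",
    "CumulativeSuvHistogram",
    "delineate_by_fraction",
    "total_lesion_glycolysis",
    "cumulative_suv_histogram",
]


@dataclass
class LesionSegmentation:
    """Result of fractional-SUVmax delineation, with volume, SUVmean and TLG."""

    fraction: float
    reference_suv_max: float
    mask: BinaryMask
    volume_ml: float
    suv_mean: float
    tlg: float  # SUV * mL
    bounding_box: tuple[tuple[int, int], tuple[int, int], tuple[int, int]] | None
    #: member voxel indices, shape (n, 3) — the "tumor coordinate information"
    voxel_indices: np.ndarray


def delineate_by_fraction(
    suv: ScalarVolume,
    organ: BinaryMask,
    fraction: float,
    largest_component_only: bool = False,
) -> LesionSegmentation:
    """Segment the lesion: organ voxels with SUV >= fraction * organ SUVmax.

    ``fraction`` must lie in (0, 1); the organ's SUVmax must be positive so
    the threshold is meaningful.  With ``largest_component_only`` the lesion
    is restricted to its largest 26-connected component.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must lie in (0, 1), got {fraction}")
    if not grids_equal(suv.grid, organ.grid):
        raise ValueError("SUV volume and organ mask are on different grids; resample first")
    if organ.voxel_count == 0:
        raise ValueError(f"organ mask {organ.label!r} is empty")
    ref_max = float(suv.values[organ.voxels].max())
    if ref_max <= 0:
        raise ValueError(f"organ {organ.label!r} has non-positive SUVmax ({ref_max}); cannot threshold")
    lesion_voxels = organ.voxels & (suv.values >= fraction * ref_max)
    if largest_component_only and lesion_voxels.any():
        labeled, n = ndimage.label(lesion_voxels, structure=np.ones((3, 3, 3), dtype=int))
        sizes = ndimage.sum_labels(lesion_voxels, labeled, index=np.arange(1, n + 1))
        lesion_voxels = labeled == (1 + int(np.argmax(sizes)))
    mask = BinaryMask(grid=suv.grid, voxels=lesion_voxels, label=f"{organ.label}_lesion_{fraction:g}")
    idx = np.argwhere(lesion_voxels)
    bbox = (
        tuple((int(lo), int(hi)) for lo, hi in zip(idx.min(axis=0), idx.max(axis=0)))
        if idx.size
        else None
    )
    vals = suv.values[lesion_voxels]
    volume = mask.volume_ml
    suv_mean = float(vals.mean()) if vals.size else 0.0
    return LesionSegmentation(
        fraction=fraction,
        reference_suv_max=ref_max,
        mask=mask,
        volume_ml=volume,
        suv_mean=suv_mean,
        tlg=suv_mean * volume,
        bounding_box=bbox,  # type: ignore[arg-type]
        voxel_indices=idx,
    )


def total_lesion_glycolysis(lesion: LesionSegmentation) -> float:
    """TLG in SUV*mL: SUVmean of the lesion times its volume.

    An empty lesion yields 0 with a warning rather than an error — a region
    can legitimately contain no supra-threshold voxels after masking.
    """
    if lesion.mask.voxel_count == 0:
        warnings.warn("empty lesion: TLG is 0", stacklevel=2)
        return 0.0
    return lesion.suv_mean * lesion.volume_ml


@dataclass
class CumulativeSuvHistogram:
    """Volume fraction at or above each threshold of an ascending ladder."""

    thresholds: np.ndarray  # absolute SUV, or percent of SUVmax (0-100)
    fractions: np.ndarray  # in [0, 1], non-increasing
    mode: str  # "absolute" | "percent_of_max"
    reference_suv_max: float


def cumulative_suv_histogram(
    suv: ScalarVolume,
    mask: BinaryMask,
    mode: str = "percent_of_max",
    n_bins: int = 101,
) -> CumulativeSuvHistogram:
    """Fraction of region volume with SUV >= t, over a ladder of thresholds.

    ``percent_of_max`` spaces thresholds at 0..100% of the region SUVmax
    (101 points by default); ``absolute`` spans [0, SUVmax] in SUV units.
    """
    if mode not in ("absolute", "percent_of_max"):
        raise ValueError(f"unknown mode {mode!r}")
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    if not grids_equal(suv.grid, mask.grid):
        raise ValueError("SUV volume and mask are on different grids; resample first")
    if mask.voxel_count == 0:
        raise ValueError(f"mask {mask.label!r} is empty")
    vals = suv.values[mask.voxels]
    ref_max = float(vals.max())
    if mode == "percent_of_max":
        thresholds = np.linspace(0.0, 100.0, n_bins)
        abs_thr = thresholds / 100.0 * ref_max
    else:
        thresholds = np.linspace(0.0, ref_max, n_bins)
        abs_thr = thresholds
    fractions = (vals[None, :] >= abs_thr[:, None]).mean(axis=1)
    return CumulativeSuvHistogram(
        thresholds=thresholds, fractions=fractions, mode=mode, reference_suv_max=ref_max
    )
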