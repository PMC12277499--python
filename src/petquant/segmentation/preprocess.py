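"""CT preprocessing and paired volume/label augmentation."""

from __future__ import annotations

import numpy as np

from ..grids import ScalarVolume, VolumeGrid
from ..spatial import resample
from .config import SegmentationConfig

__all__ = ["preprocess_ct", "augment"]


def preprocess_ct(ct: ScalarVolume, config: SegmentationConfig) -> ScalarVolume:
    """Clip to the HU window, map linearly to [0, 1], resample to the target
    spacing (trilinear).  The output keeps modality CT with normalized values.
    """
    if ct.modality != "CT":
        raise ValueError(f"preprocess_ct expects a CT volume, got {ct.modality!r}")
    lo, hi = config.clip_range
    normalized = (np.clip(ct.values, lo, hi) - lo) / (hi - lo)
    vol = ScalarVolume(ct.grid, normalized, "CT")
    if np.allclose(ct.grid.spacing, config.target_spacing):
        return vol
    # target grid spans the same physical extent at the new spacing
    extent = np.asarray(ct.grid.dims) * np.asarray(ct.grid.spacing)
    new_dims = tuple(int(max(1, round(e / s))) for e, s in zip(extent, config.target_spacing))
    target = VolumeGrid(
        dims=new_dims,
        spacing=tuple(config.target_spacing),
        origin=ct.grid.origin,
        orientation=ct.grid.orientation,
    )
    return resample(vol, target, interpolation="trilinear")


def augment(
    volume: np.ndarray,
    labels: np.ndarray,
    config: SegmentationConfig,
    seed: int,
    *,
    force_flip_axes: tuple[int, ...] = (),
    force_rotate_axes: tuple[int, ...] = (),
) -> tuple[np.ndarray, np.ndarray]:
    """Random flips and 90-degree rotations along all 3 axes (each with
    ``rotate_prob``/``flip_prob``), plus intensity shifting on the volume only.

    The identical spatial transform is applied to volume and labels, so voxel
    correspondence is preserved exactly.  Deterministic per seed; the
    ``force_*`` arguments bypass the coin flips for targeted tests.
    """
    if volume.shape != labels.shape:
        raise ValueError("volume and labels must share a shape")
    rng = np.random.default_rng(seed)
    vol = np.array(volume, dtype=float)
    lab = np.array(labels)
    for axis in range(3):
        if axis in force_flip_axes or rng.random() < config.flip_prob:
            vol = np.flip(vol, axis=axis)
            lab = np.flip(lab, axis=axis)
    for axis in range(3):
        if axis in force_rotate_axes or rng.random() < config.rotate_prob:
            plane = tuple(a for a in range(3) if a != axis)
            k = int(rng.integers(1, 4)) if axis not in force_rotate_axes else 1
            vol = np.rot90(vol, k=k, axes=plane)
            lab = np.rot90(lab, k=k, axes=plane)
    if rng.random() < config.intensity_shift_prob:
        vol = vol + rng.uniform(-config.intensity_shift_offset, config.intensity_shift_offset)
    return np.ascontiguousarray(vol), np.ascontiguousarray(lab)
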