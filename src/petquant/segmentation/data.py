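"""Phantom-based training data for the segmentation backend.

Each sample is a preprocessed (normalized, resampled, cropped) CT cube with
a matching integer label volume.  Per-sample variation comes from small
random rigid shifts of the organ set and additive HU noise, emulating
patient-to-patient anatomy variation at desk scale.
"""

from __future__ import annotations

import numpy as np

from ..grids import VolumeGrid
from ..phantom import desk_phantom_spec, generate_phantom, rasterize_ellipsoid
from .config import SegmentationConfig
from .preprocess import preprocess_ct

__all__ = ["make_phantom_dataset"]


def make_phantom_dataset(
    n_samples: int,
    config: SegmentationConfig,
    seed: int = 0,
    shift_scale_mm: float = 6.0,
    hu_noise_sd: float = 20.0,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Build (volume, labels) pairs on ``config.crop_size`` cubes.

    Labels follow ``config.class_names`` order (0 = background); tumor voxels
    inherit their host organ's class.  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    dataset = []
    for _ in range(n_samples):
        shift = tuple(rng.normal(0.0, shift_scale_mm, size=3))
        spec = desk_phantom_spec(shift_mm=shift, with_tumor=False)
        phantom = generate_phantom(spec)
        ct = phantom.ct
        noisy = ct.values + rng.normal(0.0, hu_noise_sd, size=ct.values.shape)
        ct = type(ct)(ct.grid, noisy, "CT")
        pre = preprocess_ct(ct, config)

        # center crop to the configured cube
        c = config.crop_size
        lo = [(d - c) // 2 for d in pre.grid.dims]
        if any(l < 0 for l in lo):
            raise ValueError(
                f"preprocessed volume {pre.grid.dims} smaller than crop_size {c}"
            )
        volume = pre.values[lo[0] : lo[0] + c, lo[1] : lo[1] + c, lo[2] : lo[2] + c]
        crop_grid = VolumeGrid(
            dims=(c, c, c),
            spacing=pre.grid.spacing,
            origin=tuple(pre.grid.index_to_physical(np.asarray(lo, float))),
            orientation=pre.grid.orientation,
        )
        labels = np.zeros((c, c, c), dtype=int)
        for organ in spec.organs:
            cls = config.class_names.index(organ.name)
            labels[rasterize_ellipsoid(crop_grid, organ).voxels] = cls
        dataset.append((np.ascontiguousarray(volume), labels))
    return dataset
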