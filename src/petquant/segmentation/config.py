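"""Configuration for the segmentation backend.

Defaults reproduce the full-scale training recipe: 2x2x2 patch embedding to
48 features, 4 patch-merging stages, 96^3 crops of CT normalized from the
[-175, 250] HU window, 1.5x1.5x2.0 mm resampling, flip/rotation probability
0.1 and intensity shift probability 0.5 with offset 0.1, dice +
cross-entropy loss (1:1) and 20,000 iterations.  ``desk_config`` is the
CPU-scale preset used by the test suite and the examples.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

__all__ = ["SegmentationConfig", "desk_config"]

#: background + right breast, left breast, liver, spleen, bone marrow
DEFAULT_CLASS_NAMES = ("background", "breast_r", "breast_l", "liver", "spleen", "bone_marrow")


@dataclass(frozen=True)
class SegmentationConfig:
    patch_size: int = 2
    embed_dim: int = 48
    n_stages: int = 4
    window_size: int = 7  # per axis, capped by the token-map size at each stage
    n_classes: int = 6
    class_names: tuple[str, ...] = DEFAULT_CLASS_NAMES
    crop_size: int = 96
    clip_range: tuple[float, float] = (-175.0, 250.0)
    target_spacing: tuple[float, float, float] = (1.5, 1.5, 2.0)
    flip_prob: float = 0.1
    rotate_prob: float = 0.1
    intensity_shift_prob: float = 0.5
    intensity_shift_offset: float = 0.1
    dice_weight: float = 1.0
    ce_weight: float = 1.0
    iterations: int = 20_000
    learning_rate: float = 0.2  # Adam step for the readout head
    eval_every: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        stride = self.patch_size * 2**self.n_stages
        if self.crop_size % stride != 0:
            raise ValueError(
                f"crop_size ({self.crop_size}) must be divisible by "
                f"patch_size * 2**n_stages ({stride})"
            )
        for name in ("flip_prob", "rotate_prob", "intensity_shift_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        if len(self.class_names) != self.n_classes:
            raise ValueError("class_names length must equal n_classes")
        if self.clip_range[0] >= self.clip_range[1]:
            raise ValueError("clip_range must be (low, high) with low < high")


def desk_config(**overrides) -> SegmentationConfig:
    """CPU-scale preset: 32^3 crops, 12 features, <=300 iterations."""
    base = SegmentationConfig(
        embed_dim=12,
        crop_size=32,
        window_size=4,
        iterations=300,
        target_spacing=(4.8, 4.8, 4.0),
    )
    return replace(base, **overrides)
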