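"""Synthetic dual-grid PET/CT phantoms with known ground truth.

The phantom emulates the geometry of a clinical FDG PET/CT study: a fine CT
lattice and a coarser PET lattice covering a common patient-space extent, a
handful of ellipsoidal "organs" (two breasts, liver, spleen, bone marrow)
with distinct attenuation values and target SUVs, and optionally a small
hot tumor nested inside an organ.

Raw PET values are synthesized by *inverting* the body-weight SUV formula:
the stored value is chosen so that applying the forward conversion with the
phantom's acquisition metadata reproduces each organ's target SUV exactly
(before noise).  The SUV conversion path is thereby tested against an oracle
that never runs the conversion itself.

A voxel belongs to an organ iff its center lies inside the ellipsoid; there
is no fractional occupancy, so masks are exactly reproducible.  Noise, when
requested, is additive Gaussian on the raw values, clipped at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import BinaryMask, ScalarVolume, VolumeGrid
from .suv import SuvParameters

__all__ = [
    "OrganSpec",
    "PhantomSpec",
    "Phantom",
    "OverlappingOrgansError",
    "rasterize_ellipsoid",
    "generate_phantom",
    "desk_phantom_spec",
    "table1_phantom_spec",
    "raw_value_for_suv",
]


class OverlappingOrgansError(ValueError):
    """Two organs with different labels claim the same voxels."""


@dataclass(frozen=True)
class OrganSpec:
    """An ellipsoidal organ: label, geometry (mm), HU value and target SUV."""

    name: str
    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    ct_value: float
    target_suv: float

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semi_axes):
            raise ValueError(f"organ {self.name!r}: semi-axes must be positive")


@dataclass(frozen=True)
class PhantomSpec:
    """Complete recipe for one phantom: grids, organs, tumor, noise, metadata."""

    ct_grid: VolumeGrid
    pet_grid: VolumeGrid
    organs: tuple[OrganSpec, ...]
    suv_params: SuvParameters
    tumor: OrganSpec | None = None
    noise_sd: float = 0.0  # additive Gaussian sd on raw PET values
    background_hu: float = -1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        labels = [o.name for o in self.organs]
        if self.tumor is not None:
            labels.append(self.tumor.name)
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise ValueError(f"duplicate organ labels: {sorted(dupes)}")
        if not _extents_overlap(self.ct_grid, self.pet_grid):
            raise ValueError("ct_grid and pet_grid do not cover a common extent")


def _extents_overlap(a: VolumeGrid, b: VolumeGrid) -> bool:
    ca, cb = a.extent_corners(), b.extent_corners()
    lo = np.maximum(ca.min(axis=0), cb.min(axis=0))
    hi = np.minimum(ca.max(axis=0), cb.max(axis=0))
    return bool(np.all(lo < hi))


@dataclass
class Phantom:
    """Generated phantom: CT, raw PET, per-label masks on both grids, truth SUVs."""

    ct: ScalarVolume
    pet_raw: ScalarVolume
    masks: dict[str, BinaryMask]  # on the PET grid
    ct_masks: dict[str, BinaryMask]  # on the CT grid
    truth: dict[str, float]  # label -> target SUV
    suv_params: SuvParameters = field(default=None)  # type: ignore[assignment]

    def __iter__(self):
        # tuple-style unpacking: ct, pet_raw, masks, truth
        return iter((self.ct, self.pet_raw, self.masks, self.truth))


def rasterize_ellipsoid(grid: VolumeGrid, organ: OrganSpec) -> BinaryMask:
    """Boolean mask of voxels whose centers lie inside the organ's ellipsoid."""
    centers = grid.voxel_centers()
    rel = (centers - np.asarray(organ.center)) / np.asarray(organ.semi_axes)
    inside = (rel**2).sum(axis=-1) <= 1.0
    return BinaryMask(grid=grid, voxels=inside, label=organ.name)


def raw_value_for_suv(target_suv: float, params: SuvParameters) -> float:
    """Stored PET value that the forward SUV conversion maps to ``target_suv``."""
    weight_g = params.patient_weight * 1000.0
    concentration = target_suv * params.total_dose * params.decay_factor() / weight_g
    return (concentration - params.rescale_intercept) / params.rescale_slope


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Rasterize the phantom on both grids and synthesize CT and raw PET values.

    Deterministic for a fixed seed; with ``noise_sd == 0`` the output is
    independent of the seed entirely.  Raises
    :class:`OverlappingOrgansError` if two organs (tumor excluded — it is
    meant to sit inside an organ) overlap on either grid.
    """
    ct_masks: dict[str, BinaryMask] = {}
    pet_masks: dict[str, BinaryMask] = {}
    for organ in spec.organs:
        ct_masks[organ.name] = rasterize_ellipsoid(spec.ct_grid, organ)
        pet_masks[organ.name] = rasterize_ellipsoid(spec.pet_grid, organ)
    for grid_masks in (ct_masks, pet_masks):
        names = list(grid_masks)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                if np.any(grid_masks[a].voxels & grid_masks[b].voxels):
                    raise OverlappingOrgansError(
                        f"organs {a!r} and {b!r} overlap with conflicting labels"
                    )

    ct_values = np.full(spec.ct_grid.dims, spec.background_hu, dtype=float)
    pet_suv = np.zeros(spec.pet_grid.dims, dtype=float)
    for organ in spec.organs:
        ct_values[ct_masks[organ.name].voxels] = organ.ct_value
        pet_suv[pet_masks[organ.name].voxels] = organ.target_suv

    truth = {o.name: o.target_suv for o in spec.organs}
    if spec.tumor is not None:
        t = spec.tumor
        ct_masks[t.name] = rasterize_ellipsoid(spec.ct_grid, t)
        pet_masks[t.name] = rasterize_ellipsoid(spec.pet_grid, t)
        ct_values[ct_masks[t.name].voxels] = t.ct_value
        pet_suv[pet_masks[t.name].voxels] = t.target_suv
        truth[t.name] = t.target_suv

    # invert the SUV formula: linear in SUV, so apply to the whole lattice at once
    pet_raw = raw_value_for_suv(1.0, spec.suv_params) * pet_suv
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        pet_raw = pet_raw + rng.normal(0.0, spec.noise_sd, size=pet_raw.shape)
        np.clip(pet_raw, 0.0, None, out=pet_raw)

    return Phantom(
        ct=ScalarVolume(spec.ct_grid, ct_values, "CT"),
        pet_raw=ScalarVolume(spec.pet_grid, pet_raw, "PET"),
        masks=pet_masks,
        ct_masks=ct_masks,
        truth=truth,
        suv_params=spec.suv_params,
    )


def _centered_grid(dims, spacing) -> VolumeGrid:
    origin = tuple(-(n - 1) / 2.0 * s for n, s in zip(dims, spacing))
    return VolumeGrid(dims=tuple(dims), spacing=tuple(spacing), origin=origin)


#: desk-scale organ set: distinct HU and SUV per organ, SUV targets in the
#: range reported for FDG-avid RES organs and breast tissue
_DESK_ORGANS = (
    OrganSpec("breast_r", (-55.0, -40.0, 40.0), (32.0, 30.0, 28.0), -80.0, 0.8),
    OrganSpec("breast_l", (55.0, -40.0, 40.0), (32.0, 30.0, 28.0), -70.0, 0.7),
    OrganSpec("liver", (-35.0, 5.0, -35.0), (45.0, 35.0, 32.0), 60.0, 2.2),
    OrganSpec("spleen", (48.0, 20.0, -40.0), (22.0, 18.0, 20.0), 45.0, 1.6),
    OrganSpec("bone_marrow", (0.0, 45.0, -10.0), (12.0, 12.0, 65.0), 250.0, 1.2),
)

_DESK_TUMOR = OrganSpec("tumor", (-55.0, -40.0, 40.0), (9.0, 9.0, 9.0), 40.0, 8.0)


def default_suv_params() -> SuvParameters:
    """Typical acquisition metadata: 60 kg patient, 5.18 MBq/kg dose, 60 min uptake."""
    return SuvParameters(
        patient_weight=60.0,
        total_dose=5.18e6 * 60.0,  # Bq
        radiopharmaceutical_start_time=10 * 3600.0,
        series_time=11 * 3600.0,
        half_life=6586.2,
        rescale_slope=1.0,
    )


def desk_phantom_spec(
    *,
    noise_sd: float = 0.0,
    seed: int = 0,
    with_tumor: bool = True,
    shift_mm: tuple[float, float, float] = (0.0, 0.0, 0.0),
    suv_params: SuvParameters | None = None,
) -> PhantomSpec:
    """Reduced dual-grid phantom spec: CT 64x64x40 @ 3x3x4 mm, PET 40x40x40 @
    4.8x4.8x4 mm, both centered on a common 192x192x160 mm extent.

    ``shift_mm`` translates every organ (and the tumor) rigidly — handy for
    constructing registration pairs with a known ground-truth displacement.
    """
    shift = np.asarray(shift_mm, dtype=float)

    def shifted(o: OrganSpec) -> OrganSpec:
        return OrganSpec(o.name, tuple(np.asarray(o.center) + shift), o.semi_axes, o.ct_value, o.target_suv)

    return PhantomSpec(
        ct_grid=_centered_grid((64, 64, 40), (3.0, 3.0, 4.0)),
        pet_grid=_centered_grid((40, 40, 40), (4.8, 4.8, 4.0)),
        organs=tuple(shifted(o) for o in _DESK_ORGANS),
        tumor=shifted(_DESK_TUMOR) if with_tumor else None,
        noise_sd=noise_sd,
        suv_params=suv_params or default_suv_params(),
        seed=seed,
    )


def table1_phantom_spec(patient: int = 1, **kwargs) -> PhantomSpec:
    """Full clinical-scale grids (CT 512x512 in-plane, PET 200x200; 2-3 mm
    slices).  Organ geometry as in :func:`desk_phantom_spec` but on the large
    lattices; allocates ~600 MB for the CT volume — intended for end-to-end
    demonstrations, not the routine test suite.
    """
    if patient == 1:
        ct_dims, ct_sp, pet_dims, pet_sp = (512, 512, 284), (1.3672, 1.3672, 3.0), (200, 200, 283), (3.5, 3.5, 3.0)
    elif patient == 2:
        ct_dims, ct_sp, pet_dims, pet_sp = (512, 512, 462), (1.3672, 1.3672, 2.0), (200, 200, 284), (3.5, 3.5, 3.0)
    else:
        raise ValueError("patient must be 1 or 2")
    base = desk_phantom_spec(**kwargs)
    return PhantomSpec(
        ct_grid=_centered_grid(ct_dims, ct_sp),
        pet_grid=_centered_grid(pet_dims, pet_sp),
        organs=base.organs,
        tumor=base.tumor,
        noise_sd=base.noise_sd,
        suv_params=base.suv_params,
        seed=base.seed,
    )
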