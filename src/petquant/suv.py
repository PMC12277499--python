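"""Body-weight SUV conversion with radioactive decay correction.

A PET voxel stores a raw integer that the DICOM rescale factor maps to an
activity concentration in Bq/mL.  The body-weight standardized uptake value
normalizes that concentration by the injected dose per gram of patient:

    SUV_bw = (raw * slope + intercept) * weight_g
             -----------------------------------------
             total_dose * 2^(-(t_series - t_start) / T_half)

The denominator decay-corrects the injected dose to the series (scan start)
time.  With concentration in Bq/mL, dose in Bq and weight in grams, SUV_bw is
the conventional dimensionless g/mL quantity (uniform tracer distribution in a
1 g/mL body gives SUV 1).  Negative rescaled values are passed through
unchanged; clipping is a display concern.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import ScalarVolume, SuvVolume

__all__ = ["F18_HALF_LIFE_S", "SuvParameters", "decay_factor", "convert_to_suv"]

#: Half-life of fluorine-18 in seconds (109.77 min), the default when a PET
#: series does not carry the radionuclide half-life attribute.
F18_HALF_LIFE_S = 6586.2


@dataclass(frozen=True)
class SuvParameters:
    """Everything the SUV formula needs, as read from a PET DICOM series.

    Times are clock values in seconds since midnight; :meth:`uptake_time_s`
    resolves a series time that falls "before" the injection time as a
    midnight crossing (uptake is ~60 min, never negative).
    """

    patient_weight: float  # kg
    total_dose: float  # Bq
    radiopharmaceutical_start_time: float  # s since midnight
    series_time: float  # s since midnight
    half_life: float = F18_HALF_LIFE_S  # s
    rescale_slope: float = 1.0
    rescale_intercept: float = 0.0

    def __post_init__(self) -> None:
        if self.patient_weight <= 0:
            raise ValueError("patient_weight must be positive (kg)")
        if self.total_dose <= 0:
            raise ValueError("total_dose must be positive (Bq)")
        if self.half_life <= 0:
            raise ValueError("half_life must be positive (s)")
        if self.rescale_slope == 0:
            raise ValueError("rescale_slope must be nonzero")

    def uptake_time_s(self) -> float:
        """Series time minus injection time, wrapping once across midnight."""
        dt = self.series_time - self.radiopharmaceutical_start_time
        if dt < 0:
            dt += 24 * 3600.0
        return dt

    def decay_factor(self) -> float:
        return decay_factor(self.uptake_time_s(), self.half_life)


def decay_factor(delta_t: float, half_life: float) -> float:
    """Fraction of activity remaining after ``delta_t``: ``2**(-delta_t/half_life)``.

    Lies in (0, 1] for non-negative ``delta_t``; 0.5 at exactly one half-life.
    """
    if half_life <= 0:
        raise ValueError("half_life must be positive")
    return float(2.0 ** (-float(delta_t) / float(half_life)))


def convert_to_suv(volume: ScalarVolume, params: SuvParameters) -> SuvVolume:
    """Convert a raw PET volume to body-weight SUV, voxel by voxel.

    The map is affine in the stored value (slope, optional intercept) followed
    by division through the decay-corrected dose per gram of body weight; it
    is therefore linear in the stored value when the intercept is zero.
    """
    if volume.modality != "PET":
        raise ValueError(f"convert_to_suv expects a PET volume, got {volume.modality!r}")
    weight_g = params.patient_weight * 1000.0
    corrected_dose = params.total_dose * params.decay_factor()
    concentration = volume.values * params.rescale_slope + params.rescale_intercept
    suv = concentration * weight_g / corrected_dose
    return ScalarVolume(grid=volume.grid, values=np.asarray(suv, dtype=float), modality="SUV")
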