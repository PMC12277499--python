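"""Fractional-SUVmax delineation, TLG identities, cumulative SUV histograms."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import petquant as pq
from petquant.lesions import (
    cumulative_suv_histogram,
    delineate_by_fraction,
    total_lesion_glycolysis,
)
from petquant.phantom import generate_phantom

from conftest import make_random_lesion_spec


def test_uniform_organ_is_entirely_lesion(clean_suv, clean_phantom):
    organ = clean_phantom.masks["liver"]
    for fraction in (0.1, 0.4, 0.5, 0.9):
        lesion = delineate_by_fraction(clean_suv, organ, fraction)
        assert np.array_equal(lesion.mask.voxels, organ.voxels)


def test_tumor_recovered_at_half_max(clean_suv, clean_phantom):
    lesion = delineate_by_fraction(clean_suv, clean_phantom.masks["breast_r"], 0.5)
    assert lesion.reference_suv_max == pytest.approx(8.0)
    assert np.array_equal(lesion.mask.voxels, clean_phantom.masks["tumor"].voxels)
    assert lesion.bounding_box is not None
    lo, hi = zip(*lesion.bounding_box)
    assert np.all(lesion.voxel_indices >= np.asarray(lo))
    assert np.all(lesion.voxel_indices <= np.asarray(hi))


@given(st.integers(0, 2**31 - 1))
def test_higher_fraction_never_grows_lesion(seed):
    rng = np.random.default_rng(seed)
    ph = generate_phantom(make_random_lesion_spec(rng))
    suv = pq.convert_to_suv(ph.pet_raw, ph.suv_params)
    m40 = delineate_by_fraction(suv, ph.masks["organ"], 0.4).mask.voxels
    m50 = delineate_by_fraction(suv, ph.masks["organ"], 0.5).mask.voxels
    assert np.all(m50 <= m40)  # mask(0.5) subset of mask(0.4)


def test_fraction_bounds_and_nonpositive_max_rejected(clean_suv, clean_phantom):
    organ = clean_phantom.masks["liver"]
    for bad in (0.0, 1.0, -0.2, 1.5):
        with pytest.raises(ValueError, match="fraction"):
            delineate_by_fraction(clean_suv, organ, bad)
    zero_suv = pq.ScalarVolume(clean_suv.grid, np.zeros(clean_suv.grid.dims), "SUV")
    with pytest.raises(ValueError, match="SUVmax"):
        delineate_by_fraction(zero_suv, organ, 0.5)


def test_tlg_single_voxel_closed_form():
    grid = pq.VolumeGrid((4, 4, 4), (10.0, 10.0, 10.0))  # 1 mL voxels
    suv = pq.ScalarVolume(grid, np.zeros(grid.dims), "SUV")
    suv.values[1, 1, 1] = 2.0
    organ = pq.BinaryMask(grid, np.ones(grid.dims, bool))
    lesion = delineate_by_fraction(suv, organ, 0.5)
    assert lesion.mask.voxel_count == 1
    assert total_lesion_glycolysis(lesion) == pytest.approx(2.0)


def test_tlg_uniform_lesion_closed_form(clean_suv, clean_phantom):
    lesion = delineate_by_fraction(clean_suv, clean_phantom.masks["spleen"], 0.5)
    n, v = lesion.mask.voxel_count, clean_suv.grid.voxel_volume_ml
    assert total_lesion_glycolysis(lesion) == pytest.approx(1.6 * n * v)


def test_tlg_two_route_identity_on_noisy_phantom(noisy_suv, noisy_phantom):
    lesion = delineate_by_fraction(noisy_suv, noisy_phantom.masks["breast_r"], 0.4)
    voxel_sum = noisy_suv.values[lesion.mask.voxels].sum() * noisy_suv.grid.voxel_volume_ml
    assert total_lesion_glycolysis(lesion) == pytest.approx(voxel_sum, rel=1e-12)


def test_tlg_ordering_holds_on_100_random_phantoms():
    """TLG at the 50% threshold never exceeds TLG at 40% (smaller or equal
    lesion of at-least-as-hot voxels): checked on 100 randomized phantoms."""
    rng = np.random.default_rng(2024)
    for _ in range(100):
        ph = generate_phantom(make_random_lesion_spec(rng))
        suv = pq.convert_to_suv(ph.pet_raw, ph.suv_params)
        t40 = delineate_by_fraction(suv, ph.masks["organ"], 0.4).tlg
        t50 = delineate_by_fraction(suv, ph.masks["organ"], 0.5).tlg
        assert t50 <= t40 + 1e-12


def test_empty_lesion_tlg_is_zero_with_warning(clean_suv, clean_phantom):
    lesion = delineate_by_fraction(clean_suv, clean_phantom.masks["liver"], 0.5)
    lesion.mask.voxels[:] = False
    with pytest.warns(UserWarning, match="empty"):
        assert total_lesion_glycolysis(lesion) == 0.0


# ------------------------------------------------------- cumulative histogram


def test_csh_uniform_region_is_step_function(clean_suv, clean_phantom):
    hist = cumulative_suv_histogram(clean_suv, clean_phantom.masks["liver"], mode="absolute")
    assert np.all(hist.fractions == 1.0)  # every voxel at SUVmax
    assert hist.fractions[0] == 1.0  # threshold 0


def test_csh_non_increasing_and_bounded(noisy_suv, noisy_phantom):
    for mode in ("absolute", "percent_of_max"):
        hist = cumulative_suv_histogram(noisy_suv, noisy_phantom.masks["breast_r"], mode=mode)
        assert np.all(np.diff(hist.fractions) <= 0)
        assert 0.0 <= hist.fractions[-1] <= hist.fractions[0] <= 1.0
        assert len(hist.thresholds) == 101


def test_csh_tumor_vs_healthy_shape_separation(noisy_suv, noisy_phantom):
    """The lesion's histogram dominates the healthy breast's at mid-range
    percent thresholds, and the tumor-bearing breast's curve is convex
    downward (collapses to the small hot fraction early) where the healthy
    breast's is convex upward (stays near 1 until its noise ceiling)."""
    lesion = cumulative_suv_histogram(noisy_suv, noisy_phantom.masks["tumor"], mode="percent_of_max")
    healthy = cumulative_suv_histogram(
        noisy_suv, noisy_phantom.masks["breast_l"], mode="percent_of_max"
    )
    mid = slice(30, 71)  # 30-70% of each region's own SUVmax
    assert np.all(lesion.fractions[mid] >= healthy.fractions[mid])
    assert lesion.fractions[90] > healthy.fractions[90]  # strict gap near the top
    tumor_side = cumulative_suv_histogram(
        noisy_suv, noisy_phantom.masks["breast_r"], mode="percent_of_max"
    )
    # convexity read off the chord midpoint between thresholds 0% and 100%
    chord_mid = (tumor_side.fractions[0] + tumor_side.fractions[-1]) / 2
    assert tumor_side.fractions[50] < chord_mid
    assert healthy.fractions[50] > (healthy.fractions[0] + healthy.fractions[-1]) / 2


def test_csh_rejects_empty_mask_and_bad_bins(clean_suv, clean_phantom):
    empty = pq.BinaryMask(clean_suv.grid, np.zeros(clean_suv.grid.dims, bool))
    with pytest.raises(ValueError, match="empty"):
        cumulative_suv_histogram(clean_suv, empty)
    with pytest.raises(ValueError, match="n_bins"):
        cumulative_suv_histogram(clean_suv, clean_phantom.masks["liver"], n_bins=1)
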