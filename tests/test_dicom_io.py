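"""DICOM/NIfTI round trips, time parsing, slice ordering, error contracts."""

import numpy as np
import pydicom
import pytest

import petquant as pq
from petquant import dicom_io
from petquant.dicom_io import (
    MissingDicomAttributeError,
    format_dicom_time,
    parse_dicom_time,
    read_ct_series,
    read_mask,
    read_nifti,
    read_pet_series,
    write_ct_series,
    write_labelmap,
    write_nifti,
    write_pet_series,
)


@pytest.mark.parametrize(
    "text, expected",
    [("000000", 0.0), ("130512.5", 13 * 3600 + 5 * 60 + 12.5), ("235959.999999", 86399.999999)],
)
def test_parse_dicom_time(text, expected):
    assert parse_dicom_time(text) == pytest.approx(expected)


@pytest.mark.parametrize("bad", ["236000", "245900", "1300", "12:00:00", "123465", "abcdef"])
def test_parse_dicom_time_rejects_malformed(bad):
    with pytest.raises(ValueError):
        parse_dicom_time(bad)


def test_time_format_round_trip():
    assert parse_dicom_time(format_dicom_time(47112.5)) == pytest.approx(47112.5)


@pytest.fixture(scope="module")
def pet_series_dir(tmp_path_factory, clean_phantom):
    d = tmp_path_factory.mktemp("pet_series")
    write_pet_series(clean_phantom.pet_raw, clean_phantom.suv_params, d)
    return d


def test_pet_round_trip_values_grid_and_parameters(pet_series_dir, clean_phantom):
    vol, params = read_pet_series(pet_series_dir)
    assert pq.grids_equal(vol.grid, clean_phantom.pet_raw.grid)
    # stored as 16-bit integers: lossless up to rounding of the raw value
    assert np.abs(vol.values - clean_phantom.pet_raw.values).max() <= 0.5
    assert params == clean_phantom.suv_params


def test_slice_order_on_disk_is_irrelevant(pet_series_dir, tmp_path):
    shuffled = tmp_path / "shuffled"
    shuffled.mkdir()
    files = sorted(pet_series_dir.iterdir())
    rng = np.random.default_rng(0)
    for f, j in zip(files, rng.permutation(len(files))):
        (shuffled / f"slice_{j:04d}.dcm").write_bytes(f.read_bytes())
    a, _ = read_pet_series(pet_series_dir)
    b, _ = read_pet_series(shuffled)
    assert np.array_equal(a.values, b.values)
    assert pq.grids_equal(a.grid, b.grid)


def test_missing_weight_reported_by_name(pet_series_dir, tmp_path):
    broken = tmp_path / "noweight"
    broken.mkdir()
    for f in pet_series_dir.iterdir():
        ds = pydicom.dcmread(f)
        del ds.PatientWeight
        ds.save_as(broken / f.name, enforce_file_format=True)
    with pytest.raises(MissingDicomAttributeError, match="patient_weight absent"):
        read_pet_series(broken)


def test_mixed_series_uids_rejected(pet_series_dir, tmp_path):
    mixed = tmp_path / "mixed"
    mixed.mkdir()
    files = sorted(pet_series_dir.iterdir())
    for f in files:
        (mixed / f.name).write_bytes(f.read_bytes())
    ds = pydicom.dcmread(files[0])
    ds.SeriesInstanceUID = ds.SeriesInstanceUID + ".9"
    ds.save_as(mixed / "foreign.dcm", enforce_file_format=True)
    with pytest.raises(ValueError, match="series UIDs"):
        read_pet_series(mixed)


def test_ct_round_trip(tmp_path, clean_phantom):
    write_ct_series(clean_phantom.ct, tmp_path / "ct")
    ct = read_ct_series(tmp_path / "ct")
    assert pq.grids_equal(ct.grid, clean_phantom.ct.grid)
    assert np.array_equal(ct.values, clean_phantom.ct.values)  # integer HU


def test_nifti_round_trip(tmp_path, clean_phantom):
    path = tmp_path / "ct.nii.gz"
    write_nifti(clean_phantom.ct, path)
    back = read_nifti(path, modality="CT")
    assert pq.grids_equal(back.grid, clean_phantom.ct.grid, tol=1e-4)
    assert np.abs(back.values - clean_phantom.ct.values).max() < 1e-3


def test_labelmap_round_trip_and_name_recovery(tmp_path, clean_phantom):
    path = tmp_path / "labels.nii.gz"
    write_labelmap(clean_phantom.ct_masks, path)
    masks = read_mask(path)
    assert set(masks) == set(clean_phantom.ct_masks)
    # tumor was written last, so it punches a hole in its host breast
    host = clean_phantom.ct_masks["breast_r"].voxels & ~clean_phantom.ct_masks["tumor"].voxels
    assert np.array_equal(masks["breast_r"].voxels, host)
    assert np.array_equal(masks["liver"].voxels, clean_phantom.ct_masks["liver"].voxels)


def test_read_mask_resamples_to_requested_grid(tmp_path, clean_phantom):
    path = tmp_path / "labels.nii.gz"
    write_labelmap({"liver": clean_phantom.ct_masks["liver"]}, path)
    masks = read_mask(path, grid=clean_phantom.pet_raw.grid)
    assert pq.grids_equal(masks["liver"].grid, clean_phantom.pet_raw.grid)
    assert pq.dice(masks["liver"], clean_phantom.masks["liver"]) > 0.95


def test_read_mask_rejects_non_integer_labels(tmp_path, clean_phantom):
    path = tmp_path / "bad.nii.gz"
    frac = pq.ScalarVolume(clean_phantom.ct.grid, np.full(clean_phantom.ct.grid.dims, 0.5), "CT")
    write_nifti(frac, path, dtype=np.float32)
    with pytest.raises(ValueError, match="non-integer"):
        read_mask(path)


def test_empty_label_volume_gives_empty_map(tmp_path, clean_phantom):
    path = tmp_path / "empty.nii.gz"
    zeros = pq.ScalarVolume(clean_phantom.ct.grid, np.zeros(clean_phantom.ct.grid.dims), "CT")
    write_nifti(zeros, path, dtype=np.int16)
    assert read_mask(path) == {}
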