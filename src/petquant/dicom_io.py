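"""Reading and writing PET/CT series (DICOM), volumes and label masks (NIfTI).

A PET series is read into a raw-valued :class:`~petquant.grids.ScalarVolume`
plus the :class:`~petquant.suv.SuvParameters` extracted from the
radiopharmaceutical information sequence and patient attributes; the rescale
factor is *not* applied to the stored values — it is one of the SUV formula's
symbols and travels with the parameters.  CT series are read with the
rescale applied (Hounsfield units).

Geometry conventions: DICOM patient space is LPS; NIfTI affines are RAS, so
the first two axes change sign on the way in and out.  Slices are sorted by
the projection of their position onto the slice normal, so on-disk file order
is irrelevant.
"""

from __future__ import annotations

import json
import re
import warnings
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid
import nibabel as nib

from .grids import BinaryMask, ScalarVolume, VolumeGrid, grids_equal
from .suv import F18_HALF_LIFE_S, SuvParameters

__all__ = [
    "MissingDicomAttributeError",
    "parse_dicom_time",
    "format_dicom_time",
    "read_pet_series",
    "read_ct_series",
    "write_pet_series",
    "write_ct_series",
    "read_nifti",
    "write_nifti",
    "read_mask",
    "write_labelmap",
]

_PET_SOP = "1.2.840.10008.5.1.4.1.1.128"
_CT_SOP = "1.2.840.10008.5.1.4.1.1.2"


class MissingDicomAttributeError(KeyError):
    """A DICOM attribute the SUV formula needs is absent from the series."""


def parse_dicom_time(time_string: str) -> float:
    """Parse a DICOM TM value (HHMMSS or HHMMSS.FFFFFF) to seconds since
    midnight, preserving fractional seconds."""
    s = str(time_string).strip()
    if not re.fullmatch(r"\d{6}(\.\d{1,6})?", s):
        raise ValueError(f"malformed DICOM time {time_string!r}; expected HHMMSS[.FFFFFF]")
    hh, mm = int(s[0:2]), int(s[2:4])
    ss = float(s[4:])
    if hh > 23 or mm > 59 or ss >= 60.0:
        raise ValueError(f"DICOM time {time_string!r} has out-of-range components")
    return hh * 3600.0 + mm * 60.0 + ss


def format_dicom_time(seconds: float) -> str:
    """Inverse of :func:`parse_dicom_time` (microsecond precision)."""
    seconds = float(seconds) % (24 * 3600)
    hh = int(seconds // 3600)
    mm = int((seconds % 3600) // 60)
    ss = seconds - hh * 3600 - mm * 60
    return f"{hh:02d}{mm:02d}{ss:09.6f}"


# ---------------------------------------------------------------- DICOM read


def _dcm_files(path) -> list[Path]:
    p = Path(path)
    files = sorted(q for q in p.iterdir() if q.suffix.lower() == ".dcm") if p.is_dir() else [p]
    if not files:
        raise FileNotFoundError(f"no DICOM files under {p}")
    return files


def _read_sorted_slices(path) -> list[Dataset]:
    slices = [pydicom.dcmread(f) for f in _dcm_files(path)]
    uids = {s.SeriesInstanceUID for s in slices}
    if len(uids) != 1:
        raise ValueError(f"directory mixes {len(uids)} series UIDs: {sorted(uids)}")
    iop = np.asarray(slices[0].ImageOrientationPatient, dtype=float)
    normal = np.cross(iop[0:3], iop[3:6])
    slices.sort(key=lambda s: float(np.dot(np.asarray(s.ImagePositionPatient, float), normal)))
    return slices


def _grid_and_values(slices: list[Dataset]) -> tuple[VolumeGrid, np.ndarray]:
    first = slices[0]
    iop = np.asarray(first.ImageOrientationPatient, dtype=float)
    dx, dy = iop[0:3], iop[3:6]
    dz = np.cross(dx, dy)
    ipp = np.asarray([s.ImagePositionPatient for s in slices], dtype=float)
    if len(slices) > 1:
        steps = np.diff(ipp @ dz)
        z_spacing = float(np.mean(steps))
        if np.ptp(steps) > 1e-3:
            warnings.warn("non-uniform slice spacing; using the mean", stacklevel=2)
    else:
        z_spacing = float(getattr(first, "SliceThickness", 1.0))
    row_sp, col_sp = (float(v) for v in first.PixelSpacing)  # (y, x)
    nx, ny, nz = int(first.Columns), int(first.Rows), len(slices)
    grid = VolumeGrid(
        dims=(nx, ny, nz),
        spacing=(col_sp, row_sp, z_spacing),
        origin=tuple(ipp[0]),
        orientation=tuple(np.column_stack([dx, dy, dz]).reshape(-1)),
    )
    values = np.empty((nx, ny, nz), dtype=float)
    for k, s in enumerate(slices):
        values[:, :, k] = s.pixel_array.T  # (Rows, Cols) -> (x, y)
    return grid, values


def _require(ds: Dataset, attr: str, name: str):
    value = getattr(ds, attr, None)
    if value in (None, ""):
        raise MissingDicomAttributeError(f"{name} absent")
    return value


def read_pet_series(path, time_source: str = "series") -> tuple[ScalarVolume, SuvParameters]:
    """Read a single-frame-per-file PET series: raw stored values + SUV metadata.

    ``time_source`` selects the scan-time attribute for the decay interval:
    ``"series"`` (scan initiation time, the formula's choice) or
    ``"acquisition"``.
    """
    if time_source not in ("series", "acquisition"):
        raise ValueError(f"time_source must be 'series' or 'acquisition', got {time_source!r}")
    slices = _read_sorted_slices(path)
    grid, values = _grid_and_values(slices)
    first = slices[0]

    weight = float(_require(first, "PatientWeight", "patient_weight"))  # kg
    seq = getattr(first, "RadiopharmaceuticalInformationSequence", None)
    if not seq:
        raise MissingDicomAttributeError("radiopharmaceutical_information_sequence absent")
    rp = seq[0]
    dose = float(_require(rp, "RadionuclideTotalDose", "total_dose"))  # Bq
    start = parse_dicom_time(_require(rp, "RadiopharmaceuticalStartTime", "radiopharmaceutical_start_time"))
    attr = "SeriesTime" if time_source == "series" else "AcquisitionTime"
    scan = parse_dicom_time(_require(first, attr, "series_time" if time_source == "series" else "acquisition_time"))
    half_life = float(getattr(rp, "RadionuclideHalfLife", None) or F18_HALF_LIFE_S)

    params = SuvParameters(
        patient_weight=weight,
        total_dose=dose,
        radiopharmaceutical_start_time=start,
        series_time=scan,
        half_life=half_life,
        rescale_slope=float(getattr(first, "RescaleSlope", 1.0)),
        rescale_intercept=float(getattr(first, "RescaleIntercept", 0.0)),
    )
    return ScalarVolume(grid, values, "PET"), params


def read_ct_series(path) -> ScalarVolume:
    """Read a CT series with the rescale applied (values in HU)."""
    slices = _read_sorted_slices(path)
    grid, values = _grid_and_values(slices)
    slope = float(getattr(slices[0], "RescaleSlope", 1.0))
    intercept = float(getattr(slices[0], "RescaleIntercept", 0.0))
    return ScalarVolume(grid, values * slope + intercept, "CT")


# --------------------------------------------------------------- DICOM write


def _base_dataset(sop_class: str, modality: str, series_uid: str, frame_uid: str) -> Dataset:
    ds = Dataset()
    ds.file_meta = FileMetaDataset()
    ds.file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds.file_meta.MediaStorageSOPClassUID = sop_class
    ds.file_meta.MediaStorageSOPInstanceUID = generate_uid()
    ds.SOPClassUID = sop_class
    ds.SOPInstanceUID = ds.file_meta.MediaStorageSOPInstanceUID
    ds.Modality = modality
    ds.SeriesInstanceUID = series_uid
    ds.StudyInstanceUID = frame_uid  # one study per written series
    ds.FrameOfReferenceUID = frame_uid
    ds.PatientName = "Phantom^Synthetic"
    ds.PatientID = "PHANTOM"
    return ds


def _write_slices(
    values: np.ndarray,
    grid: VolumeGrid,
    out_dir,
    *,
    sop_class: str,
    modality: str,
    slope: float,
    intercept: float,
    extra: dict,
    stored_dtype=np.uint16,
) -> list[Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid()
    frame_uid = generate_uid()
    D = grid.direction
    paths = []
    signed = np.issubdtype(stored_dtype, np.signedinteger)
    for k in range(grid.dims[2]):
        ds = _base_dataset(sop_class, modality, series_uid, frame_uid)
        ds.Rows, ds.Columns = grid.dims[1], grid.dims[0]
        ds.PixelSpacing = [grid.spacing[1], grid.spacing[0]]  # (row=y, col=x)
        ds.SliceThickness = grid.spacing[2]
        ds.ImageOrientationPatient = list(D[:, 0]) + list(D[:, 1])
        ds.ImagePositionPatient = list(grid.index_to_physical(np.array([0, 0, k])))
        ds.InstanceNumber = k + 1
        ds.RescaleSlope = slope
        ds.RescaleIntercept = intercept
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1 if signed else 0
        for key, val in extra.items():
            setattr(ds, key, val)
        ds.PixelData = np.ascontiguousarray(values[:, :, k].T.astype(stored_dtype)).tobytes()
        path = out / f"{modality.lower()}_{k:04d}.dcm"
        pydicom.dcmwrite(path, ds, enforce_file_format=True)
        paths.append(path)
    return paths


def write_pet_series(volume: ScalarVolume, params: SuvParameters, out_dir) -> list[Path]:
    """Write a raw-valued PET volume as a single-frame-per-file DICOM series
    with the SUV metadata (weight, dose, times, half-life, rescale) populated.

    Stored values are rounded to 16-bit integers; when the raw range does not
    fit, the rescale slope is scaled up (with a warning) so the physical
    values survive.
    """
    if volume.modality != "PET":
        raise ValueError("write_pet_series expects a PET volume")
    raw = volume.values
    slope = params.rescale_slope
    if raw.min() < 0 or raw.max() > 65535:
        scale = max(abs(raw.min()), raw.max()) / 32000.0
        warnings.warn(f"raw PET values exceed uint16 range; folding factor {scale:g} into the rescale slope")
        raw = raw / scale
        slope = slope * scale
    rp = Dataset()
    rp.RadionuclideTotalDose = params.total_dose
    rp.RadiopharmaceuticalStartTime = format_dicom_time(params.radiopharmaceutical_start_time)
    rp.RadionuclideHalfLife = params.half_life
    extra = {
        "PatientWeight": params.patient_weight,
        "SeriesTime": format_dicom_time(params.series_time),
        "AcquisitionTime": format_dicom_time(params.series_time),
        "RadiopharmaceuticalInformationSequence": [rp],
        "Units": "BQML",
        "DecayCorrection": "START",
    }
    return _write_slices(
        np.round(raw),
        volume.grid,
        out_dir,
        sop_class=_PET_SOP,
        modality="PT",
        slope=slope,
        intercept=params.rescale_intercept,
        extra=extra,
    )


def write_ct_series(volume: ScalarVolume, out_dir) -> list[Path]:
    """Write a CT volume (HU) as a DICOM series with int16 stored values."""
    if volume.modality != "CT":
        raise ValueError("write_ct_series expects a CT volume")
    return _write_slices(
        np.round(np.clip(volume.values, -32768, 32767)),
        volume.grid,
        out_dir,
        sop_class=_CT_SOP,
        modality="CT",
        slope=1.0,
        intercept=0.0,
        extra={"KVP": 120},
        stored_dtype=np.int16,
    )


# --------------------------------------------------------------------- NIfTI

_LPS_TO_RAS = np.diag([-1.0, -1.0, 1.0, 1.0])


def _grid_to_ras_affine(grid: VolumeGrid) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = grid.direction * np.asarray(grid.spacing)
    aff[:3, 3] = grid.origin
    return _LPS_TO_RAS @ aff


def _grid_from_ras_affine(affine: np.ndarray, dims) -> VolumeGrid:
    aff = _LPS_TO_RAS @ np.asarray(affine, dtype=float)
    M = aff[:3, :3]
    spacing = np.linalg.norm(M, axis=0)
    return VolumeGrid(
        dims=tuple(int(d) for d in dims),
        spacing=tuple(spacing),
        origin=tuple(aff[:3, 3]),
        orientation=tuple((M / spacing).reshape(-1)),
    )


def write_nifti(volume: ScalarVolume, path, dtype=np.float32) -> None:
    img = nib.Nifti1Image(volume.values.astype(dtype), _grid_to_ras_affine(volume.grid))
    nib.save(img, str(path))


def read_nifti(path, modality: str = "CT") -> ScalarVolume:
    img = nib.load(str(path))
    grid = _grid_from_ras_affine(img.affine, img.shape[:3])
    return ScalarVolume(grid, np.asarray(img.dataobj, dtype=float), modality)


def write_labelmap(masks: dict[str, BinaryMask], path) -> dict[int, str]:
    """Write masks as one integer label volume (labels 1..n in iteration
    order; later masks overwrite earlier ones where they overlap, so nested
    structures should be listed outermost first).  The label->name map is
    stored in a JSON sidecar next to the volume and returned."""
    masks = dict(masks)
    if not masks:
        raise ValueError("no masks to write")
    first = next(iter(masks.values()))
    labels = np.zeros(first.grid.dims, dtype=np.uint16)
    mapping: dict[int, str] = {}
    for i, (name, mask) in enumerate(masks.items(), start=1):
        if not grids_equal(mask.grid, first.grid):
            raise ValueError(f"mask {name!r} is on a different grid")
        labels[mask.voxels] = i
        mapping[i] = name
    img = nib.Nifti1Image(labels, _grid_to_ras_affine(first.grid))
    nib.save(img, str(path))
    Path(str(path) + ".labels.json").write_text(json.dumps(mapping))
    return mapping


def read_mask(path, grid: VolumeGrid | None = None) -> dict[str, BinaryMask]:
    """Read a label volume into one BinaryMask per nonzero label.

    Labels must be integers.  If ``grid`` is given and differs from the file's
    geometry, the label volume is transferred with nearest-neighbor sampling.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if not np.allclose(data, np.round(data)):
        raise ValueError(f"label volume {path} contains non-integer labels")
    file_grid = _grid_from_ras_affine(img.affine, img.shape[:3])
    volume = ScalarVolume(file_grid, data, "CT")
    if grid is not None and not grids_equal(file_grid, grid):
        from .spatial import resample

        volume = resample(volume, grid, interpolation="nearest")
    sidecar = Path(str(path) + ".labels.json")
    names = {int(k): v for k, v in json.loads(sidecar.read_text()).items()} if sidecar.exists() else {}
    out: dict[str, BinaryMask] = {}
    for label in np.unique(volume.values):
        if label == 0:
            continue
        name = names.get(int(label), str(int(label)))
        out[name] = BinaryMask(volume.grid, volume.values == label, label=name)
    return out
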