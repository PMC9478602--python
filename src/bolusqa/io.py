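"""File I/O: NIfTI volumes/masks, DICOM RT Dose, and CSV record formats.

Internal grids are LPS; NIfTI affines are expressed in RAS per the format,
so the x/y axes are negated on write and on read.
"""

from __future__ import annotations

import csv
import datetime

import nibabel as nib
import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .errors import ValidationError
from .grids import DoseGrid, ImageVolume, StructureMask
from .toxicity import ToxicityRecord

__all__ = [
    "save_nifti",
    "load_nifti_volume",
    "load_nifti_mask",
    "save_rtdose",
    "load_rtdose",
    "save_cohort_csv",
    "load_cohort_csv",
    "load_film_csv",
    "load_tps_csv",
]

_RT_DOSE_STORAGE = "1.2.840.10008.5.1.4.1.1.481.2"


def _lps_affine(spacing, origin) -> np.ndarray:
    aff = np.diag([-spacing[0], -spacing[1], spacing[2], 1.0])
    aff[:3, 3] = [-origin[0], -origin[1], origin[2]]
    return aff


def save_nifti(obj: ImageVolume | StructureMask, path) -> None:
    """Write a volume (float32) or mask (uint8) as NIfTI-1."""
    if isinstance(obj, StructureMask):
        data = obj.mask.astype(np.uint8)
    else:
        data = np.asarray(obj.values, dtype=np.float32)
    img = nib.Nifti1Image(data, _lps_affine(obj.spacing, obj.origin))
    nib.save(img, str(path))


def _grid_from_affine(img) -> tuple[tuple, tuple]:
    aff = img.affine
    if not np.allclose(aff[:3, :3], np.diag(np.diag(aff[:3, :3]))):
        raise ValidationError("NIfTI affine: only axis-aligned volumes are supported")
    d = np.diag(aff[:3, :3])
    spacing = (abs(d[0]), abs(d[1]), abs(d[2]))
    origin = (-aff[0, 3], -aff[1, 3], aff[2, 3])  # RAS translation -> LPS
    return spacing, origin


def load_nifti_volume(path) -> ImageVolume:
    img = nib.load(str(path))
    spacing, origin = _grid_from_affine(img)
    return ImageVolume(np.asarray(img.dataobj, dtype=float), spacing, origin)


def load_nifti_mask(path, name: str = "") -> StructureMask:
    img = nib.load(str(path))
    spacing, origin = _grid_from_affine(img)
    return StructureMask(np.asarray(img.dataobj) > 0, spacing, origin, name)


def save_rtdose(dose: DoseGrid, path, dose_units: str = "GY") -> None:
    """Write a single-volume DICOM RT Dose.

    Pixel data are uint32 with DoseGridScaling chosen to span the grid
    maximum; internal cGy values are stored in Gy per DICOM convention.
    """
    values_gy = np.asarray(dose.values, dtype=float) / 100.0
    scaling = max(values_gy.max(), 1e-12) / (2**32 - 1)
    pixels = np.round(values_gy / scaling).astype(np.uint32)
    # array axes (x, y, z) -> DICOM (frame=z, row=y, col=x)
    pixels = np.transpose(pixels, (2, 1, 0))

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.UID(_RT_DOSE_STORAGE)
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTDOSE"
    now = datetime.datetime.now()
    ds.ContentDate = now.strftime("%Y%m%d")
    ds.ContentTime = now.strftime("%H%M%S")
    ds.PatientName = "PHANTOM^CHEST"
    ds.PatientID = "BOLUSQA"
    ds.StudyInstanceUID = generate_uid()
    ds.SeriesInstanceUID = generate_uid()
    ds.FrameOfReferenceUID = generate_uid()

    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    ds.NumberOfFrames = pixels.shape[0]
    ds.Rows = pixels.shape[1]
    ds.Columns = pixels.shape[2]
    ds.PixelSpacing = [f"{dose.spacing[1]:.6f}", f"{dose.spacing[0]:.6f}"]  # row, col
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.ImagePositionPatient = [f"{o:.6f}" for o in dose.origin]
    ds.GridFrameOffsetVector = [f"{k * dose.spacing[2]:.6f}" for k in range(pixels.shape[0])]
    ds.DoseUnits = dose_units
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    ds.DoseGridScaling = f"{scaling:.9e}"  # DS values are limited to 16 chars
    ds.PixelData = pixels.tobytes()
    ds.save_as(str(path), enforce_file_format=True)


def load_rtdose(path) -> DoseGrid:
    """Read a DICOM RT Dose back into a cGy grid."""
    ds = pydicom.dcmread(str(path))
    pixels = ds.pixel_array.astype(float) * float(ds.DoseGridScaling)
    if str(getattr(ds, "DoseUnits", "GY")).upper() == "GY":
        pixels *= 100.0
    values = np.transpose(pixels, (2, 1, 0))  # back to (x, y, z)
    spacing = (
        float(ds.PixelSpacing[1]),
        float(ds.PixelSpacing[0]),
        float(ds.GridFrameOffsetVector[1]) - float(ds.GridFrameOffsetVector[0])
        if len(ds.GridFrameOffsetVector) > 1
        else 1.0,
    )
    origin = tuple(float(v) for v in ds.ImagePositionPatient)
    return DoseGrid(values, spacing, origin)


# ---------------------------------------------------------------------------
# CSV record formats
# ---------------------------------------------------------------------------

def save_cohort_csv(records, path) -> None:
    """`patient_id,fraction_bin,presentations,interrupted` with ';'-joined codes."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "fraction_bin", "presentations", "interrupted"])
        for r in records:
            w.writerow(
                [r.patient_id, r.fraction_bin, ";".join(sorted(r.presentations)), int(r.interrupted)]
            )


def load_cohort_csv(path) -> list[ToxicityRecord]:
    records = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            records.append(
                ToxicityRecord(
                    row["patient_id"],
                    row["fraction_bin"],
                    frozenset(c for c in row["presentations"].split(";") if c),
                    bool(int(row["interrupted"])),
                )
            )
    return records


def _read_keyed_csv(path, value_col: str) -> dict[str, dict[int, float]]:
    out: dict[str, dict[int, float]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.setdefault(row["patient_id"], {})[int(row["subregion"])] = float(row[value_col])
    return out


def load_film_csv(path) -> dict[str, dict[int, float]]:
    """`patient_id,subregion,roi_mean_response` -> responses per patient."""
    return _read_keyed_csv(path, "roi_mean_response")


def load_tps_csv(path) -> dict[str, dict[int, float]]:
    """`patient_id,subregion,tps_dose_cGy` -> planned doses per patient."""
    return _read_keyed_csv(path, "tps_dose_cGy")
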