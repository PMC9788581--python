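"""Scalar image volumes, acquisition metadata, and SUV conversion.

All voxel-level computation in the package runs on :class:`ImageVolume`, a
plain 3-D array in a canonical axis-aligned frame: ``values[i, j, k]`` sits at
physical position ``origin + (i, j, k) * spacing`` (mm).  NIfTI files are
reoriented to the closest canonical (RAS-like) orientation at load so that
downstream mask algebra is index-aligned; DICOM series are assembled
column/row/slice -> (x, y, z).

PET volumes may arrive either as activity concentration (Bq/mL) or already
converted to body-weight-normalised SUV by the scanner console; the
``value_kind`` tag records which, and :func:`to_suv` performs the standard
conversion

    SUV_bw(v) = C(v) / (A_scan / (W * 1000))

with ``A_scan`` the injected activity decay-corrected to scan start,
``A_scan = A_inj * 2**(-t_uptake / t_half)``.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np


class Modality(str, Enum):
    """Which study a volume belongs to."""

    CT = "CT"
    PET_PSMA = "PET_PSMA"
    PET_NAF = "PET_NAF"


class ValueKind(str, Enum):
    """Physical meaning of the voxel values."""

    HU = "HU"
    ACTIVITY_CONC = "ACTIVITY_CONC"  # Bq/mL
    SUV = "SUV"


@dataclass(frozen=True)
class ImageVolume:
    """A 3-D scalar grid with geometry and modality tags.

    Parameters
    ----------
    values
        3-D array of voxel values (HU for CT, Bq/mL or SUV for PET).
    spacing
        Per-axis voxel size in mm, strictly positive.
    origin
        Physical position (mm) of voxel (0, 0, 0).
    modality
        One of CT / PET_PSMA / PET_NAF.
    value_kind
        One of HU / ACTIVITY_CONC / SUV; CT volumes must be HU.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    modality: Modality = Modality.CT
    value_kind: ValueKind = ValueKind.HU

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 3:
            raise ValueError(f"expected a 3-D volume, got ndim={values.ndim}")
        if values.size == 0:
            raise ValueError("volume is empty")
        spacing = tuple(float(s) for s in self.spacing)
        origin = tuple(float(o) for o in self.origin)
        if len(spacing) != 3 or len(origin) != 3:
            raise ValueError("spacing and origin must be length-3")
        if any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be strictly positive, got {spacing}")
        modality = Modality(self.modality)
        value_kind = ValueKind(self.value_kind)
        if modality is Modality.CT and value_kind is not ValueKind.HU:
            raise ValueError("CT volumes must carry HU values")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "modality", modality)
        object.__setattr__(self, "value_kind", value_kind)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in mL (spacing product / 1000)."""
        sx, sy, sz = self.spacing
        return sx * sy * sz / 1000.0

    def same_grid(self, other: "ImageVolume", atol: float = 1e-6) -> bool:
        """True if shape, spacing and origin match within ``atol`` mm."""
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def physical_points(self) -> np.ndarray:
        """All voxel centers as an (N, 3) array of physical mm coordinates."""
        idx = np.indices(self.shape).reshape(3, -1).T.astype(float)
        return idx * np.asarray(self.spacing) + np.asarray(self.origin)

    def with_values(self, values: np.ndarray, value_kind: ValueKind | None = None) -> "ImageVolume":
        """Copy of this volume with new voxel data on the same grid."""
        return replace(self, values=values, value_kind=value_kind or self.value_kind)


@dataclass(frozen=True)
class AcquisitionMeta:
    """Injection and timing metadata needed for SUV normalisation.

    ``injected_activity_mbq`` is the activity at injection time (MBq),
    ``uptake_time_min`` the injection-to-scan delay, and
    ``half_life_min`` the radionuclide half-life (68Ga: 67.71 min,
    18F: 109.77 min).
    """

    injected_activity_mbq: float
    body_weight_kg: float
    uptake_time_min: float
    half_life_min: float

    def __post_init__(self) -> None:
        for name in ("injected_activity_mbq", "body_weight_kg", "half_life_min"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.uptake_time_min < 0:
            raise ValueError("uptake_time_min must be non-negative")

    def activity_at_scan_bq(self) -> float:
        """Injected activity decay-corrected to scan start, in Bq."""
        decay = 2.0 ** (-self.uptake_time_min / self.half_life_min)
        return self.injected_activity_mbq * 1e6 * decay


VALID_GROUPS = ("M", "N")


@dataclass(frozen=True)
class StudyPair:
    """One patient's coregistered CT + PSMA-PET + NaF-PET plus clinical data.

    After the registration stage all three volumes live on one common grid;
    ``validate_grid`` enforces this before segmentation.  ``group`` is "M"
    (metastatic, >5 bone lesions) or "N" (no skeletal metastases); ``psa`` is
    serum PSA (ug/L) at the time of the PET studies.
    """

    ct: ImageVolume
    psma: ImageVolume
    naf: ImageVolume
    meta_psma: AcquisitionMeta | None = None
    meta_naf: AcquisitionMeta | None = None
    psa: float = 0.0
    group: str = "M"
    patient_id: str = ""

    def __post_init__(self) -> None:
        if self.ct.value_kind is not ValueKind.HU:
            raise ValueError("StudyPair.ct must be a HU volume")
        if self.group not in VALID_GROUPS:
            raise ValueError(f"group must be one of {VALID_GROUPS}, got {self.group!r}")
        if not self.psa >= 0:
            raise ValueError("psa must be non-negative")

    def validate_grid(self) -> None:
        """Raise if the three volumes are not on a single common grid."""
        if not (self.ct.same_grid(self.psma) and self.ct.same_grid(self.naf)):
            raise ValueError(
                f"study {self.patient_id or '<unnamed>'}: CT/PSMA/NaF grids differ; "
                "run the registration stage first"
            )


def to_suv(pet: ImageVolume, meta: AcquisitionMeta) -> ImageVolume:
    """Convert a PET activity-concentration volume (Bq/mL) to SUV_bw.

    SUV_bw = C / (A_scan / (W * 1000)) with W*1000 the body weight in grams
    and A_scan the injected activity decay-corrected to scan start.  The
    conversion is linear in C.
    """
    if pet.value_kind is not ValueKind.ACTIVITY_CONC:
        raise ValueError(f"to_suv expects ACTIVITY_CONC input, got {pet.value_kind}")
    denom = meta.activity_at_scan_bq() / (meta.body_weight_kg * 1000.0)
    return pet.with_values(pet.values / denom, value_kind=ValueKind.SUV)


# ---------------------------------------------------------------------------
# File I/O


def write_volume(vol: ImageVolume, path: str | os.PathLike) -> None:
    """Write a volume as NIfTI-1 with a diagonal affine built from its grid."""
    import nibabel as nib

    affine = np.diag(list(vol.spacing) + [1.0])
    affine[:3, 3] = vol.origin
    img = nib.Nifti1Image(np.asarray(vol.values, dtype=np.float64), affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, os.fspath(path))


def _read_nifti(path: str | os.PathLike, modality: Modality, value_kind: ValueKind) -> ImageVolume:
    import nibabel as nib

    img = nib.load(os.fspath(path))
    if img.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got {img.ndim}-D")
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj, dtype=float)
    affine = img.affine
    spacing = tuple(float(np.linalg.norm(affine[:3, i])) for i in range(3))
    origin = tuple(float(x) for x in affine[:3, 3])
    return ImageVolume(data, spacing, origin, modality, value_kind)


def _read_dicom_series(path: str | os.PathLike, modality: Modality, value_kind: ValueKind) -> ImageVolume:
    """Assemble a single-frame DICOM series into one volume.

    Minimal reader: pixel data, PixelSpacing, ImagePositionPatient-based slice
    ordering, RescaleSlope/Intercept.  Slices are sorted along the slice
    normal; spacing along z is the median center-to-center distance.
    """
    import pydicom

    path = Path(path)
    files = sorted(p for p in path.iterdir() if p.is_file() and p.suffix.lower() in {".dcm", ""})
    datasets = []
    for f in files:
        try:
            ds = pydicom.dcmread(os.fspath(f))
        except Exception:  # skip non-DICOM clutter in the directory
            continue
        if hasattr(ds, "PixelData"):
            datasets.append(ds)
    if not datasets:
        raise IOError(f"{path}: no readable DICOM slices found")

    first = datasets[0]
    orient = np.array(getattr(first, "ImageOrientationPatient", [1, 0, 0, 0, 1, 0]), dtype=float)
    normal = np.cross(orient[:3], orient[3:])

    def slice_pos(ds) -> float:
        ipp = np.array(getattr(ds, "ImagePositionPatient", [0, 0, 0]), dtype=float)
        return float(np.dot(ipp, normal))

    datasets.sort(key=slice_pos)
    positions = np.array([slice_pos(ds) for ds in datasets])
    if len(datasets) > 1:
        dz = float(np.median(np.diff(positions)))
        if dz <= 0:
            raise IOError(f"{path}: slice positions are not strictly increasing")
    else:
        dz = float(getattr(first, "SliceThickness", 1.0))

    rows, cols = int(first.Rows), int(first.Columns)
    py, px = (float(v) for v in first.PixelSpacing)  # PixelSpacing is (row, col)
    arr = np.empty((cols, rows, len(datasets)), dtype=float)
    for k, ds in enumerate(datasets):
        if (int(ds.Rows), int(ds.Columns)) != (rows, cols):
            raise IOError(f"{path}: inconsistent slice dimensions")
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        pixels = ds.pixel_array.astype(float) * slope + intercept
        arr[:, :, k] = pixels.T  # (row, col) -> (x=col, y=row)

    ipp0 = np.array(getattr(datasets[0], "ImagePositionPatient", [0, 0, 0]), dtype=float)
    origin = (float(ipp0[0]), float(ipp0[1]), float(ipp0[2]))
    return ImageVolume(arr, (px, py, dz), origin, modality, value_kind)


def read_volume(
    path: str | os.PathLike,
    format: str | None = None,
    modality: Modality | str = Modality.CT,
    value_kind: ValueKind | str = ValueKind.HU,
) -> ImageVolume:
    """Read a 3-D scalar volume from NIfTI (.nii/.nii.gz) or a DICOM series dir.

    ``format`` is "nifti" or "dicom"; when omitted it is inferred from the
    path (directory -> DICOM series, otherwise NIfTI).  The caller supplies
    the modality and value-kind tags, which the file formats do not carry
    unambiguously.
    """
    modality = Modality(modality)
    value_kind = ValueKind(value_kind)
    p = Path(path)
    if not p.exists():
        raise IOError(f"no such file or directory: {p}")
    if format is None:
        format = "dicom" if p.is_dir() else "nifti"
    format = format.lower()
    if format == "nifti":
        return _read_nifti(p, modality, value_kind)
    if format == "dicom":
        return _read_dicom_series(p, modality, value_kind)
    raise ValueError(f"unknown format {format!r}")
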