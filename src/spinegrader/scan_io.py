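"""Reading, normalising and resampling sagittal spinal MR scans.

Coordinate convention used throughout the package
-------------------------------------------------
All grids are indexed ``(slice, row, col)``, 0-based, with half-open boxes
``[start, end)``.  Row 0 is the most superior row, so the row axis is the
superior->inferior "height" axis used by the level labeller.  The physical
position of in-plane pixel ``(r, c)`` is ``(r * row_mm, c * col_mm)`` measured
from the slice top-left corner.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom
from scipy import ndimage


class Sequence(str, enum.Enum):
    T1W = "T1w"
    T2W = "T2w"
    STIR = "STIR"
    FLAIR = "FLAIR"
    OTHER = "OTHER"


_SEQUENCE_KEYWORDS = [
    (Sequence.STIR, ("stir",)),
    (Sequence.FLAIR, ("flair",)),
    (Sequence.T1W, ("t1",)),
    (Sequence.T2W, ("t2",)),
]


def infer_sequence(description: str | None) -> Sequence:
    """Guess the MR sequence from a series description; OTHER on no match."""
    if not description:
        return Sequence.OTHER
    lowered = description.lower()
    for seq, keys in _SEQUENCE_KEYWORDS:
        if any(k in lowered for k in keys):
            return seq
    return Sequence.OTHER


@dataclass
class SagittalScan:
    """A stack of sagittal slices with physical spacing.

    voxels are indexed (slice, row, col); rows increase inferiorly.
    """

    voxels: np.ndarray
    pixel_spacing_mm: tuple[float, float]   # (row_mm, col_mm)
    slice_spacing_mm: float
    sequence: Sequence = Sequence.OTHER
    patient_id: str = ""
    study_id: str = ""

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be 3D (slice, row, col)")
        if self.voxels.shape[0] < 1 or min(self.voxels.shape[1:]) < 32:
            raise ValueError("scan must have >=1 slice of at least 32x32 pixels")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("scan intensities must be finite")
        if min(self.pixel_spacing_mm) <= 0 or self.slice_spacing_mm <= 0:
            raise ValueError("spacings must be positive")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def extent_mm(self) -> tuple[float, float]:
        """(height_mm, width_mm) of one slice."""
        return (self.voxels.shape[1] * self.pixel_spacing_mm[0],
                self.voxels.shape[2] * self.pixel_spacing_mm[1])


def load_dicom_series(directory: Path | str) -> SagittalScan:
    """Load one single-frame DICOM series from a directory.

    Slices are sorted by their position along the series normal (fallback:
    InstanceNumber), so the result is independent of filename order.
    """
    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.is_file())
    datasets = []
    for p in files:
        try:
            ds = pydicom.dcmread(str(p))
        except pydicom.errors.InvalidDicomError:
            continue
        datasets.append(ds)
    if not datasets:
        raise ValueError(f"no DICOM files found in {directory}")
    uids = {str(getattr(ds, "SeriesInstanceUID", "")) for ds in datasets}
    if len(uids) != 1:
        raise ValueError(f"mixed series in {directory}: found series UIDs {sorted(uids)}")
    first = datasets[0]
    if "PixelSpacing" not in first:
        raise ValueError("missing PixelSpacing tag; cannot establish physical scale")

    def sort_key(ds):
        pos = getattr(ds, "ImagePositionPatient", None)
        if pos is not None:
            return float(pos[0])  # sagittal stacks vary along patient x
        return float(getattr(ds, "InstanceNumber", 0))

    datasets.sort(key=sort_key)
    voxels = np.stack([ds.pixel_array.astype(np.float32) for ds in datasets])
    row_mm, col_mm = (float(v) for v in first.PixelSpacing)
    slice_mm = float(getattr(first, "SpacingBetweenSlices",
                             getattr(first, "SliceThickness", 1.0)) or 1.0)
    return SagittalScan(
        voxels=voxels,
        pixel_spacing_mm=(row_mm, col_mm),
        slice_spacing_mm=slice_mm,
        sequence=infer_sequence(str(getattr(first, "SeriesDescription", ""))),
        patient_id=str(getattr(first, "PatientID", "")),
        study_id=str(getattr(first, "StudyInstanceUID", "")),
    )


def load_nifti(path: Path | str, sequence: Sequence = Sequence.OTHER) -> SagittalScan:
    """Load a sagittal-major NIfTI volume (axis 0 = slices)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float32)
    if data.ndim == 2:
        data = data[None]
    zooms = img.header.get_zooms()
    slice_mm = float(zooms[0]) if len(zooms) >= 1 else 1.0
    row_mm = float(zooms[1]) if len(zooms) >= 2 else 1.0
    col_mm = float(zooms[2]) if len(zooms) >= 3 else 1.0
    return SagittalScan(voxels=data, pixel_spacing_mm=(row_mm, col_mm),
                        slice_spacing_mm=slice_mm, sequence=sequence)


def save_nifti(scan: SagittalScan, path: Path | str) -> None:
    affine = np.diag([scan.slice_spacing_mm, scan.pixel_spacing_mm[0],
                      scan.pixel_spacing_mm[1], 1.0])
    img = nib.Nifti1Image(scan.voxels.astype(np.float32), affine)
    img.header.set_zooms((scan.slice_spacing_mm,) + tuple(scan.pixel_spacing_mm))
    nib.save(img, str(path))


def normalise_intensity(scan: SagittalScan, p_low: float = 1.0,
                        p_high: float = 99.0) -> SagittalScan:
    """Robust percentile rescale of intensities to [0, 1].

    A constant image maps to all-zeros.  Percentiles rather than min/max make
    the scale insensitive to isolated spike artefacts.
    """
    v = scan.voxels
    lo, hi = np.percentile(v, [p_low, p_high])
    if hi <= lo:
        out = np.zeros_like(v)
    else:
        out = np.clip((v - lo) / (hi - lo), 0.0, 1.0)
    return replace(scan, voxels=out.astype(np.float32))


@dataclass
class PatchAffine:
    """In-plane affine mapping patch pixel (r, c) -> scan pixel (r, c).

    scan_px = scale * patch_px + offset, per axis.
    """

    scale: tuple[float, float]
    offset: tuple[float, float]

    def patch_to_scan(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        return pts * np.asarray(self.scale) + np.asarray(self.offset)

    def scan_to_patch(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        return (pts - np.asarray(self.offset)) / np.asarray(self.scale)


def resample_patch(scan: SagittalScan, slice_index: int,
                   window_mm: tuple[float, float, float, float],
                   out_px: int | tuple[int, int],
                   order: int = 3) -> tuple[np.ndarray, PatchAffine]:
    """Resample a physical window of one slice to a pixel grid.

    window_mm is (top_mm, left_mm, height_mm, width_mm) in slice physical
    coordinates; out-of-scan area is zero-padded.  Interpolation is bicubic
    by default.  Returns (pixels, affine patch->scan pixels).
    """
    top, left, height, width = window_mm
    if height <= 0 or width <= 0:
        raise ValueError("window must have positive extent")
    if isinstance(out_px, int):
        out_r, out_c = out_px, out_px
    else:
        out_r, out_c = out_px
    row_mm, col_mm = scan.pixel_spacing_mm
    # corner-aligned sampling: patch pixel 0 sits exactly on the window origin
    scale_r = (height / out_r) / row_mm
    scale_c = (width / out_c) / col_mm
    off_r = top / row_mm
    off_c = left / col_mm
    rr = off_r + scale_r * np.arange(out_r)
    cc = off_c + scale_c * np.arange(out_c)
    grid_r, grid_c = np.meshgrid(rr, cc, indexing="ij")
    pixels = ndimage.map_coordinates(
        scan.voxels[slice_index].astype(np.float64),
        np.stack([grid_r.ravel(), grid_c.ravel()]),
        order=order, mode="constant", cval=0.0,
    ).reshape(out_r, out_c)
    affine = PatchAffine(scale=(scale_r, scale_c), offset=(off_r, off_c))
    return pixels, affine
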