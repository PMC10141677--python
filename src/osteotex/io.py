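"""Scan reading, ROI resolution and region cropping.

Scans are single-frame grayscale wrist MRI slices, either 12-bit DICOM
(original acquisition representation) or 8-bit PNG renditions normalized to
0-255.  A 16-bit grayscale PNG container may carry 12-bit data, in which case
the caller states the effective bit depth explicitly.

Coordinates are 0-based and row-major; rectangles are half-open
``[row0, row0+n_rows) x [col0, col0+n_cols)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pydicom
from PIL import Image


class UnsupportedFormatError(ValueError):
    """Raised for color, multi-frame, or otherwise unsupported images."""


class MissingMetadataError(ValueError):
    """Raised when pixel spacing is unavailable and no override is given."""


class RoiOutOfBoundsError(ValueError):
    """Raised when a resolved ROI rectangle escapes the scan."""


def _round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (platform stable)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class ScanImage:
    """One grayscale MRI slice with its acquisition metadata.

    Parameters
    ----------
    pixels : ndarray of int
        2-D intensity grid, rows x cols.
    bit_depth : int
        Effective sample depth (8 or 12); intensities lie in
        ``[0, 2**bit_depth - 1]``.
    pixel_spacing : float
        Isotropic physical pixel size in millimetres.
    modality : str
        MR contrast, ``"T1"`` or ``"T2"``.
    source_format : str
        ``"DICOM"`` or ``"PNG"``.
    patient_id : str
        Opaque subject identifier.
    age_years : int
        Integer age label.
    """

    pixels: np.ndarray
    bit_depth: int
    pixel_spacing: float
    modality: str
    source_format: str
    patient_id: str
    age_years: int

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise UnsupportedFormatError("scan pixels must form a non-empty 2-D grid")
        if not np.issubdtype(px.dtype, np.integer):
            raise ValueError("scan pixels must be integer-valued")
        lo, hi = int(px.min()), int(px.max())
        if lo < 0 or hi > 2 ** self.bit_depth - 1:
            raise ValueError(
                f"intensities [{lo}, {hi}] outside the {self.bit_depth}-bit range"
            )
        if not self.pixel_spacing > 0:
            raise ValueError("pixel_spacing must be positive")
        if self.modality not in ("T1", "T2"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.source_format not in ("DICOM", "PNG"):
            raise ValueError(f"unknown source format {self.source_format!r}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape

    @property
    def gray_max(self) -> int:
        return 2 ** self.bit_depth - 1


@dataclass(frozen=True)
class RoiSpec:
    """Rectangular region-of-interest definition.

    ``size_mode="pixels"`` gives ``height``/``width`` directly in pixels;
    ``size_mode="metric"`` gives them in millimetres, to be resolved against a
    scan's pixel spacing so that regions cover equal physical extents across
    scans with different spacings.
    """

    region_kind: str  # "bone" | "growth"
    anchor: Tuple[int, int]  # (row0, col0) of the top-left corner
    height: float
    width: float
    size_mode: str = "pixels"

    def __post_init__(self) -> None:
        if self.region_kind not in ("bone", "growth"):
            raise ValueError(f"unknown region kind {self.region_kind!r}")
        if self.size_mode not in ("pixels", "metric"):
            raise ValueError(f"unknown size mode {self.size_mode!r}")
        if not (self.height > 0 and self.width > 0):
            raise ValueError("ROI height and width must be positive")


@dataclass(frozen=True)
class Region:
    """A cropped ROI carrying its provenance and age label."""

    pixels: np.ndarray
    bit_depth: int
    patient_id: str
    region_kind: str
    modality: str
    source_format: str
    age_years: int

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("region must be a non-empty 2-D grid")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape

    @property
    def gray_max(self) -> int:
        return 2 ** self.bit_depth - 1

    @property
    def provenance(self) -> Tuple[str, str, str, str]:
        return (self.patient_id, self.region_kind, self.modality, self.source_format)


def read_scan(
    path,
    age_years: int,
    modality: str,
    patient_id: str,
    pixel_spacing: Optional[float] = None,
    bit_depth: Optional[int] = None,
) -> ScanImage:
    """Read a single-frame grayscale DICOM or PNG scan.

    For DICOM the bit depth comes from ``BitsStored`` and the spacing from
    ``PixelSpacing`` (an explicit ``pixel_spacing`` overrides it); rescale
    slope/intercept are applied when present, then rounded.  PNG carries no
    spacing, so ``pixel_spacing`` is required; the sample depth of the
    container determines the bit depth unless ``bit_depth`` narrows it
    (12-bit data in a 16-bit container).
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    if path.suffix.lower() in (".dcm", ".dicom", ""):
        return _read_dicom(path, age_years, modality, patient_id, pixel_spacing, bit_depth)
    if path.suffix.lower() == ".png":
        return _read_png(path, age_years, modality, patient_id, pixel_spacing, bit_depth)
    raise UnsupportedFormatError(f"unrecognized scan format: {path.suffix}")


def _read_dicom(path, age_years, modality, patient_id, pixel_spacing, bit_depth):
    try:
        ds = pydicom.dcmread(str(path))
        arr = ds.pixel_array
    except Exception as exc:  # pragma: no cover - corrupt-file path
        raise IOError(f"unreadable DICOM file {path}: {exc}") from exc
    if int(getattr(ds, "NumberOfFrames", 1)) > 1:
        raise UnsupportedFormatError("multi-frame DICOM is not supported")
    if int(getattr(ds, "SamplesPerPixel", 1)) != 1:
        raise UnsupportedFormatError("color DICOM is not supported")
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    if slope != 1.0 or intercept != 0.0:
        arr = np.rint(arr.astype(np.float64) * slope + intercept).astype(np.int64)
    if pixel_spacing is None:
        spacing = getattr(ds, "PixelSpacing", None)
        if spacing is None:
            raise MissingMetadataError(
                f"{path}: DICOM has no PixelSpacing and no override was given"
            )
        pixel_spacing = float(spacing[0])
    if bit_depth is None:
        bit_depth = int(getattr(ds, "BitsStored", 16))
    return ScanImage(
        pixels=np.asarray(arr, dtype=np.int64),
        bit_depth=bit_depth,
        pixel_spacing=float(pixel_spacing),
        modality=modality,
        source_format="DICOM",
        patient_id=str(patient_id),
        age_years=int(age_years),
    )


def _read_png(path, age_years, modality, patient_id, pixel_spacing, bit_depth):
    try:
        img = Image.open(path)
        img.load()
    except Exception as exc:
        raise IOError(f"unreadable PNG file {path}: {exc}") from exc
    if img.mode == "L":
        inferred = 8
    elif img.mode in ("I", "I;16", "I;16B"):
        inferred = 16
    else:
        raise UnsupportedFormatError(
            f"{path}: PNG mode {img.mode!r} is not single-channel grayscale"
        )
    if pixel_spacing is None:
        raise MissingMetadataError(
            f"{path}: PNG carries no pixel spacing; supply pixel_spacing explicitly"
        )
    if bit_depth is None:
        bit_depth = inferred
    return ScanImage(
        pixels=np.asarray(img, dtype=np.int64),
        bit_depth=bit_depth,
        pixel_spacing=float(pixel_spacing),
        modality=modality,
        source_format="PNG",
        patient_id=str(patient_id),
        age_years=int(age_years),
    )


def resolve_roi(spec: RoiSpec, scan: ScanImage) -> Tuple[int, int, int, int]:
    """Resolve an ROI spec to a pixel rectangle ``(row0, col0, n_rows, n_cols)``.

    Metric sizes are converted with ``mm / pixel_spacing`` and rounded to the
    nearest integer (half away from zero), with a minimum extent of 1 pixel.
    """
    row0, col0 = int(spec.anchor[0]), int(spec.anchor[1])
    if spec.size_mode == "pixels":
        n_rows, n_cols = int(spec.height), int(spec.width)
    else:
        n_rows = max(1, _round_half_away(spec.height / scan.pixel_spacing))
        n_cols = max(1, _round_half_away(spec.width / scan.pixel_spacing))
    rows, cols = scan.shape
    if row0 < 0 or col0 < 0 or row0 + n_rows > rows or col0 + n_cols > cols:
        raise RoiOutOfBoundsError(
            f"ROI [{row0}:{row0 + n_rows}) x [{col0}:{col0 + n_cols}) "
            f"escapes the {rows}x{cols} scan"
        )
    return row0, col0, n_rows, n_cols


def extract_region(scan: ScanImage, spec: RoiSpec) -> Region:
    """Crop the resolved ROI out of the scan (always a copy, never a view)."""
    row0, col0, n_rows, n_cols = resolve_roi(spec, scan)
    crop = np.array(scan.pixels[row0 : row0 + n_rows, col0 : col0 + n_cols], copy=True)
    return Region(
        pixels=crop,
        bit_depth=scan.bit_depth,
        patient_id=scan.patient_id,
        region_kind=spec.region_kind,
        modality=scan.modality,
        source_format=scan.source_format,
        age_years=scan.age_years,
    )


def write_gray_png(pixels: np.ndarray, path, bit_depth: int) -> None:
    """Write a 2-D integer grid as grayscale PNG.

    8-bit data goes into an ``L`` image; deeper data (12-bit included) is
    stored verbatim in a 16-bit container with no scaling.
    """
    px = np.asarray(pixels)
    if bit_depth <= 8:
        Image.fromarray(px.astype(np.uint8), mode="L").save(path)
    else:
        Image.fromarray(px.astype(np.uint16)).save(path)
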