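"""Slice preprocessing: grid resampling, HU windowing, and the two-sided
field-of-view truncation mask.

The truncation geometry follows the training protocol for FOV-limited
simulation CT: a strip of columns on each lateral side of the slice is
zeroed (36 + 36 columns of a 128-wide grid, about 56% of the pixels, in the
reference configuration).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

from .image import CTSlice

__all__ = [
    "TruncationMask",
    "make_truncation_mask",
    "apply_mask",
    "resample",
    "hu_to_gray8",
    "read_dicom_slice",
    "write_dicom_slice",
    "DEFAULT_HU_WINDOW",
]

# linear window mapped onto [0, 255]; water (0 HU) lands at gray 159
DEFAULT_HU_WINDOW = (-1000.0, 600.0)


@dataclass
class TruncationMask:
    """known == 1 inside the reconstructed FOV; the first ``left_cols`` and
    last ``right_cols`` columns are missing."""

    known: np.ndarray
    left_cols: int
    right_cols: int
    grid_size: int

    @property
    def missing(self) -> np.ndarray:
        return ~self.known.astype(bool)

    @property
    def missing_fraction(self) -> float:
        return (self.left_cols + self.right_cols) / self.grid_size

    @property
    def n_missing(self) -> int:
        return int((self.left_cols + self.right_cols) * self.grid_size)


def make_truncation_mask(grid_size: int, left_cols: int, right_cols: int) -> TruncationMask:
    if left_cols < 0 or right_cols < 0:
        raise ValueError("column counts must be nonnegative")
    if left_cols + right_cols >= grid_size:
        raise ValueError(
            f"left_cols + right_cols = {left_cols + right_cols} must be < grid_size = {grid_size}"
        )
    known = np.ones((grid_size, grid_size), dtype=bool)
    if left_cols:
        known[:, :left_cols] = False
    if right_cols:
        known[:, grid_size - right_cols:] = False
    return TruncationMask(known=known, left_cols=left_cols,
                          right_cols=right_cols, grid_size=grid_size)


def apply_mask(slice_: CTSlice, mask: TruncationMask) -> CTSlice:
    """Zero the missing columns; known pixels are copied bit-identically."""
    if slice_.pixels.shape != mask.known.shape:
        raise ValueError(
            f"slice shape {slice_.pixels.shape} != mask shape {mask.known.shape}"
        )
    out = slice_.pixels.copy()
    out[mask.missing] = 0
    return CTSlice(out, slice_.spacing, slice_.unit)


def resample(slice_: CTSlice, target: int) -> CTSlice:
    """Resample a square slice to target x target pixels.

    Downscaling uses anti-aliased (area-averaging-like) interpolation so the
    thin spine is not aliased away; upscaling is plain bilinear. Intensities
    are re-quantized to the slice's unit and the spacing is rescaled by the
    size ratio.
    """
    n = slice_.grid_size
    if slice_.pixels.shape[0] != slice_.pixels.shape[1]:
        raise ValueError("resample expects a square slice")
    if target < 8:
        raise ValueError("target grid must be at least 8 pixels")
    src = slice_.pixels.astype(np.float64)
    out = _sk_resize(src, (target, target), order=1,
                     anti_aliasing=target < n, preserve_range=True)
    spacing = slice_.spacing * n / target
    if slice_.unit == "gray8":
        out = np.clip(np.round(out), 0, 255).astype(np.uint8)
    elif slice_.unit == "normalized01":
        out = np.clip(out, 0.0, 1.0).astype(np.float32)
    return CTSlice(out, spacing, slice_.unit)


def hu_to_gray8(slice_: CTSlice, window: tuple[float, float] = DEFAULT_HU_WINDOW) -> CTSlice:
    """Linear HU window onto the 8-bit range."""
    if slice_.unit != "hounsfield":
        raise ValueError("hu_to_gray8 expects a hounsfield slice")
    lo, hi = window
    g = (slice_.pixels.astype(np.float64) - lo) / (hi - lo) * 255.0
    return CTSlice(np.clip(np.round(g), 0, 255).astype(np.uint8),
                   slice_.spacing, "gray8")


def water_gray(window: tuple[float, float] = DEFAULT_HU_WINDOW) -> int:
    """Gray level of water (0 HU) under a given window."""
    lo, hi = window
    return int(np.clip(np.round((0.0 - lo) / (hi - lo) * 255.0), 0, 255))


def read_dicom_slice(path) -> CTSlice:
    """Read one CT slice; RescaleSlope/Intercept are applied to yield HU."""
    import pydicom

    ds = pydicom.dcmread(path)
    arr = ds.pixel_array.astype(np.float64)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    hu = arr * slope + intercept
    spacing = float(ds.PixelSpacing[0]) if hasattr(ds, "PixelSpacing") else 1.0
    return CTSlice(hu, spacing, "hounsfield")


def write_dicom_slice(slice_: CTSlice, path) -> None:
    """Write a minimal CT DICOM (int16 stored values, slope 1 / intercept
    -1024) — used for round-trip testing and demo input."""
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    if slice_.unit != "hounsfield":
        raise ValueError("write_dicom_slice expects hounsfield data")
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\x00" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "CT"
    ds.Rows, ds.Columns = slice_.pixels.shape
    ds.PixelSpacing = [slice_.spacing, slice_.spacing]
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 1
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.RescaleSlope = 1.0
    ds.RescaleIntercept = -1024.0
    stored = np.round(slice_.pixels - ds.RescaleIntercept).astype(np.int16)
    ds.PixelData = stored.tobytes()
    ds.save_as(str(path), enforce_file_format=True)
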