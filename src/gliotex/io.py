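"""Image and ROI-mask loading, validation, and gray-level quantization.

A case is a single 2D slice (row-major, origin top-left) plus a binary
tumor mask of the same shape.  Only in-mask pixels participate in feature
extraction; masks are thresholded at nonzero and stored as booleans.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np


class FormatError(ValueError):
    """Raised when an image file cannot be read in the requested format."""


class GeometryError(ValueError):
    """Raised on shape mismatches between image and mask, or ROI vs image."""


class EmptyRoiError(ValueError):
    """Raised when a mask selects no pixels."""


@dataclass
class RoiImage:
    """A 2D intensity grid with an optional same-shape binary tumor mask.

    Parameters
    ----------
    pixels : ndarray, shape (H, W)
        Intensity values in scanner units (finite, any non-negative scale).
    mask : ndarray of bool, shape (H, W), optional
        True inside the tumor ROI.  Must select at least one pixel.
    case_id : str
        Opaque case label carried through the feature table.
    """

    pixels: np.ndarray
    mask: Optional[np.ndarray] = None
    case_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise GeometryError(
                f"expected a 2D image, got shape {self.pixels.shape}"
            )
        if self.mask is not None:
            self.mask = np.asarray(self.mask) != 0
            if self.mask.shape != self.pixels.shape:
                raise GeometryError(
                    f"mask shape {self.mask.shape} != image shape "
                    f"{self.pixels.shape}"
                )
            n = int(self.mask.sum())
            if n == 0:
                raise EmptyRoiError(f"mask of case {self.case_id!r} is empty")
            if n == 1:
                warnings.warn(
                    f"case {self.case_id!r}: single-pixel ROI", stacklevel=2
                )
            if not np.all(np.isfinite(self.pixels[self.mask])):
                raise ValueError(
                    f"case {self.case_id!r}: non-finite intensities in ROI"
                )

    @property
    def n_roi(self) -> int:
        if self.mask is None:
            raise ValueError("no mask attached")
        return int(self.mask.sum())


@dataclass
class QuantizedRoi:
    """ROI re-binned to ``n_levels`` integer gray levels for GLCM analysis.

    ``levels`` holds bin indices in [0, n_levels-1]; values outside the mask
    are set to 0 but carry no meaning.  ``degenerate`` marks a constant ROI
    (all intensities equal), in which case every level is 0.
    """

    levels: np.ndarray
    n_levels: int
    mask: np.ndarray
    degenerate: bool = False
    case_id: str = ""


def _read_png_tiff(path: Path) -> np.ndarray:
    from PIL import Image

    with Image.open(path) as im:
        if im.mode in ("RGB", "RGBA", "P", "CMYK", "YCbCr"):
            raise FormatError(
                f"{path}: multi-channel image; grayscale input required"
            )
        arr = np.asarray(im)
    if arr.ndim != 2:
        raise FormatError(f"{path}: expected 2D grayscale, got {arr.shape}")
    return arr


def _read_nifti(path: Path, slice_index: Optional[int]) -> np.ndarray:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data)
    if data.ndim == 3:
        if slice_index is None:
            raise GeometryError(
                f"{path}: 3D volume; a slice index is required"
            )
        if not 0 <= slice_index < data.shape[2]:
            raise GeometryError(
                f"{path}: slice {slice_index} out of range "
                f"[0, {data.shape[2]})"
            )
        data = data[:, :, slice_index]
    if data.ndim != 2:
        raise GeometryError(f"{path}: cannot reduce shape {data.shape} to 2D")
    return data


def _read_dicom(path: Path) -> np.ndarray:
    import pydicom

    ds = pydicom.dcmread(str(path))
    arr = ds.pixel_array
    if arr.ndim == 3:
        raise GeometryError(f"{path}: multi-frame DICOM; supply a single slice")
    return arr


_SUFFIX_FORMAT = {
    ".png": "png",
    ".tif": "tiff",
    ".tiff": "tiff",
    ".dcm": "dicom",
    ".nii": "nifti",
}


def _sniff_format(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".nii.gz"):
        return "nifti"
    fmt = _SUFFIX_FORMAT.get(path.suffix.lower())
    if fmt is None:
        raise FormatError(f"cannot infer format of {path}")
    return fmt


def load_image(
    path,
    fmt: str = "auto",
    slice_index: Optional[int] = None,
    case_id: Optional[str] = None,
) -> RoiImage:
    """Load a 2D grayscale image (mask not attached).

    Parameters
    ----------
    path : path-like
        File in DICOM, NIfTI (.nii/.nii.gz) or PNG/TIFF format.
    fmt : {'auto', 'dicom', 'nifti', 'png', 'tiff'}
        'auto' sniffs from the file suffix.
    slice_index : int, optional
        Required for 3D NIfTI volumes; selects the axial plane
        ``data[:, :, slice_index]``.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if fmt == "auto":
        fmt = _sniff_format(path)
    try:
        if fmt in ("png", "tiff"):
            arr = _read_png_tiff(path)
        elif fmt == "nifti":
            arr = _read_nifti(path, slice_index)
        elif fmt == "dicom":
            arr = _read_dicom(path)
        else:
            raise FormatError(f"unknown format {fmt!r}")
    except GeometryError:
        raise
    except FormatError:
        raise
    except Exception as exc:  # unreadable / corrupt file
        raise FormatError(f"cannot read {path} as {fmt}: {exc}") from exc
    return RoiImage(pixels=arr, case_id=case_id or path.stem)


def attach_mask(image: RoiImage, mask_path, fmt: str = "auto",
                slice_index: Optional[int] = None) -> RoiImage:
    """Return a copy of ``image`` with the mask at ``mask_path`` attached.

    Any nonzero pixel of the mask file counts as inside the ROI.  The mask
    must match the image shape exactly and select at least one pixel.
    """
    mask_img = load_image(mask_path, fmt=fmt, slice_index=slice_index)
    return RoiImage(pixels=image.pixels, mask=mask_img.pixels != 0,
                    case_id=image.case_id)


def roi_pixels(image: RoiImage) -> np.ndarray:
    """In-mask intensities in fixed row-major order.

    The returned length equals the mask cardinality N; this is the pixel
    set every histogram moment is computed from.
    """
    if image.mask is None:
        raise ValueError("no mask attached; call attach_mask first")
    return image.pixels[image.mask]


def quantize(image: RoiImage, n_levels: int = 64) -> QuantizedRoi:
    """Re-bin ROI intensities to ``n_levels`` uniform-width gray levels.

    Bins span the ROI's own [min, max] (per-case contrast normalization):
    the minimum maps to level 0, the maximum to ``n_levels - 1``, and each
    bin is right-closed so a value on an interior edge falls in the lower
    bin.  A constant ROI maps to all-zero levels and is flagged degenerate.
    """
    if n_levels < 2:
        raise ValueError(f"n_levels must be >= 2, got {n_levels}")
    vals = roi_pixels(image).astype(float)
    lo, hi = vals.min(), vals.max()
    levels = np.zeros(image.pixels.shape, dtype=np.intp)
    if hi == lo:
        return QuantizedRoi(levels=levels, n_levels=n_levels, mask=image.mask,
                            degenerate=True, case_id=image.case_id)
    scaled = n_levels * (image.pixels.astype(float) - lo) / (hi - lo)
    binned = np.clip(np.ceil(scaled) - 1, 0, n_levels - 1).astype(np.intp)
    levels[image.mask] = binned[image.mask]
    return QuantizedRoi(levels=levels, n_levels=n_levels, mask=image.mask,
                        degenerate=False, case_id=image.case_id)


def save_image(arr: np.ndarray, path) -> None:
    """Write a 2D array as 16-bit PNG/TIFF or NIfTI, by suffix."""
    path = Path(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float64), np.eye(4)),
                 str(path))
    else:
        from PIL import Image

        a = np.asarray(arr)
        if a.dtype.kind == "f":
            a = np.round(np.clip(a, 0, 65535)).astype(np.uint16)
        else:
            a = a.astype(np.uint16)
        Image.fromarray(a).save(path)
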