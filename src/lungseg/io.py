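"""Image and mask I/O.

Single-frame grayscale input from DICOM (rescale slope/intercept applied)
or 8/16-bit raster formats (PNG/TIFF), normalized onto [0, 1] by a linear
min-max map; binary masks round-trip losslessly through 8-bit PNG with
foreground 255.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from ._validation import check_mask

__all__ = ["load_image", "save_mask", "load_mask"]


class UnsupportedInputError(ValueError):
    """Multi-frame, color, or otherwise non-2-D-grayscale input."""


def _normalize(arr: np.ndarray) -> tuple[np.ndarray, tuple[float, float]]:
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        warnings.warn(
            "constant image has zero dynamic range; normalizing to all zeros",
            stacklevel=3,
        )
        return np.zeros_like(arr, dtype=np.float64), (lo, hi)
    return (arr.astype(np.float64) - lo) / (hi - lo), (lo, hi)


def _read_dicom(path: Path) -> np.ndarray:
    import pydicom

    ds = pydicom.dcmread(path)
    arr = ds.pixel_array
    if arr.ndim != 2:
        raise UnsupportedInputError(
            f"expected a single-frame grayscale DICOM, got shape {arr.shape}"
        )
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    return arr.astype(np.float64) * slope + intercept


def _read_raster(path: Path) -> np.ndarray:
    arr = iio.imread(path)
    if arr.ndim == 3 and arr.shape[2] == 1:
        arr = arr[:, :, 0]
    if arr.ndim != 2:
        raise UnsupportedInputError(
            f"expected a single 2-D grayscale frame, got shape {arr.shape}"
        )
    return arr.astype(np.float64)


def load_image(path, modality: str | None = None, return_range: bool = False):
    """Load a single-frame grayscale image, rescaled linearly to [0, 1].

    Parameters
    ----------
    path : path-like
    modality : {'dicom', 'raster'} or None
        Inferred from the suffix (.dcm -> dicom) when None.
    return_range : bool
        Also return the original (min, max) for round-tripping.
    """
    path = Path(path)
    if modality is None:
        modality = "dicom" if path.suffix.lower() in (".dcm", ".dicom") else "raster"
    if modality == "dicom":
        arr = _read_dicom(path)
    elif modality == "raster":
        arr = _read_raster(path)
    else:
        raise ValueError(f"unknown modality {modality!r}")
    img, rng = _normalize(arr)
    return (img, rng) if return_range else img


def save_mask(mask, path) -> None:
    """Write a binary mask as 8-bit PNG (foreground 255, background 0)."""
    mask = check_mask(mask)
    iio.imwrite(Path(path), (mask * 255).astype(np.uint8))


def load_mask(path) -> np.ndarray:
    """Read a binary mask PNG; any value above 127 is foreground."""
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        arr = arr[:, :, 0]
    return (arr > 127).astype(np.uint8)
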