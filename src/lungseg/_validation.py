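"""Shared input validation for image-shaped arrays and filter parameters."""

from __future__ import annotations

import numpy as np


def check_image(img, *, name: str = "image") -> np.ndarray:
    """Validate a 2-D grayscale image with finite intensities in [0, 1].

    Returns a float64 C-contiguous copy-free view where possible.
    """
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be 2-D, got shape {arr.shape}")
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError(f"{name} must be non-empty, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise ValueError(
            f"{name} intensities must lie in [0, 1]; "
            f"got range [{arr.min():.4g}, {arr.max():.4g}]"
        )
    return arr


def check_mask(mask, *, name: str = "mask") -> np.ndarray:
    """Validate a 2-D binary mask with values in {0, 1}; returns uint8."""
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be 2-D, got shape {arr.shape}")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} values must be 0 or 1")
    return arr.astype(np.uint8)


def check_window(window: int, *, name: str = "window", minimum: int = 3) -> int:
    window = int(window)
    if window < minimum or window % 2 == 0:
        raise ValueError(f"{name} must be an odd integer >= {minimum}, got {window}")
    return window
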