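"""Noise removal and contrast enhancement for grayscale CT slices.

Three speckle/impulse filters (median, two-stage adaptive median, average)
and two contrast enhancers (global histogram equalization and CLAHE). All
operate on 2-D images with intensities in [0, 1] and preserve shape.
Windowed filters replicate edge pixels at the borders, so every window is
full-sized and no dark halo is introduced at the image boundary.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage import exposure
from sklearn.base import BaseEstimator, TransformerMixin

from ._validation import check_image, check_window

__all__ = [
    "MedianFilter",
    "AdaptiveMedianFilter",
    "AverageFilter",
    "HistogramEqualizer",
    "CLAHE",
    "median_filter",
    "adaptive_median_filter",
    "average_filter",
    "global_hist_equalize",
    "clahe",
]


class _ImageTransformer(TransformerMixin, BaseEstimator):
    """Base class: stateless transformers over single 2-D images."""

    def fit(self, X, y=None):
        self._validate_params_()
        check_image(X)
        return self

    def transform(self, X):
        self._validate_params_()
        return self._apply(check_image(X))

    def _validate_params_(self):  # pragma: no cover - overridden
        pass

    def _apply(self, img):  # pragma: no cover - overridden
        raise NotImplementedError


class MedianFilter(_ImageTransformer):
    """Replace each pixel by the median of its ``window`` x ``window``
    neighborhood (edge-replicated). A 3x3 window is the classical choice
    for speckle suppression on CT.

    Parameters
    ----------
    window : int, default=3
        Odd neighborhood side length in pixels, >= 3.
    """

    def __init__(self, window: int = 3):
        self.window = window

    def _validate_params_(self):
        check_window(self.window)

    def _apply(self, img):
        return ndimage.median_filter(img, size=self.window, mode="nearest")


class AverageFilter(_ImageTransformer):
    """Replace each pixel by the arithmetic mean of its neighborhood
    (edge-replicated borders).

    Parameters
    ----------
    window : int, default=3
        Odd neighborhood side length in pixels, >= 3.
    """

    def __init__(self, window: int = 3):
        self.window = window

    def _validate_params_(self):
        check_window(self.window)

    def _apply(self, img):
        out = ndimage.uniform_filter(img, size=self.window, mode="nearest")
        # uniform_filter accumulates in floats; clip away 1-ulp excursions
        return np.clip(out, 0.0, 1.0)


class AdaptiveMedianFilter(_ImageTransformer):
    """Two-stage adaptive median filter for impulse (salt-and-pepper) noise.

    For each pixel, stage A grows the window from ``window`` up to ``smax``
    while the window median is an extreme of the window (equal to its min
    or max), i.e. while the median itself looks like an impulse. Stage B
    then outputs the original pixel if it is not an extreme of the final
    window, otherwise the window median. Non-impulse pixels are therefore
    passed through exactly, which is what lets this filter keep edges and
    fine structure that the plain median blurs.

    Parameters
    ----------
    window : int, default=3
        Initial odd window size.
    smax : int, default=7
        Maximum odd window size, >= ``window``.
    """

    def __init__(self, window: int = 3, smax: int = 7):
        self.window = window
        self.smax = smax

    def _validate_params_(self):
        check_window(self.window)
        check_window(self.smax, name="smax")
        if self.smax < self.window:
            raise ValueError(
                f"smax ({self.smax}) must be >= window ({self.window})"
            )

    def _apply(self, img):
        sizes = list(range(self.window, self.smax + 1, 2))
        h, w = img.shape
        # per-pixel window size index chosen by stage A; the med/min/max of
        # the chosen window, gathered as stage A resolves
        chosen = np.zeros((h, w), dtype=bool)
        med_f = np.empty_like(img)
        min_f = np.empty_like(img)
        max_f = np.empty_like(img)
        for i, s in enumerate(sizes):
            med = ndimage.median_filter(img, size=s, mode="nearest")
            mn = ndimage.minimum_filter(img, size=s, mode="nearest")
            mx = ndimage.maximum_filter(img, size=s, mode="nearest")
            interior = (med > mn) & (med < mx)  # median not an extreme
            take = (~chosen) & (interior | (i == len(sizes) - 1))
            med_f[take] = med[take]
            min_f[take] = mn[take]
            max_f[take] = mx[take]
            chosen |= take
            if chosen.all():
                break
        keep = (img > min_f) & (img < max_f)  # stage B: pixel not an extreme
        return np.where(keep, img, med_f)


class HistogramEqualizer(_ImageTransformer):
    """Global histogram equalization: each pixel is mapped to an intensity
    proportional to its rank (cumulative histogram mass) among all pixels.

    Parameters
    ----------
    levels : int, default=256
        Number of histogram bins used for the cumulative mapping.
    """

    def __init__(self, levels: int = 256):
        self.levels = levels

    def _validate_params_(self):
        if int(self.levels) < 2:
            raise ValueError(f"levels must be >= 2, got {self.levels}")

    def _apply(self, img):
        if img.max() == img.min():
            return img.copy()  # constant image: nothing to equalize
        return exposure.equalize_hist(img, nbins=int(self.levels))


class CLAHE(_ImageTransformer):
    """Contrast-limited adaptive histogram equalization.

    The image is tiled, each tile's histogram is clipped at ``clip`` (a
    fraction of the tile's pixel count) with the excess redistributed,
    and per-tile equalization mappings are bilinearly interpolated.

    Parameters
    ----------
    tiles : tuple of int, default=(8, 8)
        Tile grid as (rows, cols); each >= 1.
    clip : float, default=0.01
        Clip limit in (0, 1], as a fraction of tile pixels.
    """

    def __init__(self, tiles: tuple[int, int] = (8, 8), clip: float = 0.01):
        self.tiles = tiles
        self.clip = clip

    def _validate_params_(self):
        r, c = self.tiles
        if int(r) < 1 or int(c) < 1:
            raise ValueError(f"tiles must each be >= 1, got {self.tiles}")
        if not (0.0 < float(self.clip) <= 1.0):
            raise ValueError(f"clip must be in (0, 1], got {self.clip}")

    def _apply(self, img):
        if img.max() == img.min():
            return img.copy()
        r, c = int(self.tiles[0]), int(self.tiles[1])
        kernel = (max(1, img.shape[0] // r), max(1, img.shape[1] // c))
        out = exposure.equalize_adapthist(
            img, kernel_size=kernel, clip_limit=float(self.clip)
        )
        return np.clip(out, 0.0, 1.0)


def median_filter(img, window: int = 3) -> np.ndarray:
    """Median-filter ``img`` with an odd ``window`` (edge replication)."""
    return MedianFilter(window=window).transform(img)


def adaptive_median_filter(img, window: int = 3, smax: int = 7) -> np.ndarray:
    """Two-stage adaptive median filter; see :class:`AdaptiveMedianFilter`."""
    return AdaptiveMedianFilter(window=window, smax=smax).transform(img)


def average_filter(img, window: int = 3) -> np.ndarray:
    """Mean-filter ``img`` with an odd ``window`` (edge replication)."""
    return AverageFilter(window=window).transform(img)


def global_hist_equalize(img, levels: int = 256) -> np.ndarray:
    """Global histogram equalization onto [0, 1]."""
    return HistogramEqualizer(levels=levels).transform(img)


def clahe(img, tiles: tuple[int, int] = (8, 8), clip: float = 0.01) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization; see :class:`CLAHE`."""
    return CLAHE(tiles=tiles, clip=clip).transform(img)
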