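"""Radiograph cleanup: Gaussian smoothing, 3x3 median, contrast stretch.

The three operators preserve shape and the 8-bit intensity range, and are
applied in the order Gaussian -> median -> stretch by the pipeline (each
is independently callable).  Both filters use reflect boundary handling;
the stretch uses linearly interpolated quantiles (``numpy.quantile``
default convention) as its documented tail rule.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .image import GRAY_LEVELS, as_gray_image, clip_to_gray


def gaussian_smooth(img: np.ndarray, sigma: float = 1.0) -> np.ndarray:
    """Convolve with a normalized 2-D Gaussian (radius ``ceil(3*sigma)``).

    The result is rounded to the nearest integer and clipped to the 8-bit
    range.  ``sigma == 0`` returns the input unchanged.
    """
    img = as_gray_image(img)
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    if sigma == 0:
        return img.copy()
    radius = int(np.ceil(3 * sigma))
    smoothed = ndimage.gaussian_filter(
        img.astype(np.float64), sigma=sigma, mode="reflect", radius=radius
    )
    return clip_to_gray(smoothed)


def median_filter3x3(img: np.ndarray) -> np.ndarray:
    """Replace each pixel by the median of its 3x3 neighborhood.

    Reflect padding at borders; the median of 9 integers is the 5th order
    statistic, so no averaging occurs and values stay in range.
    """
    img = as_gray_image(img)
    return ndimage.median_filter(img, size=3, mode="reflect")


def contrast_stretch(
    img: np.ndarray, low_frac: float = 0.01, high_frac: float = 0.01
) -> np.ndarray:
    """Percentile-based linear intensity stretch (imadjust-style).

    The ``low_frac`` quantile maps to 0 and the ``1 - high_frac`` quantile
    to ``L-1``; values outside are clipped.  Quantiles use linear
    interpolation between order statistics.  A degenerate image in which
    both quantiles coincide maps to constant mid-gray.
    """
    img = as_gray_image(img)
    if low_frac < 0 or high_frac < 0 or low_frac + high_frac >= 1:
        raise ValueError(
            f"fractions must satisfy 0 <= low, high and low + high < 1; "
            f"got low={low_frac}, high={high_frac}"
        )
    pixels = img.astype(np.float64)
    lo = float(np.quantile(pixels, low_frac))
    hi = float(np.quantile(pixels, 1.0 - high_frac))
    if lo == hi:
        return np.full_like(img, (GRAY_LEVELS - 1) // 2)
    stretched = (pixels - lo) / (hi - lo) * (GRAY_LEVELS - 1)
    return clip_to_gray(stretched)


def preprocess_image(
    img: np.ndarray,
    sigma: float = 1.0,
    low_frac: float = 0.01,
    high_frac: float = 0.01,
) -> np.ndarray:
    """Full cleanup chain: Gaussian smooth, 3x3 median, contrast stretch."""
    return contrast_stretch(
        median_filter3x3(gaussian_smooth(img, sigma)), low_frac, high_frac
    )
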