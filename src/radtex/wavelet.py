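"""Separable 2-D filter-bank wavelet decomposition and coefficient stats.

One analysis level filters the rows of the input with the low-pass and
high-pass filters and downsamples by two, then repeats on the columns of
each half, yielding four quarter-size subbands: the approximation ``LL``
and the detail bands ``LH`` (column high-pass), ``HL`` (row high-pass)
and ``HH``.  Boundary extension is periodic, so with the default
orthonormal Haar pair ``H = (1, 1)/sqrt(2)``, ``G = (1, -1)/sqrt(2)`` the
transform is orthogonal: energy is conserved and the adjoint is the
exact inverse.

The feature vector pools every detail coefficient across all levels and
orientations into one sample and reports its mean, standard deviation,
skewness, excess kurtosis and mean absolute deviation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

#: Fixed order of the 5 wavelet features.
WAVELET_FEATURE_NAMES = ("mean", "sd", "skewness", "kurtosis", "mad")


@dataclass(frozen=True)
class FilterPair:
    """Analysis low-pass/high-pass pair of a two-channel filter bank."""

    low: np.ndarray
    high: np.ndarray
    name: str = "custom"


_SQRT2 = np.sqrt(2.0)
HAAR = FilterPair(
    low=np.array([1.0, 1.0]) / _SQRT2,
    high=np.array([1.0, -1.0]) / _SQRT2,
    name="haar",
)


@dataclass(frozen=True)
class WaveletDecomposition:
    """Per-level detail subbands plus the deepest approximation band.

    ``details[k]`` holds the ``(LH, HL, HH)`` triple of level ``k + 1``;
    subband shapes halve per level.
    """

    details: tuple[tuple[np.ndarray, np.ndarray, np.ndarray], ...]
    approximation: np.ndarray
    filter_pair: FilterPair

    @property
    def levels(self) -> int:
        return len(self.details)

    def detail_coefficients(self) -> np.ndarray:
        """All detail coefficients pooled into one flat sample."""
        return np.concatenate(
            [band.ravel() for triple in self.details for band in triple]
        )


def _analyze(x: np.ndarray, filt: np.ndarray, axis: int) -> np.ndarray:
    """Periodic filter-and-downsample along *axis*: y_k = sum_m f_m x_{2k+m}."""
    n = x.shape[axis]
    half = n // 2
    idx = (2 * np.arange(half)[:, None] + np.arange(len(filt))[None, :]) % n
    taken = np.take(x, idx.ravel(), axis=axis)
    new_shape = list(x.shape)
    new_shape[axis : axis + 1] = [half, len(filt)]
    taken = taken.reshape(new_shape)
    f = filt.reshape([-1 if a == axis + 1 else 1 for a in range(taken.ndim)])
    return (taken * f).sum(axis=axis + 1)


def _synthesize(y: np.ndarray, filt: np.ndarray, n: int, axis: int) -> np.ndarray:
    """Adjoint of :func:`_analyze`: upsample and filter back to length *n*."""
    y = np.moveaxis(y, axis, 0)
    out = np.zeros((n,) + y.shape[1:], dtype=np.float64)
    for m, fm in enumerate(filt):
        pos = (2 * np.arange(y.shape[0]) + m) % n
        np.add.at(out, pos, fm * y)
    return np.moveaxis(out, 0, axis)


def dwt2_single_level(
    A: np.ndarray, filter_pair: FilterPair = HAAR
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """One analysis level; returns ``(LL, LH, HL, HH)``.

    Rows are filtered and downsampled first, then columns; both input
    dimensions must be even.
    """
    A = np.asarray(A, dtype=np.float64)
    if A.ndim != 2:
        raise ValueError(f"expected a 2-D array, got ndim={A.ndim}")
    h, w = A.shape
    if h % 2 or w % 2:
        raise ValueError(f"both dimensions must be even, got {A.shape}")
    lo, hi = filter_pair.low, filter_pair.high
    lr = _analyze(A, lo, axis=1)
    hr = _analyze(A, hi, axis=1)
    ll = _analyze(lr, lo, axis=0)
    lh = _analyze(lr, hi, axis=0)
    hl = _analyze(hr, lo, axis=0)
    hh = _analyze(hr, hi, axis=0)
    return ll, lh, hl, hh


def idwt2_single_level(
    bands: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray],
    filter_pair: FilterPair = HAAR,
) -> np.ndarray:
    """Exact inverse of :func:`dwt2_single_level` for orthonormal pairs."""
    ll, lh, hl, hh = (np.asarray(b, dtype=np.float64) for b in bands)
    lo, hi = filter_pair.low, filter_pair.high
    h2, w2 = ll.shape
    lr = _synthesize(ll, lo, 2 * h2, axis=0) + _synthesize(lh, hi, 2 * h2, axis=0)
    hr = _synthesize(hl, lo, 2 * h2, axis=0) + _synthesize(hh, hi, 2 * h2, axis=0)
    return _synthesize(lr, lo, 2 * w2, axis=1) + _synthesize(hr, hi, 2 * w2, axis=1)


def decompose(
    A: np.ndarray, levels: int = 3, filter_pair: FilterPair = HAAR
) -> WaveletDecomposition:
    """Recursive multi-level decomposition of the approximation band.

    Dimensions not divisible by ``2 ** levels`` are zero-padded up to the
    next multiple, with a warning (the default 40x40 window needs none
    for ``levels <= 3``).
    """
    A = np.asarray(A, dtype=np.float64)
    if A.ndim != 2:
        raise ValueError(f"expected a 2-D array, got ndim={A.ndim}")
    if levels < 1:
        raise ValueError(f"levels must be >= 1, got {levels}")
    block = 2**levels
    h, w = A.shape
    pad_h = (-h) % block
    pad_w = (-w) % block
    if pad_h or pad_w:
        feasible = 0
        hh, ww = h, w
        while hh % 2 == 0 and ww % 2 == 0 and feasible < levels:
            feasible += 1
            hh //= 2
            ww //= 2
        warnings.warn(
            f"shape {A.shape} is not divisible by 2**{levels} "
            f"(maximum unpadded level: {feasible}); zero-padding to "
            f"{(h + pad_h, w + pad_w)}"
        )
        A = np.pad(A, ((0, pad_h), (0, pad_w)))
    details = []
    approx = A
    for _ in range(levels):
        approx, lh, hl, hh_band = dwt2_single_level(approx, filter_pair)
        details.append((lh, hl, hh_band))
    return WaveletDecomposition(
        details=tuple(details), approximation=approx, filter_pair=filter_pair
    )


def wavelet_feature_vector(
    patch: np.ndarray, levels: int = 3, filter_pair: FilterPair = HAAR
) -> dict[str, float]:
    """Five statistics of the pooled detail coefficients, in fixed order.

    Mean, standard deviation, skewness (Fisher, bias-uncorrected), excess
    kurtosis, and mean absolute deviation.  A zero-variance coefficient
    sample yields skewness and kurtosis of 0 (with a warning).
    """
    coeffs = decompose(np.asarray(patch, dtype=np.float64), levels, filter_pair)
    sample = coeffs.detail_coefficients()
    mean = float(sample.mean())
    centered = sample - mean
    m2 = float((centered**2).mean())
    sd = float(np.sqrt(m2))
    if m2 == 0:
        warnings.warn("zero-variance detail coefficients: skewness/kurtosis set to 0")
        skewness = kurtosis = 0.0
    else:
        skewness = float((centered**3).mean() / m2**1.5)
        kurtosis = float((centered**4).mean() / m2**2 - 3.0)
    mad = float(np.abs(centered).mean())
    return {
        "mean": mean,
        "sd": sd,
        "skewness": skewness,
        "kurtosis": kurtosis,
        "mad": mad,
    }
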