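"""Grayscale image container helpers.

Throughout the package a grayscale image is a 2-D ``numpy.ndarray`` of
unsigned 8-bit integers (intensities in ``[0, L-1]`` with ``L = 256``).
These helpers centralize validation and PNG round-tripping so that every
stage shares one pixel contract.
"""

from __future__ import annotations

import os

import numpy as np
from PIL import Image

#: Number of gray levels of the canonical 8-bit image.
GRAY_LEVELS = 256


def as_gray_image(pixels: np.ndarray, *, bit_depth: int = GRAY_LEVELS) -> np.ndarray:
    """Validate *pixels* as a grayscale image and return it as ``uint8``.

    Parameters
    ----------
    pixels:
        2-D array of integer intensities.
    bit_depth:
        Number of representable levels ``L``; intensities must lie in
        ``[0, L-1]``.

    Raises
    ------
    ValueError
        If the array is not 2-D, is empty, or holds out-of-range values.
    """
    arr = np.asarray(pixels)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got ndim={arr.ndim}")
    if arr.size == 0:
        raise ValueError("image must contain at least one pixel")
    if np.issubdtype(arr.dtype, np.floating):
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("image intensities must be integers")
        arr = np.round(arr).astype(np.int64)
    if arr.min() < 0 or arr.max() > bit_depth - 1:
        raise ValueError(
            f"intensities must lie in [0, {bit_depth - 1}], "
            f"found range [{arr.min()}, {arr.max()}]"
        )
    return arr.astype(np.uint8)


def clip_to_gray(values: np.ndarray, *, bit_depth: int = GRAY_LEVELS) -> np.ndarray:
    """Round *values* to nearest integer, clip to ``[0, L-1]``, cast to uint8."""
    return np.clip(np.round(values), 0, bit_depth - 1).astype(np.uint8)


def read_png(path: str | os.PathLike) -> np.ndarray:
    """Read an 8-bit grayscale PNG/TIFF into a validated image array."""
    with Image.open(path) as im:
        return as_gray_image(np.asarray(im.convert("L")))


def write_png(path: str | os.PathLike, pixels: np.ndarray) -> None:
    """Write a validated grayscale image as an 8-bit PNG."""
    Image.fromarray(as_gray_image(pixels), mode="L").save(path)
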