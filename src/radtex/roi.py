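"""Fixed-size analysis-window extraction and regional-maxima QA mask."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image import as_gray_image

#: Side length of the default analysis window.
DEFAULT_ROI_SIZE = 40

_EIGHT_CONN = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class ROIPatch:
    """A size x size window cropped around a lesion (or background) center.

    For even ``size`` the window spans rows ``center_row - size/2`` through
    ``center_row + size/2 - 1`` (likewise columns), i.e. the center sits at
    index ``size // 2`` within the patch.
    """

    pixels: np.ndarray
    source_image_id: str
    label: str
    center: tuple[int, int]

    @property
    def size(self) -> int:
        return self.pixels.shape[0]


def extract_roi(
    img: np.ndarray,
    center: tuple[int, int],
    size: int = DEFAULT_ROI_SIZE,
    *,
    image_id: str = "",
    label: str = "",
) -> ROIPatch:
    """Crop the ``size x size`` window centered at ``center``.

    Raises ``ValueError`` (with the offending coordinates) if the window
    does not lie fully inside the image — there is no silent clamping.
    """
    img = as_gray_image(img)
    if size < 1:
        raise ValueError(f"size must be >= 1, got {size}")
    h, w = img.shape
    row, col = center
    half = size // 2
    r0, c0 = row - half, col - half
    r1, c1 = r0 + size, c0 + size
    if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
        raise ValueError(
            f"window rows [{r0}, {r1}) x cols [{c0}, {c1}) around center "
            f"({row}, {col}) falls outside the {h}x{w} image"
        )
    return ROIPatch(
        pixels=img[r0:r1, c0:c1].copy(),
        source_image_id=image_id,
        label=label,
        center=(row, col),
    )


def embed_roi(img: np.ndarray, patch: ROIPatch) -> np.ndarray:
    """Paste *patch* back at its center; inverse of :func:`extract_roi`."""
    out = as_gray_image(img).copy()
    size = patch.size
    half = size // 2
    r0 = patch.center[0] - half
    c0 = patch.center[1] - half
    out[r0 : r0 + size, c0 : c0 + size] = patch.pixels
    return out


def regional_maxima(img: np.ndarray) -> np.ndarray:
    """Boolean mask of regional maxima plateaus (8-connectivity).

    A plateau — a connected component of equal-valued pixels — is marked
    when its value is strictly greater than every pixel 8-adjacent to the
    component.  A constant image is a single plateau with no external
    neighbors and is marked entirely.

    Visualization/QA aid; not part of the feature-extraction path.
    """
    img = as_gray_image(img)
    # A pixel is "dominated" when some 8-neighbor is strictly brighter.
    dilated = ndimage.grey_dilation(img, footprint=_EIGHT_CONN, mode="nearest")
    dominated = dilated > img
    mask = np.zeros(img.shape, dtype=bool)
    for value in np.unique(img):
        level = img == value
        labels, n = ndimage.label(level, structure=_EIGHT_CONN)
        if n == 0:
            continue
        bad = np.unique(labels[level & dominated])
        keep = np.setdiff1d(np.arange(1, n + 1), bad)
        if keep.size:
            mask |= np.isin(labels, keep)
    return mask
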