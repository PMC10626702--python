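"""Gray-level run-length matrices and the seven run-emphasis features.

``R(i, l)`` counts the maximal runs of quantized level ``i`` with length
``l`` along one direction (rows for 0 deg, columns for 90 deg, the two
diagonal families for 45/135 deg).  Every pixel belongs to exactly one
maximal run, so ``sum_i sum_l l * R(i, l)`` equals the pixel count.

Feature formulas follow Galloway's run-length statistics with the Chu
low/high gray-level extensions; emphasis weights use 1-based gray-level
and run-length indices (0-based levels would divide by zero in the
low-gray-level emphasis).  Features are averaged over the four
directions and returned in the fixed order SRE, LRE, GLN, RLN, RP,
LGRE, HGRE.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .texture_glcm import quantize

#: Supported scan directions in degrees.
DIRECTIONS = (0, 45, 90, 135)

#: Fixed order of the 7 run-length features.
GLRLM_FEATURE_NAMES = (
    "short_run_emphasis",
    "long_run_emphasis",
    "gray_level_nonuniformity",
    "run_length_nonuniformity",
    "run_percentage",
    "low_gray_level_run_emphasis",
    "high_gray_level_run_emphasis",
)


@dataclass(frozen=True)
class RunLengthMatrix:
    """G x Rmax run counts along one direction."""

    R: np.ndarray
    direction: int
    n_pixels: int

    @property
    def n_runs(self) -> int:
        return int(self.R.sum())


def _lines(patch: np.ndarray, direction: int) -> list[np.ndarray]:
    h, w = patch.shape
    if direction == 0:
        return [patch[r] for r in range(h)]
    if direction == 90:
        return [patch[:, c] for c in range(w)]
    if direction == 135:
        src = patch
    elif direction == 45:
        src = np.flipud(patch)
    else:
        raise ValueError(f"direction must be one of {DIRECTIONS}, got {direction}")
    return [np.diagonal(src, offset=k) for k in range(-(h - 1), w)]


def _run_lengths(line: np.ndarray) -> list[tuple[int, int]]:
    """Run-length encode one scan line into (level, length) pairs."""
    if line.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(line) != 0)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks + 1, [line.size]))
    return [(int(line[s]), int(e - s)) for s, e in zip(starts, ends)]


def compute_glrlm(patch: np.ndarray, direction: int, gray_levels: int = 8) -> RunLengthMatrix:
    """Scan every maximal line along *direction* and count maximal runs.

    *patch* must already be quantized to ``gray_levels`` levels.
    """
    patch = np.asarray(patch, dtype=np.int64)
    if patch.size == 0:
        raise ValueError("patch must be non-empty")
    if patch.min() < 0 or patch.max() >= gray_levels:
        raise ValueError(f"patch must be quantized to [0, {gray_levels - 1}]")
    max_run = max(patch.shape)
    R = np.zeros((gray_levels, max_run), dtype=np.int64)
    for line in _lines(patch, direction):
        for level, length in _run_lengths(np.asarray(line)):
            R[level, length - 1] += 1
    return RunLengthMatrix(R=R, direction=direction, n_pixels=patch.size)


def _features_from_matrix(rlm: RunLengthMatrix) -> dict[str, float]:
    R = rlm.R.astype(np.float64)
    g, rmax = R.shape
    levels = np.arange(1, g + 1, dtype=np.float64)[:, None]  # 1-based
    lengths = np.arange(1, rmax + 1, dtype=np.float64)[None, :]
    nr = float(rlm.n_runs)
    return {
        "short_run_emphasis": float((R / lengths**2).sum() / nr),
        "long_run_emphasis": float((R * lengths**2).sum() / nr),
        "gray_level_nonuniformity": float((R.sum(axis=1) ** 2).sum() / nr),
        "run_length_nonuniformity": float((R.sum(axis=0) ** 2).sum() / nr),
        "run_percentage": nr / rlm.n_pixels,
        "low_gray_level_run_emphasis": float((R / levels**2).sum() / nr),
        "high_gray_level_run_emphasis": float((R * levels**2).sum() / nr),
    }


def glrlm_feature_vector(
    patch: np.ndarray,
    gray_levels: int = 8,
    directions: tuple[int, ...] = DIRECTIONS,
) -> dict[str, float]:
    """The 7 run-length features of an 8-bit patch, direction-averaged.

    The patch is quantized to ``gray_levels`` first.  Keys follow
    :data:`GLRLM_FEATURE_NAMES` order.
    """
    patch = np.asarray(patch)
    if patch.size == 0:
        raise ValueError("patch must be non-empty")
    q = quantize(patch, gray_levels)
    acc = {name: 0.0 for name in GLRLM_FEATURE_NAMES}
    for direction in directions:
        feats = _features_from_matrix(compute_glrlm(q, direction, gray_levels))
        for name in GLRLM_FEATURE_NAMES:
            acc[name] += feats[name]
    n = len(directions)
    return {name: acc[name] / n for name in GLRLM_FEATURE_NAMES}
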