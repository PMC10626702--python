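"""Gray-level co-occurrence matrices and the 13-feature texture vector.

The co-occurrence matrix ``P(i, j | d, theta)`` is the normalized joint
frequency of quantized gray-level pairs separated by displacement ``d``
along angle ``theta``.  Four scalar statistics (energy, correlation,
contrast, homogeneity) follow the classical definitions; the remaining
nine of the 13-feature vector use the Soh–Tsatsoulis/Clausi co-occurrence
statistics, written out below as the normative formulas of this module.

Conventions (documented, fixed):

* gray-level indices ``i, j`` run ``0 .. G-1`` in every moment;
* angles are counted in (row, col) coordinates with row increasing
  downward: 0 deg -> (0, +d), 45 deg -> (-d, +d), 90 deg -> (-d, 0),
  135 deg -> (-d, -d);
* with ``symmetric=True`` both orderings of each pair are counted;
* the feature vector is the average of per-angle features over the
  requested angles;
* ``homogeneity`` is ``sum P / (1 + |i-j|)`` and ``inverse_difference``
  is ``sum P / (1 + (i-j)^2)`` (elsewhere called inverse difference
  moment), keeping the 13 features distinct;
* ``inverse_difference_normalized`` divides ``|i-j|`` by ``G`` and
  ``inverse_difference_moment_normalized`` divides ``(i-j)^2`` by ``G^2``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .image import GRAY_LEVELS

#: Angle -> (row, col) displacement unit step.
ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}

#: Fixed order of the 13 co-occurrence features.
GLCM_FEATURE_NAMES = (
    "autocorrelation",
    "contrast",
    "correlation",
    "cluster_prominence",
    "cluster_shade",
    "energy",
    "dissimilarity",
    "homogeneity",
    "info_measure_corr_1",
    "maximum_probability",
    "inverse_difference",
    "inverse_difference_normalized",
    "inverse_difference_moment_normalized",
)


@dataclass(frozen=True)
class GLCMParams:
    """Displacement, angle set, quantization depth and symmetry flag."""

    distance: int = 1
    angles: tuple[int, ...] = (0, 45, 90, 135)
    gray_levels: int = 8
    symmetric: bool = True

    def __post_init__(self) -> None:
        if self.distance < 1:
            raise ValueError(f"distance must be >= 1, got {self.distance}")
        if not 2 <= self.gray_levels <= GRAY_LEVELS:
            raise ValueError(
                f"gray_levels must lie in [2, {GRAY_LEVELS}], got {self.gray_levels}"
            )
        bad = set(self.angles) - set(ANGLE_OFFSETS)
        if bad or not self.angles:
            raise ValueError(f"angles must be a non-empty subset of {set(ANGLE_OFFSETS)}")


@dataclass(frozen=True)
class GLCM:
    """Normalized G x G co-occurrence matrix with its marginal moments."""

    P: np.ndarray
    params: GLCMParams = field(default_factory=GLCMParams)

    @property
    def px(self) -> np.ndarray:
        return self.P.sum(axis=1)

    @property
    def py(self) -> np.ndarray:
        return self.P.sum(axis=0)

    @property
    def mu(self) -> float:
        """Mean of the matrix entries."""
        return float(self.P.mean())

    @property
    def mu_x(self) -> float:
        i = np.arange(self.P.shape[0])
        return float((i * self.px).sum())

    @property
    def mu_y(self) -> float:
        j = np.arange(self.P.shape[1])
        return float((j * self.py).sum())

    @property
    def sigma_x(self) -> float:
        i = np.arange(self.P.shape[0])
        return float(np.sqrt(((i - self.mu_x) ** 2 * self.px).sum()))

    @property
    def sigma_y(self) -> float:
        j = np.arange(self.P.shape[1])
        return float(np.sqrt(((j - self.mu_y) ** 2 * self.py).sum()))


def quantize(patch: np.ndarray, gray_levels: int, bit_depth: int = GRAY_LEVELS) -> np.ndarray:
    """Uniformly bin 8-bit intensities: ``q = floor(p * G / L)``, clipped."""
    if gray_levels < 2:
        raise ValueError(f"gray_levels must be >= 2, got {gray_levels}")
    patch = np.asarray(patch, dtype=np.int64)
    q = patch * gray_levels // bit_depth
    return np.clip(q, 0, gray_levels - 1).astype(np.int64)


def compute_glcm(patch: np.ndarray, params: GLCMParams = GLCMParams()) -> GLCM:
    """Count co-occurring pairs over the requested angles and normalize.

    *patch* must already be quantized to ``params.gray_levels`` levels.
    Counts from all requested angles are accumulated into one matrix.
    """
    patch = np.asarray(patch, dtype=np.int64)
    g = params.gray_levels
    if patch.size and (patch.min() < 0 or patch.max() >= g):
        raise ValueError(f"patch must be quantized to [0, {g - 1}]")
    counts = np.zeros((g, g), dtype=np.float64)
    for angle in params.angles:
        counts += _pair_counts(patch, angle, params.distance, g)
    if params.symmetric:
        counts = counts + counts.T
    total = counts.sum()
    if total == 0:
        raise ValueError(
            f"no valid pixel pairs at distance {params.distance} "
            f"for angles {params.angles} in a patch of shape {patch.shape}"
        )
    return GLCM(P=counts / total, params=params)


def _pair_counts(patch: np.ndarray, angle: int, d: int, g: int) -> np.ndarray:
    dr, dc = ANGLE_OFFSETS[angle]
    dr, dc = dr * d, dc * d
    h, w = patch.shape
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    if r0 >= r1 or c0 >= c1:
        return np.zeros((g, g), dtype=np.float64)
    a = patch[r0:r1, c0:c1].ravel()
    b = patch[r0 + dr : r1 + dr, c0 + dc : c1 + dc].ravel()
    return np.bincount(a * g + b, minlength=g * g).reshape(g, g).astype(np.float64)


def glcm_energy(glcm: GLCM) -> float:
    """Angular second moment ``sum P^2``; 1 for a constant image."""
    return float((glcm.P**2).sum())


def glcm_contrast(glcm: GLCM) -> float:
    """``sum (i-j)^2 P(i,j)``; 0 iff all mass lies on the diagonal."""
    g = glcm.P.shape[0]
    i, j = np.indices((g, g))
    return float(((i - j) ** 2 * glcm.P).sum())


def glcm_correlation(glcm: GLCM) -> float:
    """``(sum i*j*P - mu_x*mu_y) / (sigma_x*sigma_y)``, in ``[-1, 1]``.

    A constant patch has zero marginal spread; the value is then defined
    as 0 and a warning is emitted.
    """
    sx, sy = glcm.sigma_x, glcm.sigma_y
    if sx == 0 or sy == 0:
        warnings.warn("degenerate co-occurrence matrix: correlation defined as 0")
        return 0.0
    g = glcm.P.shape[0]
    i, j = np.indices((g, g))
    return float(((i * j * glcm.P).sum() - glcm.mu_x * glcm.mu_y) / (sx * sy))


def glcm_homogeneity(glcm: GLCM) -> float:
    """``sum P / (1 + |i-j|)``; 1 iff all mass lies on the diagonal."""
    g = glcm.P.shape[0]
    i, j = np.indices((g, g))
    return float((glcm.P / (1.0 + np.abs(i - j))).sum())


def _entropy(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def _features_from_matrix(P: np.ndarray) -> dict[str, float]:
    g = P.shape[0]
    i, j = np.indices((g, g))
    px, py = P.sum(axis=1), P.sum(axis=0)
    mu_x = float((np.arange(g) * px).sum())
    mu_y = float((np.arange(g) * py).sum())
    glcm = GLCM(P=P)

    abs_diff = np.abs(i - j)
    sq_diff = (i - j) ** 2
    cluster = i + j - mu_x - mu_y

    hxy = _entropy(P)
    outer = px[:, None] * py[None, :]
    mask = P > 0
    hxy1 = float(-(P[mask] * np.log(outer[mask])).sum()) if mask.any() else 0.0
    hx, hy = _entropy(px), _entropy(py)
    denom = max(hx, hy)
    imc1 = 0.0 if denom == 0 else (hxy - hxy1) / denom

    return {
        "autocorrelation": float((i * j * P).sum()),
        "contrast": float((sq_diff * P).sum()),
        "correlation": glcm_correlation(glcm),
        "cluster_prominence": float((cluster**4 * P).sum()),
        "cluster_shade": float((cluster**3 * P).sum()),
        "energy": float((P**2).sum()),
        "dissimilarity": float((abs_diff * P).sum()),
        "homogeneity": float((P / (1.0 + abs_diff)).sum()),
        "info_measure_corr_1": imc1,
        "maximum_probability": float(P.max()),
        "inverse_difference": float((P / (1.0 + sq_diff)).sum()),
        "inverse_difference_normalized": float((P / (1.0 + abs_diff / g)).sum()),
        "inverse_difference_moment_normalized": float((P / (1.0 + sq_diff / g**2)).sum()),
    }


def glcm_feature_vector(
    patch: np.ndarray, params: GLCMParams = GLCMParams()
) -> dict[str, float]:
    """The 13 co-occurrence features of an 8-bit patch, angle-averaged.

    The patch is quantized to ``params.gray_levels`` first; per-angle
    feature values are averaged over ``params.angles``.  Keys follow
    :data:`GLCM_FEATURE_NAMES` order.
    """
    q = quantize(np.asarray(patch), params.gray_levels)
    acc = {name: 0.0 for name in GLCM_FEATURE_NAMES}
    for angle in params.angles:
        single = GLCMParams(
            distance=params.distance,
            angles=(angle,),
            gray_levels=params.gray_levels,
            symmetric=params.symmetric,
        )
        feats = _features_from_matrix(compute_glcm(q, single).P)
        for name in GLCM_FEATURE_NAMES:
            acc[name] += feats[name]
    n = len(params.angles)
    return {name: acc[name] / n for name in GLCM_FEATURE_NAMES}
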