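"""Seeded generator of panoramic-like synthetic radiographs with lesions.

Real clinical panoramic radiographs are rarely redistributable, so every
downstream stage of this package is exercised against images produced
here: a smooth vertical-gradient background with additive Gaussian noise,
and (for lesion classes) an embedded elliptical patch of stationary
Gaussian-random-field texture whose statistics (mean intensity, standard
deviation, correlation length) differ per class.  Those three parameters
were chosen because co-occurrence, run-length and wavelet statistics are
all functions of exactly these properties, so the generated classes are
separable by every feature family the package extracts.

Class texture presets are package constants (see :data:`CLASS_PRESETS`)
and can be overridden through :class:`LesionSpec`.  All randomness flows
through a single :class:`numpy.random.Generator`, so a fixed seed yields
bit-identical studies.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .image import GRAY_LEVELS, clip_to_gray, write_png

#: Recognized class labels; ``normal`` means "no lesion drawn".
LABELS = ("abscess", "cyst", "tumor", "normal")

#: Default per-class image counts of the generated study.
DEFAULT_CLASS_COUNTS = {"abscess": 73, "cyst": 52, "tumor": 27, "normal": 40}

#: Half-width of the downstream analysis window; lesion centers keep at
#: least this margin from every image border so a 40x40 crop always fits.
ROI_MARGIN = 20


@dataclass(frozen=True)
class TextureParams:
    """Second-order statistics of a stationary lesion texture field."""

    mean_intensity: float
    sd: float
    correlation_length_px: float

    def __post_init__(self) -> None:
        if not 0 <= self.mean_intensity <= GRAY_LEVELS - 1:
            raise ValueError(f"mean_intensity must lie in [0, 255], got {self.mean_intensity}")
        if self.sd < 0:
            raise ValueError(f"sd must be >= 0, got {self.sd}")
        if self.correlation_length_px < 0:
            raise ValueError(
                f"correlation_length_px must be >= 0, got {self.correlation_length_px}"
            )


#: Class texture presets, tuned so that cyst patches are homogeneous and
#: low-contrast, tumor patches high-variance with short correlation, and
#: abscess patches intermediate with a diffuse border.
CLASS_PRESETS: Mapping[str, TextureParams] = {
    "cyst": TextureParams(mean_intensity=70, sd=5, correlation_length_px=3.0),
    "tumor": TextureParams(mean_intensity=120, sd=40, correlation_length_px=0.8),
    "abscess": TextureParams(mean_intensity=95, sd=18, correlation_length_px=1.8),
}

#: Gaussian edge feathering (px) per class; abscess borders are diffuse.
CLASS_BORDER_SOFTNESS: Mapping[str, float] = {"cyst": 2.0, "tumor": 1.0, "abscess": 5.0}


@dataclass(frozen=True)
class LesionSpec:
    """Geometry and texture of one lesion (or a background sample point).

    For ``label == "normal"`` no lesion is drawn; ``center`` marks the
    background point later used as the analysis-window center.
    """

    label: str
    center: tuple[int, int]
    semi_axes: tuple[float, float] = (20.0, 20.0)
    texture_params: TextureParams | None = None
    border_softness: float = 2.0

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        if self.label != "normal":
            if min(self.semi_axes) < 5:
                raise ValueError(f"semi_axes must each be >= 5 px, got {self.semi_axes}")
            if self.texture_params is None:
                object.__setattr__(self, "texture_params", CLASS_PRESETS[self.label])


@dataclass(frozen=True)
class BackgroundParams:
    """Smooth vertical-gradient background with additive Gaussian noise."""

    base_intensity: float = 150.0
    gradient_amplitude: float = 40.0
    noise_sd: float = 9.0


@dataclass(frozen=True)
class StudyConfig:
    """Full study description: class counts, geometry, background, seed."""

    class_counts: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_CLASS_COUNTS))
    image_shape: tuple[int, int] = (400, 800)
    background_params: BackgroundParams = field(default_factory=BackgroundParams)
    seed: int = 0

    def __post_init__(self) -> None:
        for label, count in self.class_counts.items():
            if label not in LABELS:
                raise ValueError(f"unknown class label {label!r}")
            if count < 0:
                raise ValueError(f"count for {label!r} must be >= 0, got {count}")
        h, w = self.image_shape
        if h < 80 or w < 80:
            raise ValueError(f"image_shape must be at least 80x80, got {self.image_shape}")


@dataclass(frozen=True)
class GroundTruth:
    """Per-image annotation row emitted alongside each generated image."""

    image_id: str
    label: str
    center: tuple[int, int]
    path: str | None = None


def texture_field(
    shape: tuple[int, int],
    texture_params: TextureParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample a stationary Gaussian random field quantized to gray levels.

    White Gaussian noise is convolved with an isotropic Gaussian kernel of
    standard deviation ``correlation_length_px`` (periodic extension), the
    result is rescaled to the requested mean and standard deviation, then
    clipped to ``[0, 255]`` and quantized to integers.  ``sd == 0`` yields
    a constant field at ``mean_intensity``.
    """
    h, w = shape
    if h <= 0 or w <= 0:
        raise ValueError(f"shape must be positive, got {shape}")
    p = texture_params
    if p.sd == 0:
        return clip_to_gray(np.full(shape, p.mean_intensity))
    f = rng.standard_normal(shape)
    if p.correlation_length_px > 0:
        f = gaussian_filter(f, sigma=p.correlation_length_px, mode="wrap")
    spread = f.std()
    if spread == 0:  # pathological 1x1 field
        return clip_to_gray(np.full(shape, p.mean_intensity))
    f = p.mean_intensity + p.sd * (f - f.mean()) / spread
    return clip_to_gray(f)


def _background(
    shape: tuple[int, int], params: BackgroundParams, rng: np.random.Generator
) -> np.ndarray:
    h, w = shape
    ramp = np.linspace(-0.5, 0.5, h)[:, None] * params.gradient_amplitude
    field = params.base_intensity + ramp + rng.normal(0.0, params.noise_sd, size=(h, w))
    return clip_to_gray(field)


def generate_image(
    image_shape: tuple[int, int],
    background_params: BackgroundParams,
    lesion_spec: LesionSpec,
    rng: np.random.Generator,
    image_id: str = "image_000",
) -> tuple[np.ndarray, GroundTruth]:
    """Render one radiograph-like image and its ground-truth annotation.

    For lesion classes the textured patch is blended into the background
    through a feathered elliptical mask; for ``normal`` the background is
    returned untouched.
    """
    h, w = image_shape
    img = _background(image_shape, background_params, rng).astype(np.float64)

    if lesion_spec.label != "normal":
        cr, cc = lesion_spec.center
        a, b = lesion_spec.semi_axes
        if cr - a < 0 or cr + a > h - 1 or cc - b < 0 or cc + b > w - 1:
            raise ValueError(
                f"lesion ellipse (center=({cr}, {cc}), semi_axes=({a}, {b})) "
                f"exceeds image bounds {image_shape}"
            )
        pad = int(np.ceil(3 * lesion_spec.border_softness)) + 1
        r0 = max(0, int(np.floor(cr - a)) - pad)
        r1 = min(h, int(np.ceil(cr + a)) + pad + 1)
        c0 = max(0, int(np.floor(cc - b)) - pad)
        c1 = min(w, int(np.ceil(cc + b)) + pad + 1)
        rr, ccol = np.mgrid[r0:r1, c0:c1]
        mask = (((rr - cr) / a) ** 2 + ((ccol - cc) / b) ** 2 <= 1.0).astype(np.float64)
        if lesion_spec.border_softness > 0:
            mask = gaussian_filter(mask, sigma=lesion_spec.border_softness)
        tex = texture_field((r1 - r0, c1 - c0), lesion_spec.texture_params, rng).astype(
            np.float64
        )
        img[r0:r1, c0:c1] = img[r0:r1, c0:c1] * (1.0 - mask) + tex * mask

    truth = GroundTruth(image_id=image_id, label=lesion_spec.label, center=lesion_spec.center)
    return clip_to_gray(img), truth


def _sample_lesion_spec(
    label: str, image_shape: tuple[int, int], rng: np.random.Generator
) -> LesionSpec:
    h, w = image_shape
    if label == "normal":
        cr = int(rng.integers(ROI_MARGIN, h - ROI_MARGIN))
        cc = int(rng.integers(ROI_MARGIN, w - ROI_MARGIN))
        return LesionSpec(label=label, center=(cr, cc))
    a = float(rng.uniform(16, 26))
    b = float(rng.uniform(16, 26))
    margin_r = int(np.ceil(max(a, ROI_MARGIN))) + 1
    margin_c = int(np.ceil(max(b, ROI_MARGIN))) + 1
    cr = int(rng.integers(margin_r, h - margin_r))
    cc = int(rng.integers(margin_c, w - margin_c))
    return LesionSpec(
        label=label,
        center=(cr, cc),
        semi_axes=(a, b),
        texture_params=CLASS_PRESETS[label],
        border_softness=CLASS_BORDER_SOFTNESS[label],
    )


def generate_study(config: StudyConfig) -> list[tuple[np.ndarray, GroundTruth]]:
    """Generate the full study: one (image, annotation) pair per row.

    Classes are emitted in the fixed order abscess, cyst, tumor, normal;
    the total equals the sum of ``class_counts`` (172 with defaults).
    """
    rng = np.random.default_rng(config.seed)
    out: list[tuple[np.ndarray, GroundTruth]] = []
    for label in LABELS:
        for idx in range(config.class_counts.get(label, 0)):
            image_id = f"{label}_{idx:03d}"
            spec = _sample_lesion_spec(label, config.image_shape, rng)
            img, truth = generate_image(
                config.image_shape, config.background_params, spec, rng, image_id=image_id
            )
            out.append((img, truth))
    return out


def write_annotations(rows: Iterable[GroundTruth], path: str | os.PathLike) -> None:
    """Write the annotation CSV (`image_id,label,center_row,center_col`)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image_id", "label", "center_row", "center_col"])
        for gt in rows:
            writer.writerow([gt.image_id, gt.label, gt.center[0], gt.center[1]])


def write_study(config: StudyConfig, out_dir: str | os.PathLike) -> list[GroundTruth]:
    """Generate the study and persist PNG images plus the annotation CSV."""
    os.makedirs(out_dir, exist_ok=True)
    truths: list[GroundTruth] = []
    for img, truth in generate_study(config):
        path = os.path.join(out_dir, f"{truth.image_id}.png")
        write_png(path, img)
        truths.append(GroundTruth(truth.image_id, truth.label, truth.center, path=path))
    write_annotations(truths, os.path.join(out_dir, "annotations.csv"))
    return truths
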