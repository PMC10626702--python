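"""End-to-end orchestration: simulate -> preprocess -> ROI -> features -> evaluate.

Every stage leaves an inspectable artifact on disk (PNG, CSV or JSON);
nothing opaque passes between stages, and the whole run is deterministic
under the configured seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import synthetic_data
from .classify import FeatureTable, SplitSpec
from .evaluation import MethodEvaluation, evaluate_method
from .image import write_png
from .preprocess import preprocess_image
from .roi import DEFAULT_ROI_SIZE, ROIPatch, extract_roi
from .texture_glcm import GLCM_FEATURE_NAMES, GLCMParams, glcm_feature_vector
from .texture_glrlm import GLRLM_FEATURE_NAMES, glrlm_feature_vector
from .wavelet import WAVELET_FEATURE_NAMES, wavelet_feature_vector

logger = logging.getLogger("radtex")

FEATURE_METHODS = ("glcm", "glrlm", "wavelet")


@dataclass(frozen=True)
class PipelineConfig:
    """Validated configuration of a full pipeline run."""

    seed: int = 0
    class_counts: Mapping[str, int] = field(
        default_factory=lambda: dict(synthetic_data.DEFAULT_CLASS_COUNTS)
    )
    image_shape: tuple[int, int] = (400, 800)
    gaussian_sigma: float = 1.0
    stretch_low: float = 0.01
    stretch_high: float = 0.01
    roi_size: int = DEFAULT_ROI_SIZE
    methods: tuple[str, ...] = FEATURE_METHODS
    gray_levels: int = 8
    wavelet_levels: int = 3
    train_fraction: float = 2 / 3
    task: str = "lesion-vs-normal"

    def __post_init__(self) -> None:
        unknown = set(self.methods) - set(FEATURE_METHODS)
        if unknown or not self.methods:
            raise ValueError(
                f"methods must be a non-empty subset of {FEATURE_METHODS}, "
                f"got {tuple(self.methods)}"
            )
        if self.roi_size < 1:
            raise ValueError(f"roi_size must be >= 1, got {self.roi_size}")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("image_shape", "methods"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def compute_feature_table(
    patches: Sequence[ROIPatch], method: str, config: PipelineConfig = PipelineConfig()
) -> FeatureTable:
    """Run one extractor over all patches and assemble a feature table."""
    if method == "glcm":
        names = GLCM_FEATURE_NAMES
        params = GLCMParams(gray_levels=config.gray_levels)
        extract = lambda p: glcm_feature_vector(p, params)  # noqa: E731
    elif method == "glrlm":
        names = GLRLM_FEATURE_NAMES
        extract = lambda p: glrlm_feature_vector(p, config.gray_levels)  # noqa: E731
    elif method == "wavelet":
        names = WAVELET_FEATURE_NAMES
        extract = lambda p: wavelet_feature_vector(p, config.wavelet_levels)  # noqa: E731
    else:
        raise ValueError(f"unknown feature method {method!r}")
    rows = [extract(patch.pixels) for patch in patches]
    feats = np.array([[row[n] for n in names] for row in rows], dtype=np.float64)
    return FeatureTable(
        image_ids=tuple(p.source_image_id for p in patches),
        labels=tuple(p.label for p in patches),
        features=feats.reshape(len(patches), len(names)),
        feature_names=names,
        method=method,
    )


def load_annotations(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"image_id", "label", "center_row", "center_col"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation CSV is missing columns {sorted(missing)}")
    return df


def extract_study_rois(
    images: Mapping[str, np.ndarray],
    annotations: pd.DataFrame,
    size: int = DEFAULT_ROI_SIZE,
) -> list[ROIPatch]:
    patches = []
    for row in annotations.itertuples(index=False):
        img = images[str(row.image_id)]
        patches.append(
            extract_roi(
                img,
                (int(row.center_row), int(row.center_col)),
                size,
                image_id=str(row.image_id),
                label=str(row.label),
            )
        )
    return patches


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | os.PathLike,
    write_images: bool = True,
) -> dict[str, MethodEvaluation]:
    """Execute every stage and return one evaluation per feature method.

    Stage artifacts (annotation CSV, per-method feature CSVs, report
    JSON; optionally raw and preprocessed PNGs) land under *out_dir*.
    """
    out_dir = str(out_dir)
    os.makedirs(out_dir, exist_ok=True)

    logger.info("stage simulate: %s images, seed=%d",
                sum(config.class_counts.values()), config.seed)
    study_cfg = synthetic_data.StudyConfig(
        class_counts=dict(config.class_counts),
        image_shape=config.image_shape,
        seed=config.seed,
    )
    study = synthetic_data.generate_study(study_cfg)
    synthetic_data.write_annotations(
        [truth for _, truth in study], os.path.join(out_dir, "annotations.csv")
    )

    logger.info("stage preprocess: sigma=%.2f", config.gaussian_sigma)
    images: dict[str, np.ndarray] = {}
    for img, truth in study:
        clean = preprocess_image(
            img, config.gaussian_sigma, config.stretch_low, config.stretch_high
        )
        images[truth.image_id] = clean
        if write_images:
            raw_dir = os.path.join(out_dir, "images")
            pre_dir = os.path.join(out_dir, "preprocessed")
            os.makedirs(raw_dir, exist_ok=True)
            os.makedirs(pre_dir, exist_ok=True)
            write_png(os.path.join(raw_dir, f"{truth.image_id}.png"), img)
            write_png(os.path.join(pre_dir, f"{truth.image_id}.png"), clean)

    logger.info("stage extract-roi: size=%d", config.roi_size)
    annotations = load_annotations(os.path.join(out_dir, "annotations.csv"))
    patches = extract_study_rois(images, annotations, config.roi_size)

    results: dict[str, MethodEvaluation] = {}
    split = SplitSpec(train_fraction=config.train_fraction, seed=config.seed)
    for method in config.methods:
        logger.info("stage features+evaluate: method=%s", method)
        table = compute_feature_table(patches, method, config)
        table.to_dataframe().to_csv(
            os.path.join(out_dir, f"features_{method}.csv"), index=False
        )
        results[method] = evaluate_method(table, split, config.task)

    report = {method: ev.to_dict() for method, ev in results.items()}
    with open(os.path.join(out_dir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2)
    logger.info("pipeline complete: %s", os.path.join(out_dir, "report.json"))
    return results
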