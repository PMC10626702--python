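"""Shared helpers for building small synthetic fixtures at test time."""

import warnings

from radtex.pipeline import PipelineConfig, compute_feature_table
from radtex.roi import extract_roi
from radtex.synthetic_data import StudyConfig, generate_study


def make_synthetic_patches(counts, seed=0, image_shape=(120, 160), roi_size=40):
    """Generate a small study and crop the annotated window of each image."""
    cfg = StudyConfig(class_counts=counts, image_shape=image_shape, seed=seed)
    return [
        extract_roi(img, truth.center, roi_size, image_id=truth.image_id, label=truth.label)
        for img, truth in generate_study(cfg)
    ]


def make_synthetic_feature_table(counts, seed=0, method="glcm"):
    patches = make_synthetic_patches(counts, seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # flat cyst patches flag correlation
        return compute_feature_table(patches, method, PipelineConfig(seed=seed))
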