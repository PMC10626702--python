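"""Feature-table handling, stratified splitting and SVM classification.

The study protocol is reconstructed as a stratified single hold-out with
a default train fraction of 2/3, deterministic under a seed; features
are standardized with statistics of the training split only and fed to
a soft-margin kernel support-vector machine (RBF by default, linear
available).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.svm import SVC

#: Label applied to every lesion class in the binary task.
LESION_LABEL = "lesion"
NORMAL_LABEL = "normal"


@dataclass(frozen=True)
class FeatureTable:
    """Rows of (image_id, label, feature vector) for one feature method."""

    image_ids: tuple[str, ...]
    labels: tuple[str, ...]
    features: np.ndarray
    feature_names: tuple[str, ...]
    method: str = ""

    def __post_init__(self) -> None:
        feats = np.asarray(self.features, dtype=np.float64)
        object.__setattr__(self, "features", feats)
        n = len(self.image_ids)
        if len(self.labels) != n or feats.shape[0] != n:
            raise ValueError("image_ids, labels and feature rows must align")
        if feats.ndim != 2 or feats.shape[1] != len(self.feature_names):
            raise ValueError(
                f"feature matrix shape {feats.shape} does not match "
                f"{len(self.feature_names)} feature names"
            )
        if n and not np.isfinite(feats).all():
            raise ValueError("feature table contains non-finite values")

    def __len__(self) -> int:
        return len(self.image_ids)

    def subset(self, idx: Sequence[int]) -> "FeatureTable":
        idx = list(idx)
        return FeatureTable(
            image_ids=tuple(self.image_ids[i] for i in idx),
            labels=tuple(self.labels[i] for i in idx),
            features=self.features[idx],
            feature_names=self.feature_names,
            method=self.method,
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.features, columns=list(self.feature_names))
        df.insert(0, "label", list(self.labels))
        df.insert(0, "image_id", list(self.image_ids))
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, method: str = "") -> "FeatureTable":
        feature_names = tuple(c for c in df.columns if c not in ("image_id", "label"))
        return cls(
            image_ids=tuple(df["image_id"].astype(str)),
            labels=tuple(df["label"].astype(str)),
            features=df[list(feature_names)].to_numpy(dtype=np.float64),
            feature_names=feature_names,
            method=method,
        )


def relabel_lesion_vs_normal(table: FeatureTable) -> FeatureTable:
    """Collapse the three lesion classes into one positive 'lesion' label."""
    labels = tuple(
        NORMAL_LABEL if lab == NORMAL_LABEL else LESION_LABEL for lab in table.labels
    )
    return replace(table, labels=labels)


@dataclass(frozen=True)
class SplitSpec:
    """Stratified hold-out specification (always stratified by label)."""

    train_fraction: float = 2 / 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError(
                f"train_fraction must lie in (0, 1), got {self.train_fraction}"
            )


def split_dataset(
    table: FeatureTable, spec: SplitSpec = SplitSpec()
) -> tuple[FeatureTable, FeatureTable]:
    """Deterministic stratified split into disjoint train/test tables.

    Per class, ``floor(train_fraction * n)`` rows go to training; every
    class must have at least 2 rows.
    """
    rng = np.random.default_rng(spec.seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for label in sorted(set(table.labels)):
        idx = [i for i, lab in enumerate(table.labels) if lab == label]
        if len(idx) < 2:
            raise ValueError(f"class {label!r} has fewer than 2 rows")
        perm = rng.permutation(len(idx))
        n_train = int(np.floor(spec.train_fraction * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)  # both sides non-empty
        train_idx.extend(idx[p] for p in perm[:n_train])
        test_idx.extend(idx[p] for p in perm[n_train:])
    return table.subset(sorted(train_idx)), table.subset(sorted(test_idx))


@dataclass(frozen=True)
class TrainedModel:
    """Fitted SVM plus the training-split standardization constants."""

    svc: SVC
    scaler_mean: np.ndarray
    scaler_sd: np.ndarray
    feature_names: tuple[str, ...]
    classes: tuple[str, ...] = field(default=())

    @property
    def positive_class(self) -> str:
        """Class whose decision score is positive (binary models)."""
        return self.classes[-1]


def fit(
    train_table: FeatureTable,
    kernel: str = "rbf",
    C: float = 1.0,
    gamma: str | float = "scale",
) -> TrainedModel:
    """Standardize on training statistics and fit a kernel SVM."""
    if len(set(train_table.labels)) < 2:
        raise ValueError("training set must contain at least 2 classes")
    mean = train_table.features.mean(axis=0)
    sd = train_table.features.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    X = (train_table.features - mean) / sd
    svc = SVC(kernel=kernel, C=C, gamma=gamma)
    svc.fit(X, list(train_table.labels))
    return TrainedModel(
        svc=svc,
        scaler_mean=mean,
        scaler_sd=sd,
        feature_names=train_table.feature_names,
        classes=tuple(svc.classes_),
    )


def predict(model: TrainedModel, table: FeatureTable) -> tuple[list[str], np.ndarray]:
    """Predicted labels plus real-valued decision scores per row.

    Binary models return the signed margin (positive toward
    ``model.positive_class``); multiclass models return the one-vs-one
    aggregate decision values.
    """
    if table.feature_names != model.feature_names:
        raise ValueError(
            f"feature names {table.feature_names} do not match the "
            f"model's training features {model.feature_names}"
        )
    X = (table.features - model.scaler_mean) / model.scaler_sd
    labels = list(model.svc.predict(X))
    scores = np.asarray(model.svc.decision_function(X), dtype=np.float64)
    return labels, scores
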