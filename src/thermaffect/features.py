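"""Nine statistical temperature features per ROI, feature tables, outlier filter.

For each region the apex window ``X`` and the apex-minus-onset difference
``Xd`` yield nine features:

====  =========================================
f1    mean(X)
f2    mean(Xd)
f3    Var(X)        (population, divide by l*m)
f4    Var(Xd)
f5    max(X)
f6    min(X)
f7    (f5 + f6) / 2
f8    median(X)
f9    median(Xd)
====  =========================================

Temperatures enter in degrees C, so f1/f5-f8 are degC, f2/f9 are degC
differences and f3/f4 are degC^2. Under an affine recalibration
T -> aT + b (a > 0), f1, f5-f8 map affinely, f2/f9 scale by a and f3/f4 by
a^2 — the feature set is calibration-consistent.

Feature-table columns are ROI-major then f1..f9, giving widths 54 / 243 / 99
for the main6 / sub27 / sel11 layouts.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import ThermaffectError, ValidationError
from .layout import ROILayout, ROIPatch, crop_rois

logger = logging.getLogger(__name__)

FEATURE_NAMES = ("f1", "f2", "f3", "f4", "f5", "f6", "f7", "f8", "f9")
N_FEATURES_PER_ROI = 9


def compute_features(patch: ROIPatch, sample_variance: bool = False) -> np.ndarray:
    """The nine statistics of one patch, in f1..f9 order."""
    x = patch.apex_values
    xd = patch.difference
    ddof = 1 if sample_variance else 0
    f5 = float(x.max())
    f6 = float(x.min())
    return np.array(
        [
            float(x.mean()),
            float(xd.mean()),
            float(x.var(ddof=ddof)),
            float(xd.var(ddof=ddof)),
            f5,
            f6,
            (f5 + f6) / 2.0,
            float(np.median(x)),
            float(np.median(xd)),
        ]
    )


@dataclass
class FeatureTable:
    """Instances x (ROI x 9) matrix with labels and provenance.

    ``data`` holds one row per subject with columns ``<region>_f<k>``;
    ``labels`` is the aligned emotion Series; ``provenance`` records how the
    table was built (layout id, seed or manifest path).
    """

    data: pd.DataFrame
    labels: pd.Series
    layout_id: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.data) != len(self.labels):
            raise ValidationError("feature rows and labels are misaligned")
        if self.data.isna().any().any():
            raise ValidationError("feature table contains missing values")
        self.data.index.name = "subject_id"

    @property
    def X(self) -> np.ndarray:
        return self.data.to_numpy(dtype=np.float64)

    @property
    def y(self) -> np.ndarray:
        return self.labels.to_numpy()

    @property
    def n_classes(self) -> int:
        return int(self.labels.nunique())

    def subset_rows(self, index) -> "FeatureTable":
        return FeatureTable(
            self.data.loc[index], self.labels.loc[index], self.layout_id, dict(self.provenance)
        )

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        out = self.data.copy()
        out.insert(0, "emotion", self.labels.values)
        out.to_csv(path, index_label="subject_id")
        sidecar = {
            "layout_id": self.layout_id,
            "columns": list(self.data.columns),
            "provenance": self.provenance,
        }
        path.with_suffix(".schema.json").write_text(json.dumps(sidecar, indent=2, default=str))

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureTable":
        path = Path(path)
        df = pd.read_csv(path, index_col="subject_id")
        sidecar = json.loads(path.with_suffix(".schema.json").read_text())
        labels = df.pop("emotion")
        return cls(df, labels, sidecar["layout_id"], sidecar.get("provenance", {}))


def feature_columns(layout: ROILayout) -> list[str]:
    return [f"{name}_{f}" for name in layout.names for f in FEATURE_NAMES]


def build_feature_table(
    processed: Iterable,
    layout: ROILayout,
    sample_variance: bool = False,
    provenance: dict | None = None,
) -> FeatureTable:
    """One row of 9 x |regions| features per subject.

    ``processed`` yields objects with ``pair`` (registered
    :class:`~thermaffect.core.ThermogramPair`), ``face_bbox`` and
    ``subject_id`` attributes (see :mod:`thermaffect.pipeline`). Subjects
    whose ROIs cannot be cropped are logged and skipped, never silently
    dropped.
    """
    cols = feature_columns(layout)
    rows, labels, index = [], [], []
    for item in processed:
        pair = item.pair
        try:
            patches = crop_rois(pair, item.face_bbox, layout)
        except ThermaffectError as exc:
            logger.warning("skipping subject %s: %s", item.subject_id, exc)
            warnings.warn(f"skipping subject {item.subject_id}: {exc}", stacklevel=2)
            continue
        vec = np.concatenate([compute_features(p, sample_variance) for p in patches])
        rows.append(vec)
        labels.append(pair.emotion)
        index.append(item.subject_id)
    data = pd.DataFrame(np.asarray(rows), columns=cols, index=index)
    return FeatureTable(
        data,
        pd.Series(labels, index=index, name="emotion"),
        layout.model_id,
        provenance or {},
    )


def remove_outliers(
    table: FeatureTable, n_sd: float = 3.0
) -> tuple[FeatureTable, list[str]]:
    """Drop instances lying more than ``n_sd`` class SDs from the class mean.

    The rule is univariate per feature with an any-feature trigger: within
    each class, a row is excluded when any of its features falls outside
    mean +/- n_sd * SD of that class. Zero-SD columns are skipped (they
    cannot produce outliers). Refuses to reduce any class below 2 rows.
    """
    keep = pd.Series(True, index=table.data.index)
    for emotion, idx in table.labels.groupby(table.labels).groups.items():
        block = table.data.loc[idx]
        if len(block) < 5:
            raise ValidationError(
                f"class {emotion} has {len(block)} rows; need >= 5 for the outlier filter"
            )
        mu = block.mean(axis=0)
        sd = block.std(axis=0, ddof=0)
        usable = sd > 0
        z = (block.loc[:, usable] - mu[usable]).abs().div(sd[usable], axis=1)
        bad = (z > n_sd).any(axis=1)
        if (len(block) - int(bad.sum())) < 2:
            raise ValidationError(
                f"outlier filter would leave class {emotion} with fewer than 2 rows"
            )
        keep.loc[bad[bad].index] = False
    removed = list(table.data.index[~keep])
    return table.subset_rows(keep[keep].index), removed
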