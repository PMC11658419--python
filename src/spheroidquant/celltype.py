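"""Fibroblast vs tumor discrimination in co-cultures.

Fibroblast nuclei are smaller and elongated and sit inside secreted
collagen-1; tumor nuclei are larger and rounder but late-mitotic tumor
nuclei can mimic fibroblast size, so volume alone is biased. The default
classifier is a standardized linear SVM on [nuclear volume, elongation,
mean collagen-1 in the outer region, mean collagen-1 in the nucleus].
Training labels come from CellTracker-stained fibroblasts, expanded from a
small manual annotation by the one-feature CellTracker SVM.

``crop_for_cnn`` prepares the three-channel (nuclei, collagen-1, nucleus
mask) 48x64x64 crops used by a volumetric CNN classifier; training such a
CNN requires a deep-learning backend and is outside this package's default
path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import NucleusRecord
from .markers import MarkerModel, celltracker_feature, train_marker_svm
from .volumes import LabelVolume, MultiChannelVolume

__all__ = [
    "CELLTYPE_FEATURE_NAMES",
    "CorrectedCounts",
    "expand_labels_with_celltracker",
    "celltype_features",
    "train_celltype_svm",
    "predict_celltype",
    "crop_for_cnn",
    "corrected_counts",
]

CELLTYPE_FEATURE_NAMES = [
    "volume_um3",
    "elongation",
    "collagen1_outer_mean",
    "collagen1_nucleus_mean",
]

FIBROBLAST, TUMOR = "fibroblast", "tumor"


def expand_labels_with_celltracker(
    records: list[NucleusRecord],
    model: MarkerModel,
    celltracker_channel: str = "celltracker",
) -> list[str]:
    """CellTracker-positive nuclei -> fibroblast, the rest -> tumor."""
    X = np.array(
        [
            celltracker_feature(
                r, celltracker_channel=celltracker_channel, use_smoothed=model.use_smoothed
            )
            for r in records
        ]
    )
    return [FIBROBLAST if pos else TUMOR for pos in model.predict(X)]


def celltype_features(
    record: NucleusRecord, collagen_channel: str = "collagen1", use_smoothed: bool = True
) -> np.ndarray:
    """Ordered 4-vector: volume, elongation, collagen-1 outer mean, collagen-1
    nucleus mean. An empty outer region contributes 0 (record flags it)."""
    v = "smooth" if use_smoothed else "raw"
    return np.array(
        [
            record.volume_um3,
            record.elongation,
            record.stat(collagen_channel, v, "outer").mean,
            record.stat(collagen_channel, v, "nucleus").mean,
        ]
    )


def train_celltype_svm(
    records: list[NucleusRecord],
    type_labels: list[str],
    seed: int = 0,
    collagen_channel: str = "collagen1",
    use_smoothed: bool = True,
    feature_subset: list[str] | None = None,
) -> MarkerModel:
    """Standardized linear SVM separating fibroblast from tumor records.

    ``feature_subset`` restricts to named features (e.g. a volume-only
    ablation). The positive class is fibroblast.
    """
    if len(records) != len(type_labels):
        raise ValueError(f"{len(records)} records but {len(type_labels)} labels")
    X = np.array(
        [celltype_features(r, collagen_channel=collagen_channel, use_smoothed=use_smoothed)
         for r in records]
    )
    names = CELLTYPE_FEATURE_NAMES
    if feature_subset is not None:
        idx = [names.index(n) for n in feature_subset]
        X = X[:, idx]
        names = list(feature_subset)
    y = [t == FIBROBLAST for t in type_labels]
    model = train_marker_svm(
        X, y, seed=seed, marker="celltype", feature_names=names, use_smoothed=use_smoothed
    )
    return model


def predict_celltype(
    model: MarkerModel,
    records: list[NucleusRecord],
    collagen_channel: str = "collagen1",
) -> list[str]:
    X = np.array(
        [celltype_features(r, collagen_channel=collagen_channel, use_smoothed=model.use_smoothed)
         for r in records]
    )
    if model.feature_names != CELLTYPE_FEATURE_NAMES:
        idx = [CELLTYPE_FEATURE_NAMES.index(n) for n in model.feature_names]
        X = X[:, idx]
    return [FIBROBLAST if pos else TUMOR for pos in model.predict(X)]


def crop_for_cnn(
    volume: MultiChannelVolume,
    labels: LabelVolume,
    nucleus_id: int,
    crop_shape: tuple[int, int, int] = (48, 64, 64),
    nuclei_channel: str = "nuclei",
    collagen_channel: str = "collagen1",
) -> np.ndarray:
    """Three-channel crop (nuclei, collagen-1, focal-nucleus binary mask) of
    shape (3, 48, 64, 64), centered on the nucleus centroid; out-of-bounds
    regions are zero-padded. The mask channel contains only the focal
    nucleus."""
    lab = labels.labels
    coords = np.argwhere(lab == nucleus_id)
    if coords.size == 0:
        raise ValueError(f"nucleus id {nucleus_id} not present in label volume")
    center = np.round(coords.mean(axis=0)).astype(int)
    shape = np.asarray(lab.shape)
    cs = np.asarray(crop_shape)
    lo = center - cs // 2
    hi = lo + cs

    src = tuple(slice(max(a, 0), min(b, n)) for a, b, n in zip(lo, hi, shape))
    dst = tuple(
        slice(max(-a, 0), max(-a, 0) + (min(b, n) - max(a, 0)))
        for a, b, n in zip(lo, hi, shape)
    )
    out = np.zeros((3, *crop_shape), dtype=np.float64)
    out[(0, *dst)] = volume.channel(nuclei_channel)[src]
    out[(1, *dst)] = volume.channel(collagen_channel)[src]
    out[(2, *dst)] = (lab[src] == nucleus_id).astype(np.float64)
    return out


@dataclass(frozen=True)
class CorrectedCounts:
    """Co-culture nuclei decomposed into predicted fibroblasts and the
    remainder attributed to tumor cells."""

    total: int
    fibroblast: int

    @property
    def tumor(self) -> int:
        return self.total - self.fibroblast


def corrected_counts(records: list[NucleusRecord], predictions: list[str]) -> CorrectedCounts:
    """Corrected tumor count = total nuclei - predicted fibroblast nuclei."""
    if len(records) != len(predictions):
        raise ValueError(f"{len(records)} records but {len(predictions)} predictions")
    bad = sorted({p for p in predictions} - {FIBROBLAST, TUMOR})
    if bad:
        raise ValueError(f"unknown cell-type predictions: {bad}")
    fib = sum(1 for p in predictions if p == FIBROBLAST)
    return CorrectedCounts(total=len(records), fibroblast=fib)
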