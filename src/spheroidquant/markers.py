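"""SVM gating of nuclear marker positivity and the apoptosis intensity index.

Two gates classify per-nucleus marker state: Ki-67 (proliferation) from the
nuclear-dye mean, the Ki-67 mean inside the nucleus, and the Ki-67 mean in
the perinuclear outer region; Live-or-Dye (necrosis) from the nuclear-dye
and Live-or-Dye means inside the nucleus. A third, one-feature linear SVM
thresholds the mean CellTracker signal (Gaussian-smoothed, sigma 1) to
expand manually annotated fibroblast labels.

Cleaved Caspase-3 signal cannot be attributed to single cells in dense
apoptotic clusters, so it is reported as an aggregate index: summed
above-threshold intensity divided by the nucleus count.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml
from sklearn.svm import SVC

from .features import NucleusRecord

__all__ = [
    "MarkerModel",
    "GateResult",
    "ki67_features",
    "lod_features",
    "celltracker_feature",
    "train_marker_svm",
    "predict_marker",
    "celltracker_svm",
    "cas3_index",
]


@dataclass
class MarkerModel:
    """A standardized linear SVM gate, fully described by its parameters.

    Prediction is sign(w . (x - mu) / sd + b) > 0, so a serialized model
    reproduces training-time predictions exactly.
    """

    marker: str
    feature_names: list[str]
    mean: list[float]
    sd: list[float]
    coef: list[float]
    intercept: float
    seed: int = 0
    use_smoothed: bool = True
    training_predictions: list[bool] = field(default_factory=list)

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        Xs = (X - np.asarray(self.mean)) / np.asarray(self.sd)
        return Xs @ np.asarray(self.coef) + self.intercept

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.decision_function(X) > 0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump({"spheroidquant_marker_model": 1, **asdict(self)}))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MarkerModel":
        d = yaml.safe_load(Path(path).read_text())
        d.pop("spheroidquant_marker_model", None)
        return cls(**d)


@dataclass
class GateResult:
    flags: list[bool]
    positive_count: int
    total: int

    @property
    def fraction(self) -> float:
        return self.positive_count / self.total if self.total else 0.0


def _variant(use_smoothed: bool) -> str:
    return "smooth" if use_smoothed else "raw"


def ki67_features(
    record: NucleusRecord,
    nuclei_channel: str = "nuclei",
    ki67_channel: str = "ki67",
    use_smoothed: bool = False,
) -> np.ndarray:
    """[mean(nuclei ch, nucleus), mean(Ki-67 ch, nucleus), mean(Ki-67 ch, outer)].

    An empty outer region contributes 0 for the outer feature (the record's
    ``outer_empty`` flag marks it).
    """
    v = _variant(use_smoothed)
    return np.array(
        [
            record.stat(nuclei_channel, v, "nucleus").mean,
            record.stat(ki67_channel, v, "nucleus").mean,
            record.stat(ki67_channel, v, "outer").mean,
        ]
    )


def lod_features(
    record: NucleusRecord,
    nuclei_channel: str = "nuclei",
    lod_channel: str = "lod",
    use_smoothed: bool = False,
) -> np.ndarray:
    """[mean(nuclei ch, nucleus), mean(Live-or-Dye ch, nucleus)]."""
    v = _variant(use_smoothed)
    return np.array(
        [
            record.stat(nuclei_channel, v, "nucleus").mean,
            record.stat(lod_channel, v, "nucleus").mean,
        ]
    )


def celltracker_feature(
    record: NucleusRecord, celltracker_channel: str = "celltracker", use_smoothed: bool = True
) -> np.ndarray:
    """Mean CellTracker signal within the nucleus (1-vector)."""
    v = _variant(use_smoothed)
    return np.array([record.stat(celltracker_channel, v, "nucleus").mean])


FEATURE_EXTRACTORS = {
    "ki67": ki67_features,
    "lod": lod_features,
    "celltracker": celltracker_feature,
}


def train_marker_svm(
    features: np.ndarray,
    labels,
    seed: int = 0,
    marker: str = "marker",
    feature_names: list[str] | None = None,
    use_smoothed: bool = False,
) -> MarkerModel:
    """Fit a standardized linear-kernel SVM (C = 1) gate.

    Features are standardized with the training mean/SD; the fit is
    deterministic for a fixed seed. Raises if only one class is present.
    """
    X = np.atleast_2d(np.asarray(features, dtype=np.float64))
    y = np.asarray(labels, dtype=bool)
    if X.shape[0] != y.shape[0]:
        raise ValueError(f"{X.shape[0]} feature rows but {y.shape[0]} labels")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class; need both positives and negatives")
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    Xs = (X - mu) / sd
    svc = SVC(kernel="linear", C=1.0, random_state=int(seed))
    svc.fit(Xs, y)
    model = MarkerModel(
        marker=marker,
        feature_names=list(feature_names or [f"f{i}" for i in range(X.shape[1])]),
        mean=[float(v) for v in mu],
        sd=[float(v) for v in sd],
        coef=[float(v) for v in svc.coef_[0]],
        intercept=float(svc.intercept_[0]),
        seed=int(seed),
        use_smoothed=use_smoothed,
    )
    model.training_predictions = [bool(v) for v in model.predict(X)]
    return model


def extract_features(model: MarkerModel, records: list[NucleusRecord], **channel_kwargs) -> np.ndarray:
    extractor = FEATURE_EXTRACTORS.get(model.marker)
    if extractor is None:
        raise ValueError(
            f"no feature extractor for marker {model.marker!r}; known: {sorted(FEATURE_EXTRACTORS)}"
        )
    return np.array(
        [extractor(r, use_smoothed=model.use_smoothed, **channel_kwargs) for r in records]
    )


def predict_marker(model: MarkerModel, records: list[NucleusRecord], **channel_kwargs) -> GateResult:
    """Gate every record; the positive fraction is over all surviving nuclei."""
    if not records:
        raise ValueError("no records to gate")
    X = extract_features(model, records, **channel_kwargs)
    flags = [bool(v) for v in model.predict(X)]
    return GateResult(flags=flags, positive_count=int(sum(flags)), total=len(records))


def celltracker_svm(
    records: list[NucleusRecord],
    annotations: dict[int, bool],
    sigma: float = 1.0,
    seed: int = 0,
    celltracker_channel: str = "celltracker",
) -> MarkerModel:
    """Linear SVM on the mean nuclear CellTracker signal (smoothed, sigma 1).

    ``annotations`` maps nucleus id -> CellTracker-positive; it must contain
    both classes. The smoothing sigma is a contract of the upstream feature
    extraction (the cell table's smoothed statistics); the default of 1
    matches the package-wide smoothing default.
    """
    if sigma != 1.0:
        raise ValueError(
            "the CellTracker gate is defined on sigma=1 smoothed intensities; "
            "rebuild the cell table with smooth_sigma matching any other choice"
        )
    by_id = {r.id: r for r in records}
    missing = sorted(set(annotations) - set(by_id))
    if missing:
        raise ValueError(f"annotated ids not present in records: {missing}")
    ids = sorted(annotations)
    X = np.array(
        [celltracker_feature(by_id[i], celltracker_channel=celltracker_channel) for i in ids]
    )
    y = [annotations[i] for i in ids]
    return train_marker_svm(
        X, y, seed=seed, marker="celltracker", use_smoothed=True,
        feature_names=[f"mean_{celltracker_channel}_nucleus_smooth"],
    )


def train_gate_from_flags(
    records: list[NucleusRecord],
    flags_by_id: dict[int, bool],
    marker: str,
    seed: int = 0,
    use_smoothed: bool = False,
    **channel_kwargs,
) -> MarkerModel:
    """Train a marker gate from per-nucleus boolean annotations keyed by id."""
    extractor = FEATURE_EXTRACTORS.get(marker)
    if extractor is None:
        raise ValueError(f"no feature extractor for marker {marker!r}")
    subset = [r for r in records if r.id in flags_by_id]
    if not subset:
        raise ValueError("no annotated records")
    X = np.array([extractor(r, use_smoothed=use_smoothed, **channel_kwargs) for r in subset])
    y = [flags_by_id[r.id] for r in subset]
    return train_marker_svm(X, y, seed=seed, marker=marker, use_smoothed=use_smoothed)


def cas3_index(cas3_channel: np.ndarray, threshold: float, n_nuclei: int) -> float:
    """Aggregate Cleaved Caspase-3 intensity per cell (a.u./cell):
    sum of above-threshold voxel intensities divided by the nucleus count."""
    if n_nuclei < 1:
        raise ValueError(f"n_nuclei must be >= 1; got {n_nuclei}")
    arr = np.asarray(cas3_channel, dtype=np.float64)
    return float(arr[arr > threshold].sum()) / n_nuclei
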