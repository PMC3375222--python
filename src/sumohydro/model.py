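"""RBF-SVM training, persistence and threshold-based classification.

Decision scores follow the raw SVM margin convention (positive side =
sumoylated) so that the three operating cutoffs -0.2 (low), 0 (medium)
and +0.2 (high) are directly meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

MODEL_FORMAT_VERSION = "sumohydro-model-1"

#: Operating thresholds on the decision score.
THRESHOLDS: dict[str, float] = {"low": -0.2, "medium": 0.0, "high": 0.2}

# libsvm-style default grids
DEFAULT_C_GRID: tuple[float, ...] = tuple(2.0**e for e in range(-5, 16, 2))
DEFAULT_GAMMA_GRID: tuple[float, ...] = tuple(2.0**e for e in range(-15, 4, 2))


class ModelError(ValueError):
    """Raised on invalid training inputs or persistence failures."""


@dataclass
class SvmConfig:
    """RBF-SVM hyper-parameters and search grids.

    ``C``/``gamma`` set the operating point; ``grid_search`` fills them
    in from the grids when unset.
    """

    C: float = 1.0
    gamma: float | str = "scale"
    c_grid: Sequence[float] = field(default_factory=lambda: DEFAULT_C_GRID)
    gamma_grid: Sequence[float] = field(default_factory=lambda: DEFAULT_GAMMA_GRID)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.c_grid or not self.gamma_grid:
            raise ModelError("hyper-parameter grids must be non-empty")
        if self.C <= 0:
            raise ModelError(f"C must be positive, got {self.C}")
        if isinstance(self.gamma, (int, float)) and self.gamma <= 0:
            raise ModelError(f"gamma must be positive, got {self.gamma}")


@dataclass
class TrainedModel:
    """A fitted RBF-SVM together with its scheme identity and provenance."""

    estimator: SVC
    scheme: str
    C: float
    gamma: float | str
    metadata: dict = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return int(self.estimator.n_features_in_)


def _check_training_inputs(features: np.ndarray, labels: np.ndarray) -> None:
    features = np.asarray(features, dtype=float)
    if not np.all(np.isfinite(features)):
        raise ModelError("features contain non-finite values")
    if len(np.unique(labels)) < 2:
        raise ModelError("training labels contain a single class")


def _mcc(tp: int, fp: int, fn: int, tn: int) -> float:
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / np.sqrt(denom)


def grid_search(
    features: np.ndarray,
    labels: np.ndarray,
    config: SvmConfig,
    folds: int = 10,
) -> tuple[float, float]:
    """Exhaustive (C, gamma) selection by mean cross-validated MCC.

    Ties break toward smaller C, then smaller gamma; fold assignment is
    deterministic given ``config.seed``.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    _check_training_inputs(features, labels)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=config.seed)
    splits = list(skf.split(features, labels))
    best: tuple[float, float] | None = None
    best_score = -np.inf
    for c in sorted(config.c_grid):
        for g in sorted(config.gamma_grid):
            fold_mcc = []
            for tr, te in splits:
                clf = SVC(kernel="rbf", C=c, gamma=g)
                clf.fit(features[tr], labels[tr])
                pred = (clf.decision_function(features[te]) >= 0).astype(int)
                yt = labels[te]
                tp = int(np.sum((yt == 1) & (pred == 1)))
                fp = int(np.sum((yt == 0) & (pred == 1)))
                fn = int(np.sum((yt == 1) & (pred == 0)))
                tn = int(np.sum((yt == 0) & (pred == 0)))
                fold_mcc.append(_mcc(tp, fp, fn, tn))
            score = float(np.mean(fold_mcc))
            if score > best_score:  # strict: earlier (smaller) params win ties
                best_score = score
                best = (c, g)
    assert best is not None
    return best


def train_model(
    features: np.ndarray,
    labels: np.ndarray,
    C: float,
    gamma: float | str,
    scheme: str = "unknown",
    metadata: dict | None = None,
) -> TrainedModel:
    """Fit an RBF-SVM on encoded features."""
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    _check_training_inputs(features, labels)
    clf = SVC(kernel="rbf", C=C, gamma=gamma)
    clf.fit(features, labels)
    meta = dict(metadata or {})
    meta.setdefault("n_train", int(labels.size))
    meta.setdefault("n_positives", int(np.sum(labels == 1)))
    return TrainedModel(estimator=clf, scheme=scheme, C=C, gamma=gamma, metadata=meta)


def decision_scores(model: TrainedModel, features: np.ndarray) -> np.ndarray:
    """Signed margin per row; larger = more sumoylation-like."""
    features = np.asarray(features, dtype=float)
    if features.ndim != 2 or features.shape[1] != model.n_features:
        raise ModelError(
            f"feature dimension {features.shape} does not match model "
            f"({model.n_features} features, scheme {model.scheme!r})"
        )
    return model.estimator.decision_function(features)


def classify(scores: np.ndarray, level: str = "medium") -> np.ndarray:
    """Binary calls at a named threshold level: positive iff score >= cutoff.

    Predicted-positive sets nest: high ⊆ medium ⊆ low.
    """
    if level not in THRESHOLDS:
        raise ModelError(
            f"unknown threshold level {level!r}; valid: {', '.join(THRESHOLDS)}"
        )
    return (np.asarray(scores) >= THRESHOLDS[level]).astype(int)


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Persist a model bundle (format version, scheme, params, estimator)."""
    bundle = {
        "format_version": MODEL_FORMAT_VERSION,
        "scheme": model.scheme,
        "C": model.C,
        "gamma": model.gamma,
        "metadata": model.metadata,
        "estimator": model.estimator,
    }
    joblib.dump(bundle, path)


def load_model(path: str | Path) -> TrainedModel:
    """Load a model bundle, verifying the format version."""
    try:
        bundle = joblib.load(path)
    except Exception as exc:
        raise ModelError(f"cannot read model archive {path}: {exc}") from exc
    if not isinstance(bundle, dict) or "format_version" not in bundle:
        raise ModelError(f"{path}: not a model archive (missing format version)")
    if bundle["format_version"] != MODEL_FORMAT_VERSION:
        raise ModelError(
            f"{path}: format version {bundle['format_version']!r} "
            f"does not match expected {MODEL_FORMAT_VERSION!r}"
        )
    return TrainedModel(
        estimator=bundle["estimator"],
        scheme=bundle["scheme"],
        C=bundle["C"],
        gamma=bundle["gamma"],
        metadata=bundle.get("metadata", {}),
    )
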