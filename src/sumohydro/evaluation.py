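"""Performance assessment: confusion counts, Sn/Sp/Ac/MCC, ROC/AUC and
the cross-validation / repeated-resampling protocols.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold

from .dataset import LabeledDataset, sample_negatives
from .encoders import DEFAULT_KNN_K, encode_dataset
from .model import SvmConfig, TrainedModel, decision_scores, train_model


class EvaluationError(ValueError):
    """Raised on invalid evaluation inputs."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricSet:
    """Sn/Sp/Ac as fractions, MCC in [-1, 1], optional AUC and per-metric
    standard deviations from repeated runs."""

    sn: float
    sp: float
    ac: float
    mcc: float
    auc: float | None = None
    sd: dict = field(default_factory=dict)
    degenerate_mcc: bool = False

    def as_dict(self) -> dict:
        d = {"Sn": self.sn, "Sp": self.sp, "Ac": self.ac, "MCC": self.mcc}
        if self.auc is not None:
            d["AUC"] = self.auc
        return d


@dataclass
class RocCurve:
    """Ordered (false-positive-rate, true-positive-rate) points with AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def confusion(true_labels: Sequence[int], predicted_labels: Sequence[int]) -> ConfusionCounts:
    yt = np.asarray(true_labels)
    yp = np.asarray(predicted_labels)
    if yt.shape != yp.shape:
        raise EvaluationError(f"length mismatch: {yt.shape} vs {yp.shape}")
    return ConfusionCounts(
        tp=int(np.sum((yt == 1) & (yp == 1))),
        fp=int(np.sum((yt == 0) & (yp == 1))),
        fn=int(np.sum((yt == 1) & (yp == 0))),
        tn=int(np.sum((yt == 0) & (yp == 0))),
    )


def metrics(c: ConfusionCounts, auc: float | None = None) -> MetricSet:
    """Sn = TP/(TP+FN), Sp = TN/(TN+FP), Ac = (TP+TN)/total and the
    Matthews correlation coefficient.

    A zero factor in the MCC denominator yields MCC = 0 with the
    ``degenerate_mcc`` flag set (documented convention).
    """
    if c.total == 0:
        raise EvaluationError("empty confusion table")
    if c.tp + c.fn == 0 or c.tn + c.fp == 0:
        raise EvaluationError("confusion table lacks one true class entirely")
    sn = c.tp / (c.tp + c.fn)
    sp = c.tn / (c.tn + c.fp)
    ac = (c.tp + c.tn) / c.total
    denom = (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    degenerate = denom == 0
    mcc = 0.0 if degenerate else (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)
    return MetricSet(sn=sn, sp=sp, ac=ac, mcc=mcc, auc=auc, degenerate_mcc=degenerate)


def roc(true_labels: Sequence[int], scores: Sequence[float]) -> RocCurve:
    """ROC over all decision-score thresholds with trapezoidal AUC.

    The trapezoidal AUC equals the fraction of (positive, negative)
    pairs ranked correctly, ties counted half (Mann-Whitney statistic).
    """
    yt = np.asarray(true_labels)
    if len(np.unique(yt)) < 2:
        raise EvaluationError("ROC requires both classes present")
    fpr, tpr, _ = _sk_roc_curve(yt, np.asarray(scores, dtype=float), drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr=fpr, tpr=tpr, auc=auc)


# ---------------------------------------------------------------------------
# Cross-validation protocols
# ---------------------------------------------------------------------------


def _encode_split(
    fragments: list, train_idx: np.ndarray, test_idx: np.ndarray, scheme: str, options: dict
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Encode train/test fragments; KNN reference sets come from the
    training fold only (leave-self-out inside the fold) to avoid label
    leakage."""
    train_frags = [fragments[i] for i in train_idx]
    test_frags = [fragments[i] for i in test_idx]
    if scheme == "knn":
        refs_p = [f for f in train_frags if f.label == 1]
        refs_n = [f for f in train_frags if f.label == 0]
        opts = dict(options, ref_positives=refs_p, ref_negatives=refs_n)
        Xtr, ytr = encode_dataset(train_frags, scheme, exclude_self=True, **opts)
        Xte, yte = encode_dataset(test_frags, scheme, exclude_self=False, **opts)
    else:
        Xtr, ytr = encode_dataset(train_frags, scheme, **options)
        Xte, yte = encode_dataset(test_frags, scheme, **options)
    return Xtr, ytr, Xte, yte


def _pooled_eval(
    y_pool: np.ndarray, score_pool: np.ndarray, cutoff: float = 0.0
) -> tuple[MetricSet, RocCurve]:
    curve = roc(y_pool, score_pool)
    m = metrics(confusion(y_pool, (score_pool >= cutoff).astype(int)), auc=curve.auc)
    return m, curve


def kfold_cv(
    dataset: LabeledDataset,
    scheme: str,
    config: SvmConfig,
    k: int = 10,
    seed: int | None = None,
    **encode_options,
) -> tuple[MetricSet, RocCurve]:
    """Stratified k-fold cross-validation; held-out decision scores are
    pooled across folds, metrics are taken at cutoff 0."""
    fragments = list(dataset)
    y = np.array([f.label for f in fragments])
    n_pos, n_neg = int(np.sum(y == 1)), int(np.sum(y == 0))
    if k > min(n_pos, n_neg):
        raise EvaluationError(
            f"k={k} exceeds the smaller class count ({min(n_pos, n_neg)})"
        )
    skf = StratifiedKFold(
        n_splits=k, shuffle=True, random_state=config.seed if seed is None else seed
    )
    scores = np.empty(len(fragments))
    for train_idx, test_idx in skf.split(np.zeros(len(y)), y):
        Xtr, ytr, Xte, _ = _encode_split(fragments, train_idx, test_idx, scheme, encode_options)
        model = train_model(Xtr, ytr, C=config.C, gamma=config.gamma, scheme=scheme)
        scores[test_idx] = decision_scores(model, Xte)
    return _pooled_eval(y, scores)


def loo_cv(
    dataset: LabeledDataset,
    scheme: str,
    config: SvmConfig,
    **encode_options,
) -> tuple[MetricSet, RocCurve]:
    """Leave-one-out cross-validation (one held-out sample per round)."""
    fragments = list(dataset)
    if len(fragments) < 2:
        raise EvaluationError("leave-one-out requires at least 2 samples")
    y = np.array([f.label for f in fragments])
    scores = np.empty(len(fragments))
    all_idx = np.arange(len(fragments))
    for i in all_idx:
        train_idx = np.delete(all_idx, i)
        Xtr, ytr, Xte, _ = _encode_split(
            fragments, train_idx, np.array([i]), scheme, encode_options
        )
        model = train_model(Xtr, ytr, C=config.C, gamma=config.gamma, scheme=scheme)
        scores[i] = decision_scores(model, Xte)[0]
    return _pooled_eval(y, scores)


def repeated_eval(
    full_dataset: LabeledDataset,
    scheme: str,
    config: SvmConfig,
    ratio: int = 10,
    repeats: int = 5,
    protocol: str = "kfold",
    seed: int = 0,
    k: int = 10,
    **encode_options,
) -> MetricSet:
    """Repeat negative resampling + cross-validation and report each
    metric as mean with standard deviation over the repeats."""
    if protocol not in ("kfold", "loo"):
        raise EvaluationError(f"unknown protocol {protocol!r}; valid: kfold, loo")
    rows = []
    for r in range(repeats):
        ds = sample_negatives(full_dataset, ratio=ratio, seed=seed + r)
        if protocol == "kfold":
            m, _ = kfold_cv(ds, scheme, config, k=k, seed=seed + r, **encode_options)
        else:
            m, _ = loo_cv(ds, scheme, config, **encode_options)
        rows.append(m.as_dict())
    df = pd.DataFrame(rows)
    mean = df.mean()
    sd = df.std(ddof=0) if repeats == 1 else df.std(ddof=1)
    return MetricSet(
        sn=float(mean["Sn"]),
        sp=float(mean["Sp"]),
        ac=float(mean["Ac"]),
        mcc=float(mean["MCC"]),
        auc=float(mean["AUC"]) if "AUC" in df else None,
        sd={name: float(sd[name]) for name in df.columns},
    )


def ratio_sweep(
    full_dataset: LabeledDataset,
    scheme: str,
    config: SvmConfig,
    ratios: Sequence[int] = tuple(range(1, 26)),
    k: int = 10,
    seed: int = 0,
    **encode_options,
) -> pd.DataFrame:
    """Train at a series of positive:negative ratios and test on the
    entire dataset.

    For each ratio the sampled training set is split into stratified
    folds; every sampled fragment is scored by the fold model that did
    not train on it, and the unsampled negatives are partitioned across
    folds so each receives exactly one out-of-training score.  Metrics
    are taken at cutoff 0 over the whole dataset.
    """
    fragments = list(full_dataset)
    rows = []
    for ratio in ratios:
        ds = sample_negatives(full_dataset, ratio=ratio, seed=seed)
        sampled_sources = {f.source for f in ds}
        rest = [f for f in fragments if f.source not in sampled_sources]
        sub = list(ds)
        y_sub = np.array([f.label for f in sub])
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        scores_sub = np.empty(len(sub))
        rest_scores: list[np.ndarray] = []
        rest_labels: list[np.ndarray] = []
        rest_chunks = np.array_split(np.arange(len(rest)), k)
        for fold, (train_idx, test_idx) in enumerate(skf.split(np.zeros(len(y_sub)), y_sub)):
            Xtr, ytr, Xte, _ = _encode_split(sub, train_idx, test_idx, scheme, encode_options)
            model = train_model(Xtr, ytr, C=config.C, gamma=config.gamma, scheme=scheme)
            scores_sub[test_idx] = decision_scores(model, Xte)
            chunk = [rest[i] for i in rest_chunks[fold]]
            if chunk:
                if scheme == "knn":
                    opts = dict(
                        encode_options,
                        ref_positives=[f for f in (sub[i] for i in train_idx) if f.label == 1],
                        ref_negatives=[f for f in (sub[i] for i in train_idx) if f.label == 0],
                        exclude_self=False,
                    )
                else:
                    opts = encode_options
                Xr, yr = encode_dataset(chunk, scheme, **opts)
                rest_scores.append(decision_scores(model, Xr))
                rest_labels.append(yr)
        y_pool = np.concatenate([y_sub] + rest_labels) if rest_labels else y_sub
        s_pool = np.concatenate([scores_sub] + rest_scores) if rest_scores else scores_sub
        m, curve = _pooled_eval(y_pool, s_pool)
        rows.append(
            {
                "ratio": ratio,
                "Sn": m.sn,
                "Sp": m.sp,
                "Ac": m.ac,
                "MCC": m.mcc,
                "AUC": curve.auc,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Report output
# ---------------------------------------------------------------------------


def write_metrics_tsv(
    rows: Sequence[dict], path: str | Path
) -> None:
    """Write a metrics report (one row per scheme/protocol) as TSV."""
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_roc_tsv(curve: RocCurve, path: str | Path) -> None:
    pd.DataFrame({"fpr": curve.fpr, "tpr": curve.tpr}).to_csv(path, sep="\t", index=False)


def plot_roc(curves: dict[str, RocCurve], path: str | Path) -> None:
    """Optional ROC plot (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for name, curve in curves.items():
        ax.plot(curve.fpr, curve.tpr, label=f"{name} (AUC={curve.auc:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.5)
    ax.set_xlabel("1 - Sp (false positive rate)")
    ax.set_ylabel("Sn (true positive rate)")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
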