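"""Confusion-matrix metrics, ROC/AUC, cross-validation, and the window-size sweep.

Metrics follow the standard site-prediction conventions:

    SN  = TP / (TP + FN)                     (sensitivity, recall on positives)
    SP  = TN / (FP + TN)                     (specificity)
    ACC = (TP + TN) / n
    MCC = (TP*TN - FP*FN) / sqrt((TP+FN)(TP+FP)(TN+FN)(TN+FP))

MCC equals the Pearson correlation of the two binary label vectors; any
zero factor in its denominator (or in SN/SP's) defines the metric as 0,
with the degenerate metric named in ``flags``.

Cross-validation evaluates the *whole* pipeline: within each fold the
feature extractor, the feature scaler, and the SVM see only the k-1
training folds; the held-out fold is touched exactly once, for scoring.
Every fold records the index sets each stage was fitted on, so leakage is
auditable after the fact.
"""
from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve
from sklearn.model_selection import LeaveOneOut, StratifiedKFold

from .extractor import (
    ExtractorConfig,
    TrainedExtractor,
    build_extractor,
    extract_features,
    fine_tune,
    pretrain,
)
from .svm import SVMGridSpec, grid_search, predict_svm, train_svm
from .windows import EncodedBatch, PeptideWindow, encode, flank_from_size

__all__ = [
    "ConfusionCounts", "MetricsReport", "confusion", "metrics", "roc_auc",
    "PipelineSpec", "CVResult", "FoldRecord", "kfold_cv", "window_size_sweep",
]


class EvaluationError(ValueError):
    """Raised for invalid evaluation inputs."""


@dataclass(frozen=True, slots=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise EvaluationError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.TP + other.TP, self.TN + other.TN,
            self.FP + other.FP, self.FN + other.FN,
        )


@dataclass(frozen=True, slots=True)
class MetricsReport:
    SN: float
    SP: float
    ACC: float
    MCC: float
    AUC: float | None = None
    flags: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float]:
        d = {"SN": self.SN, "SP": self.SP, "ACC": self.ACC, "MCC": self.MCC}
        if self.AUC is not None:
            d["AUC"] = self.AUC
        return d


def _binary(vec, name: str) -> np.ndarray:
    arr = np.asarray(vec).astype(int)
    if arr.ndim != 1:
        raise EvaluationError(f"{name} must be 1-D")
    if arr.size and not np.isin(arr, (0, 1)).all():
        raise EvaluationError(f"{name} must be binary (0/1)")
    return arr


def confusion(truth, predicted) -> ConfusionCounts:
    """Count TP/TN/FP/FN from aligned binary vectors."""
    t = _binary(truth, "truth")
    p = _binary(predicted, "predicted")
    if t.shape != p.shape:
        raise EvaluationError(f"length mismatch: {t.shape} vs {p.shape}")
    return ConfusionCounts(
        TP=int(np.sum((t == 1) & (p == 1))),
        TN=int(np.sum((t == 0) & (p == 0))),
        FP=int(np.sum((t == 0) & (p == 1))),
        FN=int(np.sum((t == 1) & (p == 0))),
    )


def metrics(c: ConfusionCounts, scores=None, truth=None) -> MetricsReport:
    """SN/SP/ACC/MCC from confusion counts; optionally AUC from scores.

    A zero denominator defines the affected metric as 0 and names it in
    ``flags`` (convention for degenerate folds, e.g. leave-one-out).
    """
    if c.n == 0:
        raise EvaluationError("cannot compute metrics from all-zero counts")
    flags: list[str] = []
    if c.TP + c.FN > 0:
        sn = c.TP / (c.TP + c.FN)
    else:
        sn, flags = 0.0, flags + ["SN"]
    if c.FP + c.TN > 0:
        sp = c.TN / (c.FP + c.TN)
    else:
        sp, flags = 0.0, flags + ["SP"]
    acc = (c.TP + c.TN) / c.n
    denom = float(c.TP + c.FN) * (c.TP + c.FP) * (c.TN + c.FN) * (c.TN + c.FP)
    if denom > 0:
        mcc = (c.TP * c.TN - c.FP * c.FN) / np.sqrt(denom)
    else:
        mcc, flags = 0.0, flags + ["MCC"]
    auc = None
    if scores is not None:
        if truth is None:
            raise EvaluationError("AUC needs the truth vector alongside scores")
        _, auc = roc_auc(scores, truth)
    return MetricsReport(SN=float(sn), SP=float(sp), ACC=float(acc),
                         MCC=float(mcc), AUC=auc, flags=tuple(flags))


def roc_auc(scores, truth) -> tuple[np.ndarray, float]:
    """ROC points (FPR, TPR) and trapezoid AUC from decision scores.

    The trapezoid area equals the tie-corrected Mann-Whitney pair statistic
    over (positive, negative) score pairs.
    """
    truth = _binary(truth, "truth")
    scores = np.asarray(scores, dtype=float)
    if scores.shape != truth.shape:
        raise EvaluationError("scores and truth must align")
    if len(np.unique(truth)) < 2:
        raise EvaluationError("ROC needs both classes present")
    fpr, tpr, _ = roc_curve(truth, scores)
    points = np.column_stack([fpr, tpr])
    auc = float(np.trapezoid(tpr, fpr))
    return points, auc


# ----------------------------------------------------------------------
# Pipeline cross-validation
# ----------------------------------------------------------------------

@dataclass(slots=True)
class PipelineSpec:
    """What to run inside each cross-validation fold.

    ``source`` (optional) is the source-task batch used to pretrain the
    extractor before per-fold fine-tuning; without it the extractor trains
    directly on each fold's training windows.  ``refit_extractor=False``
    selects the cheaper protocol that fits the extractor once on all
    windows and only refits the SVM per fold (the extractor then sees
    held-out windows; the default never does).
    """

    extractor_config: ExtractorConfig = field(default_factory=ExtractorConfig)
    source: EncodedBatch | None = None
    svm_params: tuple[float, str, str] | None = (1.0, "rbf", "scale")
    grid: SVMGridSpec | None = None
    grid_k: int = 5
    refit_extractor: bool = True
    scale_features: bool = True
    epochs: int | None = None

    def fit_extractor(self, train: EncodedBatch, seed: int) -> TrainedExtractor:
        cfg = replace(self.extractor_config, seed=seed)
        model = build_extractor(cfg)
        if self.source is not None:
            pretrain(model, self.source, epochs=self.epochs)
            fine_tune(model, train, epochs=self.epochs)
        else:
            pretrain(model, train, epochs=self.epochs)
        return model


@dataclass(slots=True)
class FoldRecord:
    """Audit trail of one fold: who was trained on which window indices."""

    train_indices: np.ndarray
    test_indices: np.ndarray
    extractor_fit_indices: np.ndarray
    scaler_fit_indices: np.ndarray
    svm_fit_indices: np.ndarray
    report: MetricsReport
    scores: np.ndarray
    truth: np.ndarray


@dataclass(slots=True)
class CVResult:
    folds: list[FoldRecord]
    mean: MetricsReport
    pooled: MetricsReport

    @property
    def k(self) -> int:
        return len(self.folds)


def _mean_report(reports: Sequence[MetricsReport]) -> MetricsReport:
    aucs = [r.AUC for r in reports if r.AUC is not None]
    return MetricsReport(
        SN=float(np.mean([r.SN for r in reports])),
        SP=float(np.mean([r.SP for r in reports])),
        ACC=float(np.mean([r.ACC for r in reports])),
        MCC=float(np.mean([r.MCC for r in reports])),
        AUC=float(np.mean(aucs)) if aucs else None,
        flags=tuple(sorted({f for r in reports for f in r.flags})),
    )


def kfold_cv(
    spec: PipelineSpec,
    windows: Sequence[PeptideWindow] | EncodedBatch,
    k: int = 10,
    seed: int = 0,
) -> CVResult:
    """Stratified k-fold cross-validation of the full pipeline.

    ``k == n`` runs leave-one-out (single-sample test folds; their
    per-fold SN/SP/MCC are degenerate and flagged).  Every window lands in
    exactly one test fold, and no fitting stage ever sees held-out data
    under the default (refit-per-fold) protocol.
    """
    batch = windows if isinstance(windows, EncodedBatch) else encode(windows)
    n = len(batch)
    y = batch.labels
    if k < 2:
        raise EvaluationError(f"k must be >= 2, got {k}")
    if k > n:
        raise EvaluationError(f"k={k} exceeds the {n} available windows")
    if len(np.unique(y)) < 2:
        raise EvaluationError("both classes must be present")
    if k == n:
        splits = [(tr, te) for tr, te in LeaveOneOut().split(batch.matrix)]
    else:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = [(tr, te) for tr, te in splitter.split(batch.matrix, y)]

    all_indices = np.arange(n)
    shared_extractor = None
    if not spec.refit_extractor:
        shared_extractor = spec.fit_extractor(batch, seed=seed)
    pretrained_base = None
    if spec.refit_extractor and spec.source is not None:
        # the source task is disjoint from every target fold, so pretraining
        # once per CV run leaks nothing; only fine-tuning is per-fold
        base_cfg = replace(spec.extractor_config, seed=seed)
        pretrained_base = build_extractor(base_cfg)
        pretrain(pretrained_base, spec.source, epochs=spec.epochs)

    folds: list[FoldRecord] = []
    for fold_i, (train_idx, test_idx) in enumerate(splits):
        if len(np.unique(y[train_idx])) < 2:
            raise EvaluationError(f"fold {fold_i}: a class is absent from training data")
        train_batch = batch.subset(train_idx)
        test_batch = batch.subset(test_idx)
        if shared_extractor is not None:
            extractor = shared_extractor
            extractor_fit = all_indices
        elif pretrained_base is not None:
            extractor = copy.deepcopy(pretrained_base)
            extractor.config = replace(extractor.config, seed=seed * 1000 + fold_i)
            fine_tune(extractor, train_batch, epochs=spec.epochs)
            extractor_fit = train_idx
        else:
            extractor = spec.fit_extractor(train_batch, seed=seed * 1000 + fold_i)
            extractor_fit = train_idx
        train_feats = extract_features(extractor, train_batch)
        test_feats = extract_features(extractor, test_batch)
        if spec.grid is not None:
            gs = grid_search(train_feats, y[train_idx], spec.grid,
                             k=spec.grid_k, seed=seed)
            C, kernel, gamma = gs.best
        else:
            C, kernel, gamma = spec.svm_params
        model = train_svm(train_feats, y[train_idx], C, kernel, gamma,
                          scale_features=spec.scale_features)
        pred, scores = predict_svm(model, test_feats)
        c = confusion(y[test_idx], pred)
        both_classes = len(np.unique(y[test_idx])) == 2
        report = metrics(c, scores=scores if both_classes else None,
                         truth=y[test_idx] if both_classes else None)
        folds.append(FoldRecord(
            train_indices=train_idx, test_indices=test_idx,
            extractor_fit_indices=extractor_fit,
            scaler_fit_indices=train_idx if spec.scale_features else np.array([], dtype=int),
            svm_fit_indices=train_idx,
            report=report, scores=scores, truth=y[test_idx],
        ))
    pooled_counts = ConfusionCounts(0, 0, 0, 0)
    for f in folds:
        pooled_counts = pooled_counts + confusion(f.truth, (f.scores > 0).astype(int))
    pooled_scores = np.concatenate([f.scores for f in folds])
    pooled_truth = np.concatenate([f.truth for f in folds])
    pooled = metrics(pooled_counts, scores=pooled_scores, truth=pooled_truth)
    return CVResult(folds=folds, mean=_mean_report([f.report for f in folds]),
                    pooled=pooled)


def window_size_sweep(
    sizes: Sequence[int],
    data_builder: Callable[[int], Sequence[PeptideWindow]],
    spec: PipelineSpec,
    k: int = 10,
    seed: int = 0,
) -> tuple[pd.DataFrame, int]:
    """Cross-validate the pipeline at each window size; best size by MCC.

    ``data_builder(size)`` must return the windows re-segmented at that
    full window size (2n+1).  Returns the Size/SN/SP/ACC/MCC table and the
    best size.
    """
    rows = []
    for size in sizes:
        n = flank_from_size(size)  # validates oddness
        if size < 3:
            raise EvaluationError(f"window size must be >= 3, got {size}")
        windows = data_builder(size)
        fold_spec = copy.copy(spec)
        fold_spec.extractor_config = replace(spec.extractor_config, window_size=size)
        result = kfold_cv(fold_spec, windows, k=k, seed=seed)
        rows.append({"Size": size, **{m: getattr(result.mean, m)
                                      for m in ("SN", "SP", "ACC", "MCC")}})
    table = pd.DataFrame(rows)
    best_size = int(table.loc[table["MCC"].idxmax(), "Size"])
    return table, best_size
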