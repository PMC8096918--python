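"""SVM classification stage: standardization, grid search, training, scoring.

The classifier is a soft-margin kernel SVM (penalty factor C trading the
margin term against slack-variable misclassification); the quadratic
program is solved by scikit-learn's SVC.  Hyperparameters are chosen by
mean accuracy over a stratified k-fold split that is held fixed across all
grid combinations, so every combination is scored on identical folds.
"""
from __future__ import annotations

import hashlib
import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

#: The C ladder searched for the propionylation classifier.
DEFAULT_C_VALUES = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 10.0, 100.0, 1000.0)
DEFAULT_KERNELS = ("linear", "poly", "rbf")
DEFAULT_GAMMA_MODES = ("scale", "auto")

VALID_KERNELS = ("linear", "poly", "rbf", "sigmoid")


class SVMError(ValueError):
    """Raised for invalid SVM-stage inputs."""


@dataclass(frozen=True, slots=True)
class SVMGridSpec:
    """The hyperparameter search space: C x kernel x gamma mode."""

    C_values: tuple[float, ...] = DEFAULT_C_VALUES
    kernels: tuple[str, ...] = DEFAULT_KERNELS
    gamma_modes: tuple[str, ...] = DEFAULT_GAMMA_MODES

    def __post_init__(self) -> None:
        if not (self.C_values and self.kernels and self.gamma_modes):
            raise SVMError("grid lists must be non-empty")
        if any(c <= 0 for c in self.C_values):
            raise SVMError("C values must be positive")
        bad = set(self.kernels) - set(VALID_KERNELS)
        if bad:
            raise SVMError(f"unknown kernels: {sorted(bad)}")
        if set(self.gamma_modes) - {"scale", "auto"}:
            raise SVMError("gamma modes must be 'scale' or 'auto'")

    @classmethod
    def extended(cls) -> "SVMGridSpec":
        """The default grid plus the sigmoid kernel (9 x 4 x 2 = 72 combos)."""
        return cls(kernels=DEFAULT_KERNELS + ("sigmoid",))

    def combinations(self) -> list[tuple[float, str, str]]:
        return list(itertools.product(self.C_values, self.kernels, self.gamma_modes))


@dataclass(frozen=True, slots=True)
class Scaler:
    """Per-feature mean/scale fitted on training data (constant columns -> 0)."""

    mean: np.ndarray
    scale: np.ndarray

    def transform(self, features: np.ndarray) -> np.ndarray:
        features = np.asarray(features, dtype=float)
        if features.ndim != 2 or features.shape[1] != self.mean.shape[0]:
            raise SVMError(
                f"feature width {features.shape[-1]} does not match scaler "
                f"width {self.mean.shape[0]}"
            )
        return (features - self.mean) / self.scale


def standardize(features: np.ndarray) -> tuple[np.ndarray, Scaler]:
    """Column-wise z-scoring; constant columns map to zero.

    Returns the scaled matrix and the fitted scaler to reuse on test data
    (test data must never be scaled with its own statistics).
    """
    features = np.asarray(features, dtype=float)
    if features.ndim != 2 or features.shape[0] < 2:
        raise SVMError("standardize needs at least 2 rows of 2-D features")
    mean = features.mean(axis=0)
    sd = features.std(axis=0)
    scale = np.where(sd == 0.0, 1.0, sd)
    scaler = Scaler(mean=mean, scale=scale)
    return scaler.transform(features), scaler


@dataclass(slots=True)
class GridSearchResult:
    """Ranked grid table (Table-2 style) and the winning combination."""

    table: pd.DataFrame  # columns: C, kernel, gamma, mean_accuracy
    best: tuple[float, str, str]
    fold_hash: str
    fold_indices: list[tuple[np.ndarray, np.ndarray]] = field(repr=False, default_factory=list)


def _fold_hash(folds: Sequence[tuple[np.ndarray, np.ndarray]]) -> str:
    digest = hashlib.sha256()
    for train_idx, test_idx in folds:
        digest.update(np.asarray(train_idx).tobytes())
        digest.update(np.asarray(test_idx).tobytes())
    return digest.hexdigest()


def _check_xy(features: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels).astype(int)
    if features.shape[0] != labels.shape[0]:
        raise SVMError("features and labels must align")
    if len(np.unique(labels)) < 2:
        raise SVMError("both classes must be present")
    return features, labels


def grid_search(
    features: np.ndarray,
    labels: np.ndarray,
    grid: SVMGridSpec | None = None,
    k: int = 10,
    seed: int = 0,
) -> GridSearchResult:
    """Score every grid combination by mean accuracy on one fixed k-fold split.

    Folds are stratified, seeded, and identical across combinations (a
    paired comparison, witnessed by ``fold_hash``).  Ties are broken toward
    smaller C, then kernel order, then gamma order as listed in the grid.
    A combination that fails to fit is recorded with NaN accuracy and
    excluded from the ranking.
    """
    grid = grid or SVMGridSpec()
    if k < 2:
        raise SVMError(f"k must be >= 2, got {k}")
    features, labels = _check_xy(features, labels)
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = [(tr.copy(), te.copy()) for tr, te in splitter.split(features, labels)]
    rows = []
    for ci, C in enumerate(grid.C_values):
        for ki, kernel in enumerate(grid.kernels):
            for gi, gamma in enumerate(grid.gamma_modes):
                accs = []
                try:
                    for train_idx, test_idx in folds:
                        clf = SVC(C=C, kernel=kernel, gamma=gamma, degree=3)
                        clf.fit(features[train_idx], labels[train_idx])
                        accs.append(clf.score(features[test_idx], labels[test_idx]))
                    mean_acc = float(np.mean(accs))
                except Exception as exc:  # failed fit -> NaN, excluded from ranking
                    warnings.warn(
                        f"grid combination C={C}, kernel={kernel}, gamma={gamma} "
                        f"failed: {exc}", stacklevel=2,
                    )
                    mean_acc = float("nan")
                rows.append({
                    "C": C, "kernel": kernel, "gamma": gamma,
                    "mean_accuracy": mean_acc,
                    "_order": (ci * 100 + ki) * 100 + gi,
                })
    table = pd.DataFrame(rows)
    ranked = table.dropna(subset=["mean_accuracy"]).sort_values(
        by=["mean_accuracy", "_order"],
        ascending=[False, True],
        kind="stable",
    )
    failed = table[table["mean_accuracy"].isna()]
    table = pd.concat([ranked, failed]).drop(columns="_order").reset_index(drop=True)
    if ranked.empty:
        raise SVMError("every grid combination failed to fit")
    best_row = ranked.iloc[0]
    return GridSearchResult(
        table=table,
        best=(float(best_row["C"]), str(best_row["kernel"]), str(best_row["gamma"])),
        fold_hash=_fold_hash(folds),
        fold_indices=folds,
    )


@dataclass(slots=True)
class SVMModel:
    """A fitted SVM with the scaler used at fit time and chosen hyperparameters."""

    classifier: SVC
    scaler: Scaler | None
    C: float
    kernel: str
    gamma: str
    training_accuracy: float


def train_svm(
    features: np.ndarray,
    labels: np.ndarray,
    C: float = 1.0,
    kernel: str = "rbf",
    gamma: str = "scale",
    scale_features: bool = True,
) -> SVMModel:
    """Fit the final classifier, standardizing features unless disabled."""
    features, labels = _check_xy(features, labels)
    scaler = None
    if scale_features:
        features, scaler = standardize(features)
    clf = SVC(C=C, kernel=kernel, gamma=gamma, degree=3)
    clf.fit(features, labels)
    return SVMModel(
        classifier=clf, scaler=scaler, C=C, kernel=kernel, gamma=gamma,
        training_accuracy=float(clf.score(features, labels)),
    )


def predict_svm(model: SVMModel, features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Label (decision value > 0) and signed decision scores for each row."""
    features = np.asarray(features, dtype=float)
    if model.scaler is not None:
        features = model.scaler.transform(features)
    expected = model.classifier.n_features_in_
    if features.ndim != 2 or features.shape[1] != expected:
        raise SVMError(
            f"feature width {features.shape[-1]} does not match training width {expected}"
        )
    scores = model.classifier.decision_function(features)
    labels = (scores > 0).astype(int)
    return labels, scores
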