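"""Feature assembly, stratified splitting, standardization, models, evaluation.

The 230-feature matrix (30 color + 200 local, canonical orders) is split
80:20 with stratification on the 4-level label, standardized with training
statistics only, and classified by an RBF-kernel SVM (C=9, gamma=0.001;
multi-class by one-vs-one aggregation) and by the MLP in
:mod:`leafsense.mlp`.  Predictions are made at 4 levels first and coarsened
to 3 and 2 levels with the same maps as the labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .colorfeat import COLOR_FEATURE_NAMES, ColorFeatureVector
from .errors import ConfigError
from .localfeat import LOCAL_FEATURE_NAMES, LocalFeatureVector
from .mlp import MLPFreshnessClassifier
from .panel import coarsen

N_FEATURES = len(COLOR_FEATURE_NAMES) + len(LOCAL_FEATURE_NAMES)
FEATURE_NAMES: tuple[str, ...] = COLOR_FEATURE_NAMES + LOCAL_FEATURE_NAMES

SVM_DEFAULTS = {"C": 9.0, "gamma": 0.001, "kernel": "rbf"}


@dataclass
class FeatureVector:
    """The ordered 230-value representation of one image."""

    values: np.ndarray
    image_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_FEATURES,):
            raise ConfigError(
                f"expected {N_FEATURES} features, got shape {self.values.shape}"
            )


def assemble_features(color: ColorFeatureVector, local: LocalFeatureVector
                      ) -> FeatureVector:
    """Concatenate color (indices 0-29) and local (30-229) features."""
    if color.image_id != local.image_id:
        raise ConfigError(
            f"image id mismatch: {color.image_id!r} vs {local.image_id!r}"
        )
    return FeatureVector(np.concatenate([color.values, local.values]),
                         image_id=color.image_id)


@dataclass
class SplitPlan:
    """Stratified train/test membership by array index (and optional ids)."""

    train_idx: np.ndarray
    test_idx: np.ndarray
    seed: int
    train_ids: list[str] = field(default_factory=list)
    test_ids: list[str] = field(default_factory=list)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def stratified_split(labels4: Sequence[int], test_fraction: float = 0.2,
                     seed: int = 0, image_ids: Sequence[str] | None = None
                     ) -> SplitPlan:
    """Seeded stratified 80:20 split with largest-remainder apportionment.

    The overall test count is ``round(test_fraction * n)``; per-class test
    counts start from the floor of each class quota and the remaining slots
    go to the classes with the largest fractional remainders, keeping every
    class within one image of exact proportionality.  Classes with fewer
    than two members go entirely to training (with a warning).
    """
    y = np.asarray(labels4, dtype=int)
    if y.size == 0:
        raise ConfigError("empty label vector")
    if not 0.0 < test_fraction < 1.0:
        raise ConfigError(f"test_fraction must be in (0, 1), got {test_fraction}")
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(y, return_counts=True)

    singleton = classes[counts < 2]
    if singleton.size:
        warnings.warn(
            f"classes {singleton.tolist()} have < 2 members; assigned "
            "entirely to the training set", stacklevel=2)
    eligible = classes[counts >= 2]
    elig_counts = counts[counts >= 2]
    n_elig = int(elig_counts.sum())
    n_test = _round_half_up(test_fraction * n_elig)

    quotas = test_fraction * elig_counts
    base = np.floor(quotas).astype(int)
    base = np.minimum(base, elig_counts - 1)  # keep >= 1 training item
    extra = n_test - int(base.sum())
    remainders = quotas - np.floor(quotas)
    # largest remainder first; ties to the smaller class label
    order = np.lexsort((eligible, -remainders))
    take = base.copy()
    for pos in order:
        if extra <= 0:
            break
        if take[pos] < elig_counts[pos] - 1:
            take[pos] += 1
            extra -= 1

    test_parts = []
    for cls, k in zip(eligible, take):
        members = np.flatnonzero(y == cls)
        members = rng.permutation(members)
        test_parts.append(members[:k])
    test_idx = np.sort(np.concatenate(test_parts)) if test_parts \
        else np.array([], dtype=int)
    train_idx = np.setdiff1d(np.arange(y.size), test_idx)
    ids = list(image_ids) if image_ids is not None else []
    return SplitPlan(
        train_idx=train_idx, test_idx=test_idx, seed=seed,
        train_ids=[ids[i] for i in train_idx] if ids else [],
        test_ids=[ids[i] for i in test_idx] if ids else [])


def fit_standardizer(train_X: np.ndarray) -> StandardScaler:
    """Per-feature zero-mean unit-variance scaler, fitted on training data.

    Constant features get scale 1 (centered pass-through).
    """
    return StandardScaler().fit(np.asarray(train_X, dtype=float))


def apply_standardizer(scaler: StandardScaler, X: np.ndarray) -> np.ndarray:
    return scaler.transform(np.asarray(X, dtype=float))


def train_svm(train_X: np.ndarray, train_y: np.ndarray, C: float = 9.0,
              gamma: float = 0.001, kernel: str = "rbf") -> SVC:
    """RBF-kernel SVM with the published hyperparameters (one-vs-one)."""
    train_y = np.asarray(train_y)
    if np.unique(train_y).size < 2:
        raise ConfigError("training set contains a single class")
    model = SVC(C=C, gamma=gamma, kernel=kernel)
    return model.fit(np.asarray(train_X, dtype=float), train_y)


def train_ann(train_X: np.ndarray, train_y: np.ndarray, seed: int = 0,
              **overrides) -> MLPFreshnessClassifier:
    """The 32/128/128/64 MLP with the published training schedule."""
    model = MLPFreshnessClassifier(random_state=seed, **overrides)
    return model.fit(np.asarray(train_X, dtype=float), np.asarray(train_y))


_FAMILIES: dict[str, Callable[..., object]] = {
    "svm": lambda seed, **hp: SVC(**{**SVM_DEFAULTS, **hp}),
    "ann": lambda seed, **hp: MLPFreshnessClassifier(random_state=seed, **hp),
}


@dataclass
class CVResult:
    best_params: dict
    best_score: float
    fold_scores: list[list[float]]   # per grid point, per fold
    mean_scores: list[float]
    n_folds: int


def cross_validate(train_X: np.ndarray, train_y: np.ndarray,
                   model_family: str = "svm",
                   grid: Sequence[dict] | None = None,
                   folds: int = 5, seed: int = 0) -> CVResult:
    """Stratified k-fold CV over a hyperparameter grid.

    The default single-point grid evaluates the fixed published
    hyperparameters.  The standardizer is re-fitted inside every fold (the
    leak-free choice).  Ties in mean fold accuracy go to the first grid
    point.  If ``folds`` exceeds the smallest class count the fold count is
    reduced with a warning.
    """
    if model_family not in _FAMILIES:
        raise ConfigError(f"unknown model family {model_family!r}")
    X = np.asarray(train_X, dtype=float)
    y = np.asarray(train_y)
    grid = list(grid) if grid else [{}]
    _, counts = np.unique(y, return_counts=True)
    min_count = int(counts.min())
    n_folds = folds
    if n_folds > min_count:
        n_folds = max(min_count, 2)
        warnings.warn(
            f"reducing folds from {folds} to {n_folds}: smallest class has "
            f"{min_count} members", stacklevel=2)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)

    fold_scores: list[list[float]] = []
    for params in grid:
        scores = []
        for tr, va in skf.split(X, y):
            scaler = fit_standardizer(X[tr])
            model = _FAMILIES[model_family](seed, **params)
            model.fit(apply_standardizer(scaler, X[tr]), y[tr])
            pred = model.predict(apply_standardizer(scaler, X[va]))
            scores.append(float((pred == y[va]).mean()))
        fold_scores.append(scores)
    mean_scores = [float(np.mean(s)) for s in fold_scores]
    best = int(np.argmax(mean_scores))  # first maximizer on ties
    return CVResult(best_params=grid[best], best_score=mean_scores[best],
                    fold_scores=fold_scores, mean_scores=mean_scores,
                    n_folds=n_folds)


@dataclass
class EvalReport:
    """Confusion matrices and accuracies at 4/3/2 levels for one model."""

    confusion4: np.ndarray
    confusion3: np.ndarray
    confusion2: np.ndarray
    overall_accuracy: dict[int, float]       # percentages per level
    per_class_recall: dict[int, list[float]]
    model_tag: str

    def confusion(self, level: int) -> np.ndarray:
        return {4: self.confusion4, 3: self.confusion3, 2: self.confusion2}[level]

    def to_dict(self) -> dict:
        return {
            "model_tag": self.model_tag,
            "overall_accuracy": {str(k): v for k, v in
                                 self.overall_accuracy.items()},
            "per_class_recall": {str(k): v for k, v in
                                 self.per_class_recall.items()},
            "confusion": {str(lv): self.confusion(lv).tolist()
                          for lv in (4, 3, 2)},
        }


def evaluate(model, test_X: np.ndarray, test_labels4: np.ndarray,
             model_tag: str = "") -> EvalReport:
    """Predict at 4 levels, coarsen, and tabulate confusions/accuracies.

    Confusion rows are true classes, columns predicted classes.
    """
    test_X = np.asarray(test_X, dtype=float)
    if test_X.shape[0] == 0:
        raise ConfigError("empty test set")
    y4 = np.asarray(test_labels4, dtype=int)
    pred4 = np.asarray(model.predict(test_X), dtype=int)

    confusions: dict[int, np.ndarray] = {}
    acc: dict[int, float] = {}
    recall: dict[int, list[float]] = {}
    for level in (4, 3, 2):
        truth = coarsen(y4, level)
        pred = coarsen(pred4, level)
        label_set = sorted(set(range(1, level + 1)))
        cm = confusion_matrix(truth, pred, labels=label_set)
        confusions[level] = cm
        acc[level] = 100.0 * float((pred == truth).mean())
        with np.errstate(invalid="ignore"):
            rec = np.where(cm.sum(1) > 0, cm.diagonal() / cm.sum(1), np.nan)
        recall[level] = [float(x) for x in rec]
    return EvalReport(confusion4=confusions[4], confusion3=confusions[3],
                      confusion2=confusions[2], overall_accuracy=acc,
                      per_class_recall=recall, model_tag=model_tag)
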