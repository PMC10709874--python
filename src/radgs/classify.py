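"""Gleason-group classification under stratified 5-fold cross-validation.

Three classifiers mirror the study design: an RBF-kernel SVM with an inner
3-fold powers-of-two grid search over (C, gamma), a k = 5 Euclidean KNN
whose vote ties are resolved by the single nearest neighbor's label, and a
Gaussian naive-Bayes rule with empirical priors and a configurable
misclassification-cost matrix (0/1 by default, i.e. posterior argmax).

Three labeling tasks are supported: clinically-significant vs
non-significant (Gleason 3+3 vs >= 3+4), Gleason 3+4 vs >= 4+3 (the 3+3
lesions are dropped), and the 3-class grouping. The train/test split is
8:2 via stratified 5-fold cross-validation; accuracy is the arithmetic
mean over folds. SMOTE balancing and feature z-scoring are fitted on
training rows only, so test folds never influence training.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product
from typing import Literal

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC

from radgs.balance import smote

__all__ = [
    "ClassifierSpec",
    "TaskSpec",
    "TASKS",
    "EvalResult",
    "make_folds",
    "train_predict",
    "cross_validate",
]

#: Powers-of-two hyperparameter grids for the RBF SVM (step x4).
DEFAULT_C_GRID = tuple(2.0**e for e in range(-5, 16, 2))
DEFAULT_GAMMA_GRID = tuple(2.0**e for e in range(-15, 4, 2))


@dataclass
class ClassifierSpec:
    """Configuration of one classifier."""

    kind: Literal["svm_rbf", "knn", "gaussian_nb"]
    c_grid: tuple[float, ...] = DEFAULT_C_GRID
    gamma_grid: tuple[float, ...] = DEFAULT_GAMMA_GRID
    inner_folds: int = 3
    knn_k: int = 5
    cost_matrix: np.ndarray | None = None  # cost[action, true_class]; 0/1 if None

    def __post_init__(self) -> None:
        if not self.c_grid or not self.gamma_grid:
            raise ValueError("hyperparameter grids must be non-empty")
        if self.knn_k < 1:
            raise ValueError("knn k must be >= 1")


@dataclass
class TaskSpec:
    """A labeling task: map 3-group Gleason tags to class indices.

    ``label_map`` sends a group tag ("3+3", "3+4", ">=4+3") to a class
    index or None (row excluded from the task).
    """

    name: str
    label_map: dict[str, int | None]

    def apply(self, groups: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Returns (keep_mask, class_indices[keep])."""
        mapped = np.array([self.label_map.get(str(g), None) for g in groups], dtype=object)
        keep = np.array([m is not None for m in mapped])
        return keep, mapped[keep].astype(int)


TASKS: dict[str, TaskSpec] = {
    "sig_vs_nonsig": TaskSpec(
        "sig_vs_nonsig", {"3+3": 0, "3+4": 1, ">=4+3": 1}
    ),
    "g34_vs_g43plus": TaskSpec(
        "g34_vs_g43plus", {"3+3": None, "3+4": 0, ">=4+3": 1}
    ),
    "three_class": TaskSpec(
        "three_class", {"3+3": 0, "3+4": 1, ">=4+3": 2}
    ),
}


@dataclass
class EvalResult:
    """Cross-validation outcome for one (task, classifier, level) cell."""

    per_fold_accuracy: list[float]
    mean_accuracy: float
    confusion: np.ndarray
    task: str = ""
    classifier: str = ""
    dilation_level: int = 0
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "classifier": self.classifier,
            "dilation_level": self.dilation_level,
            "seed": self.seed,
            "per_fold_accuracy": self.per_fold_accuracy,
            "mean_accuracy": self.mean_accuracy,
            "confusion": self.confusion.tolist(),
        }


def make_folds(
    labels: np.ndarray, n_folds: int = 5, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified train/test partitions; deterministic given seed."""
    y = np.asarray(labels)
    if y.size < n_folds:
        raise ValueError(f"need at least {n_folds} samples")
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < n_folds:
        warnings.warn(
            "a class has fewer members than folds; stratification degrades",
            stacklevel=2,
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in skf.split(np.zeros_like(y, dtype=float), y)]


def _zscore_fit(xtr: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = xtr.mean(axis=0)
    sd = xtr.std(axis=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn("zero-variance training feature dropped", stacklevel=3)
    return mu, sd, keep


def _svm_grid_search(spec: ClassifierSpec, x: np.ndarray, y: np.ndarray) -> SVC:
    """Inner stratified CV over the (C, gamma) grid; first best wins."""
    _, counts = np.unique(y, return_counts=True)
    n_inner = min(spec.inner_folds, int(counts.min()))
    if n_inner >= 2:
        skf = StratifiedKFold(n_splits=n_inner, shuffle=True, random_state=0)
        splits = list(skf.split(x, y))
        best, best_acc = None, -1.0
        for c, g in product(spec.c_grid, spec.gamma_grid):
            correct = 0
            for tr, te in splits:
                clf = SVC(C=c, gamma=g, kernel="rbf")
                clf.fit(x[tr], y[tr])
                correct += int((clf.predict(x[te]) == y[te]).sum())
            acc = correct / len(y)
            if acc > best_acc:
                best, best_acc = (c, g), acc
        c, g = best
    else:  # degenerate training class: fall back to mid-grid values
        c, g = spec.c_grid[len(spec.c_grid) // 2], spec.gamma_grid[len(spec.gamma_grid) // 2]
    return SVC(C=c, gamma=g, kernel="rbf").fit(x, y)


def _knn_predict(spec: ClassifierSpec, xtr, ytr, xte) -> np.ndarray:
    k = min(spec.knn_k, len(ytr))
    nn = NearestNeighbors(n_neighbors=k).fit(xtr)
    _, neigh = nn.kneighbors(xte)
    classes = np.unique(ytr)
    out = np.empty(len(xte), dtype=ytr.dtype)
    for i, row in enumerate(neigh):
        votes = np.array([(ytr[row] == c).sum() for c in classes])
        top = np.nonzero(votes == votes.max())[0]
        if top.size == 1:
            out[i] = classes[top[0]]
        else:  # vote tie: the single nearest neighbor decides
            out[i] = ytr[row[0]]
    return out


def _nb_predict(spec: ClassifierSpec, xtr, ytr, xte) -> np.ndarray:
    nb = GaussianNB().fit(xtr, ytr)  # empirical priors
    if spec.cost_matrix is None:
        return nb.predict(xte)
    proba = nb.predict_proba(xte)
    cost = np.asarray(spec.cost_matrix, dtype=float)
    expected = proba @ cost.T  # [sample, action]
    return nb.classes_[np.argmin(expected, axis=1)]


def train_predict(
    spec: ClassifierSpec,
    train_x: np.ndarray,
    train_y: np.ndarray,
    test_x: np.ndarray,
) -> np.ndarray:
    """Fit on training rows and predict test labels.

    Features are z-scored with training-fold statistics only; training
    features with zero variance are dropped from both tables.
    """
    xtr = np.asarray(train_x, dtype=float)
    xte = np.asarray(test_x, dtype=float)
    ytr = np.asarray(train_y)
    mu, sd, keep = _zscore_fit(xtr)
    xtr = (xtr[:, keep] - mu[keep]) / sd[keep]
    xte = (xte[:, keep] - mu[keep]) / sd[keep]
    if spec.kind == "svm_rbf":
        return _svm_grid_search(spec, xtr, ytr).predict(xte)
    if spec.kind == "knn":
        return _knn_predict(spec, xtr, ytr, xte)
    if spec.kind == "gaussian_nb":
        return _nb_predict(spec, xtr, ytr, xte)
    raise ValueError(f"unknown classifier kind {spec.kind!r}")


def cross_validate(
    table: pd.DataFrame | np.ndarray,
    labels: np.ndarray,
    spec: ClassifierSpec,
    seed: int = 0,
    use_smote: bool = True,
    n_folds: int = 5,
) -> EvalResult:
    """Stratified k-fold evaluation with in-fold SMOTE balancing.

    Per fold: the training rows are (optionally) SMOTE-balanced, features
    are z-scored from training rows only, the classifier is trained and the
    held-out fold scored. Folds whose training set lacks a class are
    skipped with a warning; the mean is over the remaining folds.
    """
    x = table.to_numpy(dtype=float) if isinstance(table, pd.DataFrame) else np.asarray(table, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    folds = make_folds(y, n_folds=n_folds, seed=seed)
    accs: list[float] = []
    conf = np.zeros((classes.size, classes.size), dtype=int)
    for fold_i, (tr, te) in enumerate(folds):
        ytr = y[tr]
        if np.unique(ytr).size < classes.size:
            warnings.warn(f"fold {fold_i}: training set lacks a class; skipped", stacklevel=2)
            continue
        xtr = x[tr]
        if use_smote:
            bal = smote(xtr, ytr, seed=np.random.default_rng((seed, fold_i)))
            # provenance guard: every synthetic parent is a training-fold row
            assert all(
                p is None or (p[0] < len(tr) and p[1] < len(tr)) for p in bal.provenance
            )
            xtr, ytr = bal.x, bal.y
        pred = train_predict(spec, xtr, ytr, x[te])
        accs.append(float((pred == y[te]).mean()))
        conf += confusion_matrix(y[te], pred, labels=classes)
    if not accs:
        raise ValueError("no usable folds")
    return EvalResult(
        per_fold_accuracy=accs,
        mean_accuracy=float(np.mean(accs)),
        confusion=conf,
        classifier=spec.kind,
        seed=seed,
    )
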