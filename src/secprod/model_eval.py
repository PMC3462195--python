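"""Linear-SVM training, nested cross-validation, AUROC and interpretation.

The classifier is a soft-margin linear support vector machine. Its decision
function for a test object x is the kernel expansion

    f(x) = sum_i alpha_i y_i <phi(x_i), phi(x)> + b,

with alpha the dual coefficients of the support vectors; for a linear kernel
this collapses to f(x) = <w, phi(x)> + b with the explicit weight vector

    w = sum_i alpha_i y_i phi(x_i).

Both routes are implemented and must agree to 1e-6; the named weight vector
is the object interpreted downstream (per-feature contributions, normalized
by the maximum absolute contribution, and compared across classifiers by
Pearson correlation).

Generalization performance is the mean test AUROC of a nested (double)
stratified 10-fold cross-validation: the regularization constant C is chosen
per outer fold by an inner 10-fold loop on the training portion only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

#: Default C grid, decades from 1e-3 to 1e3.
DEFAULT_C_GRID = tuple(10.0**k for k in range(-3, 4))


@dataclass
class TrainedModel:
    """Linear SVM in support-vector form.

    ``support_coeffs`` holds alpha_i * y_i per support vector (sign encodes
    the class), ``support_features`` the corresponding feature rows.
    """

    support_coeffs: np.ndarray
    support_features: np.ndarray
    bias: float
    C: float
    column_names: tuple[str, ...]
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "support_coeffs": self.support_coeffs.tolist(),
            "support_features": self.support_features.tolist(),
            "bias": self.bias,
            "C": self.C,
            "column_names": list(self.column_names),
            "metadata": self.metadata,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrainedModel":
        return cls(
            support_coeffs=np.asarray(d["support_coeffs"], dtype=float),
            support_features=np.asarray(d["support_features"], dtype=float),
            bias=float(d["bias"]),
            C=float(d["C"]),
            column_names=tuple(d["column_names"]),
            metadata=dict(d.get("metadata", {})),
        )


def save_model(model: TrainedModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model.to_dict()))


def load_model(path: str | Path) -> TrainedModel:
    return TrainedModel.from_dict(json.loads(Path(path).read_text()))


@dataclass
class WeightVector:
    """Named per-feature contributions of a trained linear classifier."""

    values: pd.Series
    normalized: bool = False

    def __getitem__(self, name: str) -> float:
        return float(self.values[name])

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.values.index)


@dataclass
class CVResult:
    """Nested cross-validation outcome."""

    fold_aurocs: tuple[float, ...]
    chosen_C: tuple[float, ...]
    fold_assignments: np.ndarray
    seed: int
    models: tuple[TrainedModel, ...] | None = None

    @property
    def mean_auroc(self) -> float:
        return float(np.mean(self.fold_aurocs))


def _check_xy(X: pd.DataFrame, y: np.ndarray) -> None:
    if len(X) != len(y):
        raise ValueError("X and y length mismatch")
    if not ((y == 1).any() and (y == -1).any()):
        raise ValueError("training data must contain both classes")
    if X.isna().any().any():
        raise ValueError("feature matrix contains missing values")


def train_linear_svm(X: pd.DataFrame, y: Sequence[int], C: float = 1.0) -> TrainedModel:
    """Fit a soft-margin linear SVM; deterministic given fixed input order."""
    y = np.asarray(y, dtype=float)
    _check_xy(X, y)
    if C <= 0:
        raise ValueError("C must be positive")
    clf = SVC(kernel="linear", C=C)
    clf.fit(X.values, y)
    return TrainedModel(
        support_coeffs=clf.dual_coef_[0].copy(),
        support_features=clf.support_vectors_.copy(),
        bias=float(clf.intercept_[0]),
        C=C,
        column_names=tuple(X.columns),
    )


def _align_columns(model: TrainedModel, X: pd.DataFrame) -> np.ndarray:
    missing = [c for c in model.column_names if c not in X.columns]
    extra = [c for c in X.columns if c not in model.column_names]
    if missing or extra:
        raise ValueError(
            f"feature columns do not match model: missing={missing}, extra={extra}"
        )
    return X[list(model.column_names)].values


def decision_scores(model: TrainedModel, X: pd.DataFrame) -> np.ndarray:
    """Kernel-expansion decision scores sum_i a_i y_i <x_i, x> + b."""
    if len(X) == 0:
        return np.empty(0)
    mat = _align_columns(model, X)
    return mat @ model.support_features.T @ model.support_coeffs + model.bias


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve, Mann–Whitney formulation (ties count 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    neg = labels == -1
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes required to compute AUROC")
    ranks = stats.rankdata(scores)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _cv_auroc(
    X: pd.DataFrame,
    y: np.ndarray,
    C: float,
    folds: int,
    seed: int,
) -> float:
    """Mean AUROC of a seeded stratified k-fold CV at fixed C."""
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = []
    for train_idx, test_idx in skf.split(X.values, y):
        model = train_linear_svm(X.iloc[train_idx], y[train_idx], C)
        s = decision_scores(model, X.iloc[test_idx])
        scores.append(auroc(s, y[test_idx]))
    return float(np.mean(scores))


def select_C(
    X: pd.DataFrame,
    y: Sequence[int],
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    folds: int = 10,
    seed: int = 0,
) -> tuple[float, float]:
    """Grid-search C by k-fold mean AUROC; smallest C wins ties.

    Returns (best C, its mean AUROC).
    """
    y = np.asarray(y)
    best_C, best_score = None, -np.inf
    for C in sorted(C_grid):
        score = _cv_auroc(X, y, C, folds, seed)
        if score > best_score:
            best_C, best_score = C, score
    return best_C, best_score


def nested_cv(
    X: pd.DataFrame,
    y: Sequence[int],
    outer_folds: int = 10,
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    seed: int = 0,
    inner_folds: int = 10,
    return_models: bool = False,
) -> CVResult:
    """Double stratified CV: C tuned on each training portion, AUROC on test.

    Fold assignments are seeded and stratified; reported performance is the
    mean of the outer-fold test AUROCs.
    """
    y = np.asarray(y)
    _check_xy(X, y)
    n_min = min(int((y == 1).sum()), int((y == -1).sum()))
    if n_min < outer_folds:
        raise ValueError(
            f"smallest class has {n_min} members; use at most {n_min} outer folds"
        )
    skf = StratifiedKFold(n_splits=outer_folds, shuffle=True, random_state=seed)
    fold_assignments = np.empty(len(y), dtype=int)
    fold_aurocs, chosen, models = [], [], []
    for fold, (train_idx, test_idx) in enumerate(skf.split(X.values, y)):
        fold_assignments[test_idx] = fold
        C, _ = select_C(X.iloc[train_idx], y[train_idx], C_grid, inner_folds, seed)
        model = train_linear_svm(X.iloc[train_idx], y[train_idx], C)
        s = decision_scores(model, X.iloc[test_idx])
        fold_aurocs.append(auroc(s, y[test_idx]))
        chosen.append(C)
        if return_models:
            models.append(model)
    return CVResult(
        fold_aurocs=tuple(fold_aurocs),
        chosen_C=tuple(chosen),
        fold_assignments=fold_assignments,
        seed=seed,
        models=tuple(models) if return_models else None,
    )


def extract_weight_vector(model: TrainedModel) -> WeightVector:
    """Explicit weight vector w = sum_i alpha_i y_i phi(x_i), named by column."""
    if model.support_coeffs.size == 0:
        w = np.zeros(len(model.column_names))
    else:
        w = model.support_coeffs @ model.support_features
    return WeightVector(pd.Series(w, index=list(model.column_names)))


def normalize_contributions(w: WeightVector) -> WeightVector:
    """Scale so the maximum absolute contribution is 1; signs preserved."""
    m = float(w.values.abs().max())
    if m == 0:
        raise ValueError("cannot normalize an all-zero weight vector")
    return WeightVector(w.values / m, normalized=True)


def compare_weight_vectors(w1: WeightVector, w2: WeightVector) -> float:
    """Pearson correlation between two aligned weight vectors."""
    if set(w1.names) != set(w2.names):
        raise ValueError("weight vectors have different feature names")
    a = w1.values
    b = w2.values.reindex(a.index)
    r, _ = stats.pearsonr(a.values, b.values)
    return float(r)


def correlate_weights_with_property(
    w: WeightVector,
    prop: Mapping[str, float],
    exclude: Sequence[str] = (),
) -> tuple[float, float]:
    """Pearson correlation between weights and a per-feature property.

    Computed over the intersection of names, minus ``exclude`` (e.g. the
    aromatic residues when correlating amino-acid weights with biosynthetic
    cost). Returns (r, p).
    """
    shared = [n for n in w.names if n in prop and n not in set(exclude)]
    if len(shared) < 3:
        raise ValueError("need at least 3 shared names")
    a = np.array([w[n] for n in shared])
    b = np.array([prop[n] for n in shared])
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


@dataclass
class SelectionResult:
    selected: tuple[str, ...]
    scores: tuple[float, ...]  # inner-CV mean AUROC after each accepted step


def forward_feature_selection(
    X: pd.DataFrame,
    y: Sequence[int],
    candidates: Sequence[str],
    C_fixed: float = 1.0,
    folds: int = 10,
    seed: int = 0,
    max_steps: int | None = None,
) -> SelectionResult:
    """Greedy forward selection scored by inner-CV mean AUROC at fixed C.

    At each step the candidate maximizing the inner-CV score is added (ties
    break on candidate order); selection stops when the best achievable score
    drops below the current one, or after ``max_steps`` features.
    """
    y = np.asarray(y)
    candidates = list(candidates)
    if not candidates:
        raise ValueError("no candidate features")
    missing = [c for c in candidates if c not in X.columns]
    if missing:
        raise ValueError(f"candidates not in matrix: {missing}")
    selected: list[str] = []
    trajectory: list[float] = []
    current = -np.inf
    while candidates:
        if max_steps is not None and len(selected) >= max_steps:
            break
        best_feat, best_score = None, -np.inf
        for feat in candidates:
            score = _cv_auroc(X[selected + [feat]], y, C_fixed, folds, seed)
            if score > best_score:
                best_feat, best_score = feat, score
        if best_score < current:
            break
        selected.append(best_feat)
        candidates.remove(best_feat)
        trajectory.append(best_score)
        current = best_score
    return SelectionResult(tuple(selected), tuple(trajectory))


@dataclass
class TransferResult:
    auroc: float
    C: float
    model: TrainedModel


def transfer_evaluate(
    X_train: pd.DataFrame,
    y_train: Sequence[int],
    X_test: pd.DataFrame,
    y_test: Sequence[int],
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    folds: int = 10,
    seed: int = 0,
) -> TransferResult:
    """Train on one data set (C tuned by CV on it), evaluate AUROC on another."""
    if list(X_train.columns) != list(X_test.columns):
        raise ValueError("train and test feature columns must match")
    y_train = np.asarray(y_train)
    y_test = np.asarray(y_test)
    C, _ = select_C(X_train, y_train, C_grid, folds, seed)
    model = train_linear_svm(X_train, y_train, C)
    scores = decision_scores(model, X_test)
    return TransferResult(auroc(scores, y_test), C, model)
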