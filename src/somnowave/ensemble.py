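"""Ensemble of bagged trees (EBT).

Bootstrap aggregation over CART decision trees: each tree is grown on
a full-size bootstrap resample of the training data (Gini impurity,
best-first growth capped by a split budget, no feature subsampling --
this is bagging, not a random forest), and predictions average the
per-tree leaf class distributions, breaking ties toward the earliest
stage in the canonical class order.

The trees and the bagging loop are scikit-learn estimators behind this
module's surface; the split cap ``max_splits`` maps to
``max_leaf_nodes = max_splits + 1`` (a binary tree with q leaves has
q - 1 internal splits).  A ``learning_rate`` argument is accepted for
config compatibility and ignored with a log note: it is a boosting
parameter with no meaning for bagging.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.dummy import DummyClassifier
from sklearn.ensemble import BaggingClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .stages import STAGES

logger = logging.getLogger(__name__)


def _encode(y: Sequence[str]) -> np.ndarray:
    try:
        return np.array([STAGES.index(v) for v in y])
    except ValueError as exc:
        raise ValueError(f"labels must be drawn from {STAGES}: {exc}") from exc


def _decode(codes: np.ndarray) -> np.ndarray:
    return np.asarray(STAGES, dtype=object)[codes]


def _tree_estimator(max_splits: int | None, seed: int | None):
    if max_splits is not None and max_splits < 0:
        raise ValueError("max_splits must be >= 0")
    if max_splits == 0:
        return DummyClassifier(strategy="prior")
    return DecisionTreeClassifier(
        criterion="gini",
        max_leaf_nodes=None if max_splits is None else max_splits + 1,
        random_state=seed,
    )


def fit_tree(X, y, max_splits: int | None = None, seed: int = 0):
    """Fit one CART tree (split budget ``max_splits``; None = unlimited)."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if len(X) == 0:
        raise ValueError("cannot fit a tree on an empty dataset")
    est = _tree_estimator(max_splits, seed)
    est.fit(X, _encode(y))
    return est


def predict_labels(est, X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    scores = predict_scores(est, X)
    return _decode(np.argmax(scores, axis=1))


def predict_scores(est, X) -> np.ndarray:
    """Class-probability scores, columns in canonical stage order."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    proba = est.predict_proba(X)
    out = np.zeros((len(X), len(STAGES)))
    for j, cls in enumerate(est.classes_):
        out[:, int(cls)] = proba[:, j]
    return out


@dataclass
class BaggedTreeModel:
    """A fitted bagging ensemble plus its configuration."""

    estimator: BaggingClassifier
    n_learners: int
    max_splits: int | None
    seed: int

    @property
    def trees(self) -> list:
        return list(self.estimator.estimators_)

    def predict(self, X) -> tuple[np.ndarray, np.ndarray]:
        """(labels, scores); scores average the per-tree distributions."""
        scores = predict_scores(self.estimator, X)
        labels = _decode(np.argmax(scores, axis=1))
        return labels, scores


def make_bagging(n_learners: int = 50, max_splits: int | None = None,
                 seed: int = 0, learning_rate: float | None = None) -> BaggingClassifier:
    """Unfitted bagging ensemble with the package's conventions."""
    if n_learners < 1:
        raise ValueError("n_learners must be >= 1")
    if learning_rate is not None:
        logger.info(
            "learning_rate=%s accepted for config compatibility but ignored: "
            "it is a boosting parameter with no effect on bagging", learning_rate,
        )
    return BaggingClassifier(
        estimator=_tree_estimator(max_splits, None),
        n_estimators=n_learners,
        max_samples=1.0,
        bootstrap=True,
        bootstrap_features=False,
        random_state=seed & 0x7FFFFFFF,
    )


def fit_bagged(X, y, n_learners: int = 50, max_splits: int | None = None,
               seed: int = 0, learning_rate: float | None = None) -> BaggedTreeModel:
    """Fit the EBT on labelled features; deterministic given ``seed``."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if len(X) == 0:
        raise ValueError("cannot fit on an empty dataset")
    est = make_bagging(n_learners, max_splits, seed, learning_rate)
    est.fit(X, _encode(y))
    return BaggedTreeModel(estimator=est, n_learners=n_learners,
                           max_splits=max_splits, seed=seed)


def tune(
    X,
    y,
    tree_grid: Sequence[int],
    split_grid: Sequence[int | None],
    k: int = 10,
    seed: int = 0,
) -> tuple[np.ndarray, tuple[int, int | None]]:
    """Grid search of (n_learners, max_splits) by k-fold error.

    Returns the misclassification-rate surface (trees x splits) and the
    best pair; ties break toward fewer trees, then fewer splits.  The
    first surface column against ``tree_grid`` is the
    error-versus-number-of-trees curve.
    """
    if not len(tree_grid) or not len(split_grid):
        raise ValueError("grids must be non-empty")
    X = np.asarray(X, dtype=float)
    codes = _encode(y)
    surface = np.empty((len(tree_grid), len(split_grid)))
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed & 0x7FFFFFFF)
    folds = list(skf.split(X, codes))
    for i, n_trees in enumerate(tree_grid):
        for j, splits in enumerate(split_grid):
            errs = []
            for fold_id, (tr, te) in enumerate(folds):
                est = make_bagging(n_trees, splits, seed + 1000 * fold_id)
                est.fit(X[tr], codes[tr])
                errs.append(float(np.mean(est.predict(X[te]) != codes[te])))
            surface[i, j] = np.mean(errs)
    best_flat = int(np.argmin(surface.round(12), axis=None))
    bi, bj = np.unravel_index(best_flat, surface.shape)
    return surface, (int(tree_grid[bi]), split_grid[bj])
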