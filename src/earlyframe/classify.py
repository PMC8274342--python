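"""Repeated stratified hold-out nested cross-validation of a linear SVM on
parcel-mean features, with Friedman comparison of modality configurations."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .ranking import RankingResult, friedman_rank

__all__ = ["CvScheme", "make_splits", "nested_cv_classify", "compare_configurations"]

log = logging.getLogger(__name__)


@dataclass
class CvScheme:
    """Repeated hold-out with class-balanced training sets.

    The training set draws ``training_fraction`` of the smallest class from
    each class (the same count per class, minimizing class imbalance); the
    remainder is the held-out test set.
    """

    iterations: int = 250
    training_fraction: float = 0.8
    inner_folds: int = 5
    c_grid: tuple[float, ...] = (1e-3, 1e-2, 1e-1, 1.0, 1e1, 1e2)
    stratification: str = "balanced"    # or 'proportional'
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.training_fraction < 1.0:
            raise ValueError("training fraction must be in (0, 1)")
        if self.iterations < 1:
            raise ValueError("need at least one iteration")


def make_splits(labels: np.ndarray, scheme: CvScheme) -> list[tuple[np.ndarray, np.ndarray]]:
    """Iteration-indexed (train, test) index pairs, shared across modality
    configurations so their performance comparison is paired."""
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("binary classification only")
    if counts.min() < 3:
        raise ValueError("each class needs at least 3 members")
    n_small = counts.min()
    n_train_small = int(np.floor(scheme.training_fraction * n_small))
    if n_train_small < 2 or n_small - n_train_small < 1:
        raise ValueError("classes too small for the requested training fraction")

    rng = np.random.default_rng(scheme.seed)
    splits = []
    for _ in range(scheme.iterations):
        train_idx = []
        for cls, cnt in zip(classes, counts):
            members = np.flatnonzero(y == cls)
            if scheme.stratification == "balanced":
                n_take = n_train_small
            else:
                n_take = int(np.floor(scheme.training_fraction * cnt))
            train_idx.append(rng.choice(members, size=n_take, replace=False))
        train = np.sort(np.concatenate(train_idx))
        test = np.setdiff1d(np.arange(len(y)), train)
        splits.append((train, test))
    return splits


def _fit_predict(x_train, y_train, x_test, scheme: CvScheme, rng: np.random.Generator):
    best_c, best_score = scheme.c_grid[0], -np.inf
    n_splits = min(scheme.inner_folds, int(np.bincount(y_train).min()))
    inner = StratifiedKFold(n_splits=max(2, n_splits), shuffle=True,
                            random_state=int(rng.integers(2**31 - 1)))
    for c in scheme.c_grid:
        scores = []
        for tr, va in inner.split(x_train, y_train):
            model = Pipeline([
                ("scale", StandardScaler()),
                ("svm", LinearSVC(C=c, dual=True, max_iter=20000)),
            ])
            model.fit(x_train[tr], y_train[tr])
            scores.append(balanced_accuracy_score(y_train[va], model.predict(x_train[va])))
        score = float(np.mean(scores))
        if score > best_score:
            best_c, best_score = c, score
    final = Pipeline([
        ("scale", StandardScaler()),
        ("svm", LinearSVC(C=best_c, dual=True, max_iter=20000)),
    ])
    final.fit(x_train, y_train)
    return final.predict(x_test)


def nested_cv_classify(
    features: np.ndarray,
    labels: np.ndarray,
    scheme: CvScheme | None = None,
    splits: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> np.ndarray:
    """Balanced accuracy of a linear SVM over repeated nested-CV iterations.

    Standardization and the inner regularization search are fit on the
    training split only; returns the length-``iterations`` BACC vector.
    """
    if scheme is None:
        scheme = CvScheme()
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if not np.isfinite(x).all():
        raise ValueError("features must be finite")
    keep = x.std(axis=0) > 0
    if not keep.all():
        log.info("dropping %d constant feature columns", int((~keep).sum()))
        x = x[:, keep]
    if x.shape[1] == 0:
        raise ValueError("no informative features remain")
    if splits is None:
        splits = make_splits(y, scheme)

    rng = np.random.default_rng(scheme.seed + 1)
    bacc = np.empty(len(splits))
    for it, (train, test) in enumerate(splits):
        pred = _fit_predict(x[train], y[train], x[test], scheme, rng)
        bacc[it] = balanced_accuracy_score(y[test], pred)
    return bacc


def compare_configurations(
    bacc_by_config: dict[str, np.ndarray], alpha: float = 0.05
) -> RankingResult:
    """Friedman/Nemenyi ranking of configurations with CV iterations as
    blocks (higher BACC better). Vectors must be paired by iteration."""
    names = list(bacc_by_config)
    lengths = {len(v) for v in bacc_by_config.values()}
    if len(lengths) != 1:
        raise ValueError("BACC vectors are unpaired (unequal iteration counts)")
    table = np.column_stack([bacc_by_config[n] for n in names])
    return friedman_rank(table, names, direction="higher", alpha=alpha)
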