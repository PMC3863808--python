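"""Supervised baseline: cross-validated linear max-margin classification.

A linear support vector machine (LIBSVM backend via scikit-learn) is trained
and tested under stratified k-fold cross-validation; pooled predictions are
summarised as balanced accuracy with the posterior infraliminal probability
as the Bayesian significance measure. The per-subject misclassification
indicator is exposed so it can be compared against mis-clustering via
:func:`genembed.validation.set_agreement`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .embedding import ScoreSpace
from .validation import BinaryConfusion, balanced_accuracy, infraliminal_probability

__all__ = ["CvResult", "crossval_classify"]


@dataclass
class CvResult:
    """Pooled predictions of a cross-validated binary classifier."""

    predicted: np.ndarray
    true: np.ndarray
    fold: np.ndarray
    confusion: BinaryConfusion
    balanced_accuracy: float
    infraliminal_p: float
    misclassified: np.ndarray

    def __post_init__(self):
        if not (
            self.predicted.shape == self.true.shape == self.fold.shape
        ):
            raise ValueError("per-subject vectors must be aligned")
        counts = np.bincount(self.fold)
        if counts.sum() != self.fold.size:
            raise ValueError("folds must partition the subjects")


def crossval_classify(
    space: ScoreSpace | np.ndarray,
    labels: np.ndarray,
    n_folds: int = 5,
    seed: int | None = 0,
    regularisation: float = 1.0,
) -> CvResult:
    """Stratified k-fold linear-SVM classification of a (standardized) space.

    Each fold's classifier sees only its training subjects; predictions are
    pooled across folds, so every subject is predicted exactly once.
    """
    X = space.X if isinstance(space, ScoreSpace) else np.atleast_2d(np.asarray(space, float))
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("labels must be binary")
    if counts.min() < n_folds:
        raise ValueError(
            f"smallest class has {counts.min()} members; needs >= n_folds={n_folds}"
        )
    pos = classes[1]
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    pred = np.empty_like(y)
    fold_idx = np.empty(y.size, int)
    for f, (train, test) in enumerate(skf.split(X, y)):
        clf = SVC(kernel="linear", C=regularisation)
        clf.fit(X[train], y[train])
        pred[test] = clf.predict(X[test])
        fold_idx[test] = f
    conf = BinaryConfusion(
        tp=int(np.sum((pred == pos) & (y == pos))),
        fn=int(np.sum((pred != pos) & (y == pos))),
        tn=int(np.sum((pred != pos) & (y != pos))),
        fp=int(np.sum((pred == pos) & (y != pos))),
    )
    return CvResult(
        predicted=pred,
        true=y,
        fold=fold_idx,
        confusion=conf,
        balanced_accuracy=balanced_accuracy(conf),
        infraliminal_p=infraliminal_probability(conf),
        misclassified=pred != y,
    )
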