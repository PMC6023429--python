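"""Performance evaluation: ROC curves, AUC, thresholds, feature contributions.

The ROC sweep enumerates every unique fused score as a decision threshold
(classify malignant when score >= threshold); AUC is the trapezoidal area.
Feature contributions are out-of-bag permutation importances: for each tree,
the increase in misclassification on its own OOB rows when one input column
is shuffled, averaged over trees and max-normalised — the "relative
contribution" scale used for both FE feature maps and TW per-time-sample
maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .diagnosis import TrainedForest
from .errors import DataError

try:  # sklearn's bootstrap bookkeeping; verified against oob_decision_function_
    from sklearn.ensemble._forest import (
        _generate_unsampled_indices,
        _get_n_samples_bootstrap,
    )

    _HAVE_OOB_INDICES = True
except ImportError:  # pragma: no cover - fallback for other sklearn versions
    _HAVE_OOB_INDICES = False

__all__ = [
    "RocCurve",
    "ImportanceMap",
    "roc_curve",
    "optimal_threshold",
    "feature_contribution_map",
]


@dataclass
class RocCurve:
    """ROC points over a descending threshold sweep plus trapezoidal AUC."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass
class ImportanceMap:
    """Per-input relative contribution in [0,1], max-normalised."""

    values: np.ndarray
    mode: str
    raw: np.ndarray


def roc_curve(scores, labels, positive: str = "malignant") -> RocCurve:
    """ROC by sweeping the decision threshold over all unique scores.

    The curve always starts at (0,0) (threshold above every score) and ends
    at (1,1) (threshold at the minimum score).
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels) == positive
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise DataError("ROC needs both classes present")
    thresholds = np.concatenate([[np.inf], np.unique(scores)[::-1]])
    pred = scores[None, :] >= thresholds[:, None]
    tpr = (pred & y[None, :]).sum(axis=1) / n_pos
    fpr = (pred & ~y[None, :]).sum(axis=1) / n_neg
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc)


def optimal_threshold(roc: RocCurve) -> float:
    """Threshold maximising Youden's J = tpr - fpr; ties go to the lower threshold."""
    j = roc.tpr - roc.fpr
    best = np.flatnonzero(j == j.max())[-1]  # thresholds descend, so last = lowest
    return float(roc.thresholds[best])


def _oob_indices(forest: TrainedForest) -> list[np.ndarray]:
    n = forest.X_train.shape[0]
    n_boot = _get_n_samples_bootstrap(n, forest.estimator.max_samples, None)
    return [
        _generate_unsampled_indices(tree.random_state, n, n_boot, None)
        for tree in forest.estimator.estimators_
    ]


def feature_contribution_map(
    forest: TrainedForest, mode: str = "FE", seed: int = 0
) -> ImportanceMap:
    """Out-of-bag permutation importance per input dimension, max-normalised.

    For every tree, its OOB rows are predicted once intact and once with each
    input column permuted; the importance of a column is the mean OOB error
    increase across trees.  Negative means are clipped to zero before
    normalising by the maximum.
    """
    if forest.X_train is None or not hasattr(forest.estimator, "estimators_"):
        raise DataError("feature contributions require a trained forest")
    if not _HAVE_OOB_INDICES:  # pragma: no cover
        raw = forest.importances.copy()
    else:
        X, y = forest.X_train, forest.y_train
        rng = np.random.default_rng(seed)
        n_features = X.shape[1]
        deltas = np.zeros(n_features)
        n_used = 0
        for tree, oob in zip(forest.estimator.estimators_, _oob_indices(forest)):
            if len(oob) == 0:
                continue
            Xo, yo = X[oob], y[oob]
            base_err = float(np.mean(forest.estimator.classes_[
                np.argmax(tree.predict_proba(Xo), axis=1)
            ] != yo))
            for j in range(n_features):
                Xp = Xo.copy()
                Xp[:, j] = Xo[rng.permutation(len(oob)), j]
                perm_err = float(np.mean(forest.estimator.classes_[
                    np.argmax(tree.predict_proba(Xp), axis=1)
                ] != yo))
                deltas[j] += perm_err - base_err
            n_used += 1
        raw = deltas / max(n_used, 1)
    values = np.clip(raw, 0.0, None)
    vmax = values.max()
    if vmax > 0:
        values = values / vmax
    return ImportanceMap(values=values, mode=mode, raw=raw)
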