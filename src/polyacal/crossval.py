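"""Held-out score generation by cross-validation.

The calibration needs class-conditional distributions of *honest* scores:
each subject's score must come from a model that never saw that subject.
Leave-one-out gives one score per subject from n models; stratified k-fold
gives the same with k models (cheaper, at the cost of slightly coarser
calibration granularity downstream).
"""

from __future__ import annotations

import numpy as np
from sklearn.model_selection import LeaveOneOut, StratifiedKFold

from .samples import ScoreSample

__all__ = ["generate_cv_scores"]


def _folds(y_pos: np.ndarray, cv, seed: int):
    n = y_pos.size
    if isinstance(cv, str):
        if cv.lower() != "loo":
            raise ValueError(f"unknown cv scheme {cv!r}; use 'loo' or an integer k")
        yield from LeaveOneOut().split(np.zeros(n))
        return
    k = int(cv)
    if k < 2:
        raise ValueError("k-fold requires k >= 2")
    # stratified so no training fold loses a whole class
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    yield from skf.split(np.zeros(n), y_pos.astype(int))


def generate_cv_scores(
    features: np.ndarray,
    labels: np.ndarray,
    scorer,
    cv="loo",
    seed: int = 0,
) -> tuple[ScoreSample, ScoreSample]:
    """Score every subject with a model trained on the other folds.

    Parameters
    ----------
    features : (n, p) array
        One row of numeric features per subject.
    labels : (n,) array
        Binary class labels; 1 marks the positive class (0 or 2 the
        negative one).
    scorer : object
        Anything with ``train(features, labels)`` and
        ``score(row) -> float``; retrained from scratch on each fold.
    cv : "loo" or int
        Leave-one-out, or stratified k-fold with ``k = cv``.
    seed : int
        Controls the k-fold shuffle only (LOO is deterministic).

    Returns
    -------
    (x1, x2) : ScoreSample, ScoreSample
        Held-out scores of the positive and negative class respectively.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("features must be 2-D with one row per label")
    pos = _positive(y)
    if pos.sum() < 2 or (~pos).sum() < 2:
        raise ValueError("need at least 2 subjects per class")

    scores = np.empty(y.size)
    for train_idx, test_idx in _folds(pos, cv, seed):
        if len(np.unique(pos[train_idx])) < 2:
            raise ValueError("degenerate fold")
        scorer.train(X[train_idx], y[train_idx])
        for i in test_idx:
            scores[i] = scorer.score(X[i])
    if not np.all(np.isfinite(scores)):
        raise ValueError("scorer produced a non-finite score")
    return (
        ScoreSample(scores[pos], class_label=1),
        ScoreSample(scores[~pos], class_label=2),
    )


def _positive(y: np.ndarray) -> np.ndarray:
    vals = set(np.unique(y).tolist())
    if vals <= {0, 1} or vals <= {1, 2}:
        return y == 1
    raise ValueError(f"labels must be binary ({{0,1}} or {{1,2}}), got {sorted(vals)}")
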