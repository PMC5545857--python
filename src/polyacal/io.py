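"""CSV score tables and prediction output.

Score tables are plain CSV with header columns ``id, score, label`` where
``label`` is 1 for the positive class and 0 for the negative class.
Predictions are written as ``id, score, posterior_h1, log_lik_h1,
log_lik_h2``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .samples import ScoreSample

__all__ = ["read_score_table", "write_score_table", "write_predictions"]

_REQUIRED = ("id", "score", "label")


def read_score_table(path) -> tuple[ScoreSample, ScoreSample]:
    """Read a labelled score CSV and split it by class.

    Returns ``(x1, x2)``: positive-class (label 1) and negative-class
    (label 0) score samples.  Malformed rows raise with the offending
    1-based data row number.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    scores = pd.to_numeric(df["score"], errors="coerce")
    bad = scores.isna() | ~np.isfinite(scores)
    if bad.any():
        row = int(bad.idxmax()) + 1
        raise ValueError(f"{path}: non-numeric or non-finite score at data row {row}")
    labels = pd.to_numeric(df["label"], errors="coerce")
    bad = ~labels.isin([0, 1])
    if bad.any():
        row = int(bad.idxmax()) + 1
        raise ValueError(f"{path}: unknown label at data row {row} (expected 0 or 1)")
    pos = labels == 1
    if not pos.any() or pos.all():
        raise ValueError(f"{path}: both classes (labels 0 and 1) must be present")
    return (
        ScoreSample(scores[pos].to_numpy(), class_label=1),
        ScoreSample(scores[~pos].to_numpy(), class_label=2),
    )


def write_score_table(path, x1: ScoreSample, x2: ScoreSample, ids=None) -> None:
    """Write the two class samples back to the tabular format (label 1/0)."""
    scores = np.concatenate([x1.values, x2.values])
    labels = np.concatenate([np.ones(len(x1), int), np.zeros(len(x2), int)])
    if ids is None:
        ids = np.arange(scores.size)
    pd.DataFrame({"id": ids, "score": scores, "label": labels}).to_csv(path, index=False)


def write_predictions(path, predictions: pd.DataFrame, ids=None) -> None:
    out = predictions.copy()
    out.insert(0, "id", np.arange(len(out)) if ids is None else list(ids))
    out.to_csv(path, index=False)
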