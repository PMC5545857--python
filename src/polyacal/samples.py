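"""Labelled collections of classifier scores.

A :class:`ScoreSample` holds the held-out scores of one class (cases or
controls).  Scores are stored sorted ascending; sorting is the canonical
representation and every consumer may rely on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ScoreSample"]


@dataclass(frozen=True)
class ScoreSample:
    """Sorted, finite, non-empty scores of a single class.

    Parameters
    ----------
    scores : array-like of float
        Real-valued classifier scores, any order; stored sorted ascending.
    class_label : int
        1 for the positive class (cases), 2 for the negative class
        (controls).
    """

    scores: np.ndarray
    class_label: int = 1
    _sorted_list: list = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        arr = np.asarray(self.scores, dtype=float).ravel()
        if arr.size == 0:
            raise ValueError("no training scores")
        if not np.all(np.isfinite(arr)):
            raise ValueError("non-finite score")
        if self.class_label not in (1, 2):
            raise ValueError(f"class_label must be 1 or 2, got {self.class_label}")
        arr = np.sort(arr)
        arr.flags.writeable = False
        object.__setattr__(self, "scores", arr)
        # plain-list view feeds bisect in the tree traversal hot path
        object.__setattr__(self, "_sorted_list", arr.tolist())

    def __len__(self) -> int:
        return self.scores.size

    @property
    def values(self) -> np.ndarray:
        return self.scores

    def shifted(self, offset: float) -> "ScoreSample":
        return ScoreSample(self.scores + offset, self.class_label)
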