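"""Calibration model and results, statsmodels-style.

:class:`PolyaTreeCalibrator` is the model: it is built from the two
class-conditional score samples (or from raw features via cross-validated
scoring) together with the class prior and the partition depth.  Because
the method is nonparametric, ``fit()`` does no optimisation — the sorted
score samples *are* the fitted object — but it validates the inputs,
resolves the prior, and returns a :class:`PolyaTreeCalibrationResults`
carrying the prediction, evaluation, serialisation and summary API.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .evaluation import ReliabilityDiagram, reliability_diagram
from .samples import ScoreSample
from .tree import DEFAULT_MAX_LEVEL, HypothesisResult, _resolve_prior, posterior

__all__ = ["PolyaTreeCalibrator", "PolyaTreeCalibrationResults", "CalibratedPrediction"]


@dataclass(frozen=True)
class CalibratedPrediction:
    """One test score with its posterior and per-hypothesis log marginals."""

    score: float
    posterior_h1: float
    log_lik_h1: float
    log_lik_h2: float


class PolyaTreeCalibrator:
    """Polya-tree score-to-probability calibration model.

    Parameters
    ----------
    x1 : ScoreSample or array-like
        Held-out scores of the positive class (cases).
    x2 : ScoreSample or array-like
        Held-out scores of the negative class (controls).
    prior_h1 : float or "from-class-sizes"
        Prior probability of the positive-class hypothesis.  The default
        derives it from the relative class sizes, |X1| / (|X1| + |X2|);
        a numeric value overrides it (e.g. a known clinical base rate).
    max_level : int
        Depth cap of the nested dyadic partition (default 18).
    provenance : dict, optional
        Free-form record of how the score samples were produced (CV
        scheme, seed); carried through serialisation.

    Examples
    --------
    >>> model = PolyaTreeCalibrator(x1=[-1.2, -0.3, 0.1], x2=[0.9, 1.4, 2.2])
    >>> res = model.fit()
    >>> res.predict([0.0])["posterior_h1"].iloc[0]  # doctest: +SKIP
    """

    def __init__(self, x1, x2, prior_h1="from-class-sizes",
                 max_level: int = DEFAULT_MAX_LEVEL, provenance: dict | None = None):
        self.x1 = x1 if isinstance(x1, ScoreSample) else ScoreSample(x1, class_label=1)
        self.x2 = x2 if isinstance(x2, ScoreSample) else ScoreSample(x2, class_label=2)
        if self.x1.class_label == self.x2.class_label:
            raise ValueError("x1 and x2 must carry distinct class labels")
        if not 1 <= max_level <= 30:
            raise ValueError("max_level must lie in [1, 30]")
        self.prior_h1_spec = prior_h1
        self.max_level = int(max_level)
        self.provenance = dict(provenance or {})

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, score: str = "score",
                       label: str = "label", positive=1, **kwargs) -> "PolyaTreeCalibrator":
        """Build from a tidy table with one score and one binary label per row."""
        if score not in data.columns or label not in data.columns:
            raise ValueError(f"data must have columns {score!r} and {label!r}")
        pos = data[label] == positive
        if pos.all() or not pos.any():
            raise ValueError("both classes must be present")
        return cls(data.loc[pos, score].to_numpy(),
                   data.loc[~pos, score].to_numpy(), **kwargs)

    @classmethod
    def from_cv(cls, features, labels, scorer, cv="loo", seed: int = 0,
                **kwargs) -> "PolyaTreeCalibrator":
        """Build by scoring every subject on held-out cross-validation folds.

        See :func:`polyacal.crossval.generate_cv_scores` for the scorer
        contract and fold schemes.
        """
        from .crossval import generate_cv_scores

        x1, x2 = generate_cv_scores(features, labels, scorer, cv=cv, seed=seed)
        prov = {"cv": "loo" if isinstance(cv, str) else f"{int(cv)}-fold", "seed": seed}
        return cls(x1, x2, provenance=prov, **kwargs)

    def fit(self) -> "PolyaTreeCalibrationResults":
        """Resolve the prior and return the results object."""
        prior = _resolve_prior(self.prior_h1_spec, self.x1, self.x2)
        return PolyaTreeCalibrationResults(self, prior)


class PolyaTreeCalibrationResults:
    """Fitted calibration; maps scores to posterior class probabilities."""

    def __init__(self, model: PolyaTreeCalibrator, prior_h1: float):
        self.model = model
        self.prior_h1 = float(prior_h1)

    # -- prediction ----------------------------------------------------
    def calibrate_one(self, score: float) -> HypothesisResult:
        """Full hypothesis-test result for a single test score."""
        return posterior(score, self.model.x1, self.model.x2,
                         prior_h1=self.prior_h1, max_level=self.model.max_level)

    def predict(self, scores: Sequence[float]) -> pd.DataFrame:
        """Calibrate scores element-wise, preserving input order.

        Returns a frame with columns ``score``, ``posterior_h1``,
        ``log_lik_h1``, ``log_lik_h2``.
        """
        arr = np.asarray(list(np.atleast_1d(scores)), dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("non-finite score")
        rows = [self.calibrate_one(float(s)) for s in arr]
        return pd.DataFrame(
            {
                "score": arr,
                "posterior_h1": [r.posterior_h1 for r in rows],
                "log_lik_h1": [r.log_lik_h1 for r in rows],
                "log_lik_h2": [r.log_lik_h2 for r in rows],
            }
        )

    def predictions(self, scores: Sequence[float]) -> list[CalibratedPrediction]:
        df = self.predict(scores)
        return [CalibratedPrediction(*row) for row in df.itertuples(index=False)]

    # -- evaluation ----------------------------------------------------
    def evaluate(self, scores: Sequence[float], labels: Sequence[int]) -> ReliabilityDiagram:
        """Calibrate labelled test scores and build the reliability diagram."""
        post = self.predict(scores)["posterior_h1"].to_numpy()
        return reliability_diagram(post, labels)

    # -- persistence ---------------------------------------------------
    def to_dict(self) -> dict:
        m = self.model
        return {
            "x1": m.x1.values.tolist(),
            "x2": m.x2.values.tolist(),
            "prior_h1": self.prior_h1,
            "max_level": m.max_level,
            "provenance": m.provenance,
        }

    def save(self, path) -> None:
        """Serialise as JSON; the score samples are the whole model."""
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "PolyaTreeCalibrationResults":
        with open(path) as fh:
            d = json.load(fh)
        model = PolyaTreeCalibrator(
            d["x1"], d["x2"], prior_h1=d["prior_h1"],
            max_level=d["max_level"], provenance=d.get("provenance"),
        )
        return model.fit()

    # -- reporting -----------------------------------------------------
    def summary(self) -> str:
        m = self.model
        lines = [
            "Polya-tree score calibration",
            "=" * 44,
            f"{'positive-class scores (X1)':<32}{len(m.x1):>12d}",
            f"{'negative-class scores (X2)':<32}{len(m.x2):>12d}",
            f"{'prior Pr(H1)':<32}{self.prior_h1:>12.4f}",
            f"{'partition depth cap':<32}{m.max_level:>12d}",
            f"{'X1 score range':<24}[{m.x1.values.min():>9.4f}, {m.x1.values.max():>9.4f}]",
            f"{'X2 score range':<24}[{m.x2.values.min():>9.4f}, {m.x2.values.max():>9.4f}]",
        ]
        if m.provenance:
            lines.append(f"{'provenance':<32}{json.dumps(m.provenance):>12}")
        lines.append("=" * 44)
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (f"<PolyaTreeCalibrationResults: n1={len(self.model.x1)}, "
                f"n2={len(self.model.x2)}, prior_h1={self.prior_h1:.4g}>")
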