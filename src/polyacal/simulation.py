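"""Simulated classifier outputs and the overlap-sweep experiment.

Scores of the positive class are drawn from N(0, 1) and scores of the
negative class from N(delta, 1), where delta is set by the overlap
coefficient of the two unit-variance densities: overlap = 2 * Phi(-delta/2)
(shared area under the two curves; 1 means identical distributions).

The sweep experiment trains the calibrator on 50 + 50 simulated scores,
calibrates 100 balanced test scores, summarises the reliability diagram,
and repeats 20 times per overlap level, averaging the chi-squared p-value,
the number of calibrated points and the range — the three panels of the
method's simulated benchmark.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import norm

from .evaluation import reliability_diagram
from .model import PolyaTreeCalibrator
from .samples import ScoreSample
from .tree import DEFAULT_MAX_LEVEL

__all__ = ["OverlapSpec", "SweepResult", "simulate_scores", "run_overlap_sweep",
           "DEFAULT_OVERLAPS"]

DEFAULT_OVERLAPS = tuple(round(0.1 * k, 1) for k in range(1, 10))


@dataclass(frozen=True)
class OverlapSpec:
    """Overlap coefficient of the two unit-variance Gaussian score models."""

    overlap: float

    def __post_init__(self) -> None:
        if not 0.0 < self.overlap <= 1.0:
            raise ValueError("overlap must lie in (0, 1]")

    @property
    def delta(self) -> float:
        """Mean separation solving overlap = 2*Phi(-delta/2)."""
        return float(-2.0 * ndtri(self.overlap / 2.0))

    @classmethod
    def from_delta(cls, delta: float) -> "OverlapSpec":
        return cls(float(2.0 * norm.cdf(-delta / 2.0)))


@dataclass(frozen=True)
class SweepResult:
    """Per-overlap averages over the repetitions of the sweep."""

    overlaps: np.ndarray
    mean_p_value: np.ndarray
    mean_n_points: np.ndarray
    mean_range: np.ndarray
    n_reps: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "overlap": self.overlaps,
                "mean_p_value": self.mean_p_value,
                "mean_n_points": self.mean_n_points,
                "mean_range": self.mean_range,
            }
        )

    def plot(self, axes=None):
        """Three stacked panels: p-value, calibrated points, range vs overlap."""
        import matplotlib.pyplot as plt

        if axes is None:
            _, axes = plt.subplots(3, 1, sharex=True, figsize=(5, 8))
        panels = [
            (self.mean_p_value, r"mean $\chi^2$ p-value"),
            (self.mean_n_points, "mean calibrated points"),
            (self.mean_range, "mean range"),
        ]
        for ax, (y, label) in zip(axes, panels):
            ax.plot(self.overlaps, y, "o-", color="crimson")
            ax.set_ylabel(label)
        axes[-1].set_xlabel("class-distribution overlap")
        return axes


def simulate_scores(
    spec: OverlapSpec | float,
    n_pos: int,
    n_neg: int,
    seed: int | np.random.Generator = 0,
) -> tuple[ScoreSample, ScoreSample]:
    """Draw positive scores from N(0,1) and negative from N(delta,1)."""
    if not isinstance(spec, OverlapSpec):
        spec = OverlapSpec(float(spec))
    if n_pos < 1 or n_neg < 1:
        raise ValueError("need at least one score per class")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pos = rng.normal(0.0, 1.0, size=n_pos)
    neg = rng.normal(spec.delta, 1.0, size=n_neg)
    return ScoreSample(pos, class_label=1), ScoreSample(neg, class_label=2)


def run_overlap_sweep(
    overlaps=DEFAULT_OVERLAPS,
    n_train_per_class: int = 50,
    n_test: int = 100,
    n_reps: int = 20,
    seed: int = 0,
    max_level: int = DEFAULT_MAX_LEVEL,
) -> SweepResult:
    """Average calibration metrics over repetitions for each overlap level.

    Each repetition simulates fresh training scores (``n_train_per_class``
    per class), fits the calibrator with class-size priors, simulates a
    balanced test set of ``n_test`` scores, calibrates it, and summarises
    the 10-bin reliability diagram.  Fully reproducible given ``seed``.
    """
    overlaps = [OverlapSpec(float(o)) for o in overlaps]
    if n_test < 2:
        raise ValueError("need at least 2 test scores")
    root = np.random.SeedSequence(seed)
    streams = root.spawn(len(overlaps) * n_reps)

    mean_p = np.empty(len(overlaps))
    mean_k = np.empty(len(overlaps))
    mean_r = np.empty(len(overlaps))
    for i, spec in enumerate(overlaps):
        p_vals, k_vals, r_vals = [], [], []
        for rep in range(n_reps):
            rng = np.random.default_rng(streams[i * n_reps + rep])
            x1, x2 = simulate_scores(spec, n_train_per_class, n_train_per_class, rng)
            res = PolyaTreeCalibrator(x1, x2, max_level=max_level).fit()
            n_pos = n_test // 2
            t_pos, t_neg = simulate_scores(spec, n_pos, n_test - n_pos, rng)
            scores = np.concatenate([t_pos.values, t_neg.values])
            labels = np.concatenate([np.ones(n_pos), np.zeros(n_test - n_pos)])
            diagram = reliability_diagram(
                res.predict(scores)["posterior_h1"].to_numpy(), labels
            )
            p_vals.append(diagram.p_value)
            k_vals.append(diagram.n_calibrated_points)
            r_vals.append(diagram.range)
        mean_p[i] = np.mean(p_vals)
        mean_k[i] = np.mean(k_vals)
        mean_r[i] = np.mean(r_vals)
    return SweepResult(
        overlaps=np.asarray([s.overlap for s in overlaps]),
        mean_p_value=mean_p,
        mean_n_points=mean_k,
        mean_range=mean_r,
        n_reps=n_reps,
        seed=seed,
    )
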