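"""Reliability diagrams and calibration metrics.

Predicted probabilities are sorted into 10 fixed-width bins over [0, 1];
each occupied bin contributes a point (mean predicted probability,
empirical positive fraction).  Perfect calibration puts every point on the
diagonal.  Three summary metrics:

* chi2 / p-value — goodness of fit to the diagonal, residuals weighted by
  the inverse standard deviation of each bin's calibrated probability
  (the binomial noise it implies for the bin's positive fraction);
* calibrated points (granularity) — number of occupied bins;
* range — spread between the largest and smallest bin-mean predictions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["ReliabilityDiagram", "reliability_diagram", "chi2_diagonal_fit"]

N_BINS = 10


@dataclass(frozen=True)
class ReliabilityDiagram:
    """Occupied-bin summary of a set of (predicted probability, label) pairs.

    Arrays are aligned over occupied bins only, in bin order.  ``bin_index``
    holds the 0-based index of each occupied bin among the 10 fixed bins
    [0, 0.1), ..., [0.9, 1.0].
    """

    bin_index: np.ndarray
    mean_predicted: np.ndarray
    frac_positive: np.ndarray
    count: np.ndarray
    sd_predicted: np.ndarray
    chi2: float
    dof: int
    p_value: float

    @property
    def n_calibrated_points(self) -> int:
        """Granularity: number of occupied bins."""
        return int(self.bin_index.size)

    @property
    def range(self) -> float:
        """Spread of bin-mean predicted probabilities (0 if one bin)."""
        if self.n_calibrated_points <= 1:
            return 0.0
        return float(self.mean_predicted.max() - self.mean_predicted.min())

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "bin": self.bin_index,
                "mean_predicted": self.mean_predicted,
                "frac_positive": self.frac_positive,
                "count": self.count,
                "sd": self.sd_predicted,
            }
        )

    def plot(self, ax=None, **kwargs):
        """Reliability plot: bin points against the perfect-calibration diagonal."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot([0, 1], [0, 1], "k--", lw=1, label="perfect calibration")
        ax.plot(self.mean_predicted, self.frac_positive, "o-",
                **{"color": "crimson", **kwargs})
        ax.set_xlabel("mean predicted probability")
        ax.set_ylabel("fraction of positives")
        ax.set_xlim(0, 1)
        ax.set_ylim(0, 1)
        return ax


def _bin_sd(mean_pred: float, count: int) -> float:
    """Sampling uncertainty of a bin's positive fraction.

    The calibrated probability predicts the bin's positive fraction to be
    its mean p with binomial noise sqrt(p(1-p)/n); that is the scale on
    which diagonal residuals are judged.  Floored at the half-width
    resolution of a count-based frequency, 1/(2n), so degenerate bins
    (p of exactly 0 or 1) keep a finite weight.
    """
    return max(float(np.sqrt(mean_pred * (1.0 - mean_pred) / count)),
               1.0 / (2.0 * count))


def reliability_diagram(posteriors, labels=None) -> ReliabilityDiagram:
    """Bin predictions and compute the calibration metrics.

    Parameters
    ----------
    posteriors : sequence of float, or sequence of (posterior, label) pairs
        Predicted probabilities of the positive class, in [0, 1].
    labels : sequence of {0, 1}, optional
        True labels (1 = positive); omit if pairs were passed.
    """
    if labels is None:
        arr = np.asarray(posteriors, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("pass (posterior, label) pairs or two separate sequences")
        p, y = arr[:, 0], arr[:, 1]
    else:
        p = np.asarray(posteriors, dtype=float).ravel()
        y = np.asarray(labels, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("no predictions to bin")
    if p.size != y.size:
        raise ValueError("posteriors and labels differ in length")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("posteriors must lie in [0, 1]")
    if not set(np.unique(y).tolist()) <= {0.0, 1.0}:
        raise ValueError("labels must be binary 0/1")

    # bins [0,0.1), ..., [0.9,1.0]; 1.0 goes in the top bin
    idx = np.minimum((p * N_BINS).astype(int), N_BINS - 1)
    occupied, mean_pred, frac_pos, count, sd_pred = [], [], [], [], []
    for b in range(N_BINS):
        mask = idx == b
        c = int(mask.sum())
        if c == 0:
            continue
        occupied.append(b)
        mp = float(p[mask].mean())
        mean_pred.append(mp)
        frac_pos.append(float(y[mask].mean()))
        count.append(c)
        sd_pred.append(_bin_sd(mp, c))

    mean_pred = np.asarray(mean_pred)
    frac_pos = np.asarray(frac_pos)
    sd_pred = np.asarray(sd_pred)
    chi2, dof, p_value = _chi2_stats(mean_pred, frac_pos, sd_pred)
    return ReliabilityDiagram(
        bin_index=np.asarray(occupied),
        mean_predicted=mean_pred,
        frac_positive=frac_pos,
        count=np.asarray(count),
        sd_predicted=sd_pred,
        chi2=chi2,
        dof=dof,
        p_value=p_value,
    )


def chi2_diagonal_fit(diagram: ReliabilityDiagram) -> tuple[float, int, float]:
    """Weighted chi-squared fit of the occupied bins to the diagonal.

    chi2 = sum over occupied bins of
    [(frac_positive - mean_predicted) / sd_predicted]**2, where
    sd_predicted is the standard deviation the bin's calibrated
    probability implies for its positive fraction, sqrt(p*(1-p)/count),
    floored at 1/(2*count).  Degrees of freedom = number of occupied
    bins — the diagonal is fixed, no parameter is estimated.
    """
    return _chi2_stats(
        diagram.mean_predicted, diagram.frac_positive, diagram.sd_predicted
    )


def _chi2_stats(mean_pred, frac_pos, sd_pred) -> tuple[float, int, float]:
    k = np.asarray(mean_pred).size
    if k == 0:
        raise ValueError("no occupied bins")
    resid = (np.asarray(frac_pos) - np.asarray(mean_pred)) / np.asarray(sd_pred)
    chi2 = float(np.sum(resid**2))
    p_value = float(stats.chi2.sf(chi2, df=k))
    return chi2, int(k), p_value
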