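"""Polya-tree two-sample posterior for a single test score.

The score axis is wrapped in a nested dyadic partition (a Polya tree).  At
every split the three samples involved — the test score Xp, the positive
class scores X1 and the negative class scores X2 — contribute left/right
counts, and each split carries a Beta(alpha_L, alpha_L) prior on the
probability of falling right versus left, with alpha_L = L**2 at level L.
Under hypothesis H1 ("Xp came from the parent distribution of X1") the test
score shares its split probabilities with X1; under H2 it shares them with
X2.  Integrating the Beta-binomial products in closed form gives a
per-split marginal likelihood that is a pure ratio of gamma functions; the
full marginal is the product over all splits, and Bayes' rule with the
class priors yields the calibrated posterior Pr(H1 | Xp, X1, X2).

All likelihood arithmetic is done in natural-log space via log-gamma; the
product over up to 2**18 splits underflows hopelessly in linear space.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln

from .samples import ScoreSample

__all__ = [
    "PartitionTree",
    "CountTriple",
    "HypothesisResult",
    "build_partition",
    "count_node",
    "level_log_likelihood",
    "log_marginal",
    "posterior",
]

DEFAULT_MAX_LEVEL = 18
_HALF_WIDTH_FLOOR = 1e-6  # degenerate-spread floor, score units
_PAD = 1e-9  # relative padding keeping the max strictly inside [lower, upper)

# log-gamma lookup for integer arguments (counts + L**2 are always integers
# in the traversal); grown lazily, index 0 unused
_LGAMMA = np.empty(0)


def _lgamma_table(n_max: int) -> np.ndarray:
    global _LGAMMA
    if _LGAMMA.size <= n_max:
        size = max(n_max + 1, 2 * _LGAMMA.size, 1024)
        _LGAMMA = gammaln(np.arange(size, dtype=float))
    return _LGAMMA


@dataclass(frozen=True)
class PartitionTree:
    """Nested dyadic partition of the score axis.

    The bin of the node with binary-string index ``s`` at level ``L`` is
    ``[lower + k*w, lower + (k+1)*w)`` with ``w = (upper - lower) / 2**L``
    and ``k = int(s, 2)``; the root (empty string, level 0) is the whole
    half-open interval ``[lower, upper)``.
    """

    lower: float
    upper: float
    max_level: int = DEFAULT_MAX_LEVEL

    def __post_init__(self) -> None:
        if not (self.lower < self.upper):
            raise ValueError("lower must be strictly below upper")
        if self.max_level < 1:
            raise ValueError("max_level must be >= 1")

    @staticmethod
    def alpha(level: int) -> float:
        """Beta-prior concentration at a given level: alpha_L = L**2."""
        if level < 1:
            raise ValueError("levels are indexed from 1")
        return float(level * level)

    def node_bin(self, node: str) -> tuple[float, float]:
        """Half-open bin ``[a, b)`` of a binary-string node index."""
        level = len(node)
        if level > self.max_level:
            raise ValueError(f"node {node!r} deeper than max_level {self.max_level}")
        if node and set(node) - {"0", "1"}:
            raise ValueError(f"invalid node index {node!r}")
        k = int(node, 2) if node else 0
        w = (self.upper - self.lower) / (1 << level)
        return self.lower + k * w, self.lower + (k + 1) * w

    def contains(self, x: float) -> bool:
        return self.lower <= x < self.upper


@dataclass(frozen=True)
class CountTriple:
    """Left/right counts of the three samples at one node's midpoint split.

    ``l`` counts the test point(s), ``m`` the positive class X1, ``n`` the
    negative class X2; suffix 0 = left half, 1 = right half.
    """

    node: str
    l0: int
    l1: int
    m0: int
    m1: int
    n0: int
    n1: int

    def __post_init__(self) -> None:
        if min(self.l0, self.l1, self.m0, self.m1, self.n0, self.n1) < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class HypothesisResult:
    """Posterior over the two class-membership hypotheses for one score."""

    log_lik_h1: float
    log_lik_h2: float
    prior_h1: float
    prior_h2: float
    posterior_h1: float

    @property
    def posterior_h2(self) -> float:
        return 1.0 - self.posterior_h1


def _pooled(samples: Iterable[ScoreSample | np.ndarray]) -> np.ndarray:
    arrs = []
    for s in samples:
        arrs.append(s.values if isinstance(s, ScoreSample) else np.asarray(s, float).ravel())
    return np.concatenate(arrs) if arrs else np.empty(0)


def build_partition(
    train: ScoreSample | Sequence[ScoreSample],
    test_points: Sequence[float] = (),
    max_level: int = DEFAULT_MAX_LEVEL,
) -> PartitionTree:
    """Bound the partition space around the pooled training scores.

    The interval is centered at the median of the pooled training scores
    and its half-width grown symmetrically until every training and test
    point lies inside; a hair of relative padding keeps the maximum
    strictly inside the half-open interval.

    Parameters
    ----------
    train : ScoreSample or sequence of ScoreSample
        Training score samples (typically X1 and X2); pooled for the
        median and the span.
    test_points : sequence of float
        Scores that must also fall inside the partition space.
    max_level : int
        Depth cap of the nested partition.
    """
    if isinstance(train, ScoreSample):
        train = [train]
    pool = _pooled(train)
    if pool.size == 0:
        raise ValueError("no training scores")
    test = np.asarray(list(test_points), dtype=float)
    if not np.all(np.isfinite(pool)) or (test.size and not np.all(np.isfinite(test))):
        raise ValueError("non-finite score")
    center = float(np.median(pool))
    allpts = np.concatenate([pool, test]) if test.size else pool
    half = max(center - float(allpts.min()), float(allpts.max()) - center)
    half = max(half * (1.0 + _PAD), _HALF_WIDTH_FLOOR)
    return PartitionTree(center - half, center + half, max_level)


def count_node(
    tree: PartitionTree,
    node: str,
    xp: float,
    x1: ScoreSample,
    x2: ScoreSample,
) -> CountTriple:
    """Count the three samples into the two halves of a node's bin.

    Bins are half-open ``[a, mid)`` / ``[mid, b)``; a point exactly at the
    midpoint counts right.
    """
    if len(node) >= tree.max_level:
        raise ValueError(f"node {node!r} at or beyond max_level {tree.max_level}")
    a, b = tree.node_bin(node)
    mid = 0.5 * (a + b)

    def split(vals: np.ndarray) -> tuple[int, int]:
        inside = vals[(vals >= a) & (vals < b)]
        left = int(np.count_nonzero(inside < mid))
        return left, int(inside.size) - left

    l0, l1 = split(np.asarray([xp], dtype=float))
    m0, m1 = split(x1.values)
    n0, n1 = split(x2.values)
    return CountTriple(node, l0, l1, m0, m1, n0, n1)


def level_log_likelihood(
    counts: CountTriple, alpha: float, hypothesis: str = "H1"
) -> float:
    """Closed-form log marginal likelihood of one split.

    Under H1 the test-point counts are pooled with the positive class
    (Beta-binomial with the X1 counts) while the negative class gets its
    own Beta-binomial factor; under H2 the roles of X1 and X2 swap:

        [Gamma(2a)/Gamma(a)^2]^2
        * Gamma(l0+m0+a) Gamma(l1+m1+a) / Gamma(l0+l1+m0+m1+2a)
        * Gamma(n0+a) Gamma(n1+a) / Gamma(n0+n1+2a)

    evaluated entirely through log-gamma.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if hypothesis == "H1":
        u0, u1 = counts.l0 + counts.m0, counts.l1 + counts.m1
        v0, v1 = counts.n0, counts.n1
    elif hypothesis == "H2":
        u0, u1 = counts.l0 + counts.n0, counts.l1 + counts.n1
        v0, v1 = counts.m0, counts.m1
    else:
        raise ValueError("hypothesis must be 'H1' or 'H2'")
    a = float(alpha)
    norm = 2.0 * (gammaln(2 * a) - 2.0 * gammaln(a))
    pooled = gammaln(u0 + a) + gammaln(u1 + a) - gammaln(u0 + u1 + 2 * a)
    lone = gammaln(v0 + a) + gammaln(v1 + a) - gammaln(v0 + v1 + 2 * a)
    return float(norm + pooled + lone)


def _log_marginals(
    tree: PartitionTree, xp: float, x1: ScoreSample, x2: ScoreSample
) -> tuple[float, float]:
    """Log marginal likelihoods under H1 and H2 in one traversal.

    Splitting a node stops once it holds at most one point across the
    three samples, once all its occupants are numerically identical
    (further halving is pure floating-point redundancy), or at the level
    cap.  Integer-argument log-gamma values come from a shared table.
    """
    for v in (xp, *x1.values[[0, -1]], *x2.values[[0, -1]]):
        if not tree.contains(float(v)):
            raise ValueError("score outside partition space")
    s1: list = x1._sorted_list
    s2: list = x2._sorted_list
    n1, n2 = len(s1), len(s2)
    max_level = tree.max_level
    lg = _lgamma_table(n1 + n2 + 1 + 2 * max_level * max_level + 2)
    lower, width = tree.lower, tree.upper - tree.lower

    llh1 = 0.0
    llh2 = 0.0
    # node state: (level, k, i1lo, i1hi, i2lo, i2hi, xp_in_node)
    stack = [(0, 0, 0, n1, 0, n2, True)]
    while stack:
        level, k, i1lo, i1hi, i2lo, i2hi, has_xp = stack.pop()
        total = (i1hi - i1lo) + (i2hi - i2lo) + has_xp
        if total <= 1 or level >= max_level:
            continue
        # all occupants bitwise-identical -> cannot be partitioned further
        vmin = vmax = xp if has_xp else (s1[i1lo] if i1hi > i1lo else s2[i2lo])
        if i1hi > i1lo:
            vmin = min(vmin, s1[i1lo])
            vmax = max(vmax, s1[i1hi - 1])
        if i2hi > i2lo:
            vmin = min(vmin, s2[i2lo])
            vmax = max(vmax, s2[i2hi - 1])
        if vmin == vmax:
            continue

        child_level = level + 1
        mid = lower + (2 * k + 1) * width / (1 << child_level)
        i1mid = bisect_left(s1, mid, i1lo, i1hi)
        i2mid = bisect_left(s2, mid, i2lo, i2hi)
        m0, m1 = i1mid - i1lo, i1hi - i1mid
        n0, n1_ = i2mid - i2lo, i2hi - i2mid
        xp_left = has_xp and xp < mid
        l0 = 1 if xp_left else 0
        l1 = has_xp - l0

        a = child_level * child_level
        a2 = 2 * a
        norm = 2.0 * (lg[a2] - 2.0 * lg[a])
        h1 = (
            lg[l0 + m0 + a] + lg[l1 + m1 + a] - lg[l0 + l1 + m0 + m1 + a2]
            + lg[n0 + a] + lg[n1_ + a] - lg[n0 + n1_ + a2]
        )
        h2 = (
            lg[l0 + n0 + a] + lg[l1 + n1_ + a] - lg[l0 + l1 + n0 + n1_ + a2]
            + lg[m0 + a] + lg[m1 + a] - lg[m0 + m1 + a2]
        )
        llh1 += norm + h1
        llh2 += norm + h2

        stack.append((child_level, 2 * k, i1lo, i1mid, i2lo, i2mid, bool(xp_left)))
        stack.append((child_level, 2 * k + 1, i1mid, i1hi, i2mid, i2hi, has_xp and not xp_left))
    return llh1, llh2


def log_marginal(
    tree: PartitionTree,
    xp: float,
    x1: ScoreSample,
    x2: ScoreSample,
    hypothesis: str = "H1",
) -> float:
    """Log Pr(Xp, X1, X2 | hypothesis): product of split likelihoods.

    Sums :func:`level_log_likelihood` over every split from level 1 down
    to the stopping level of each branch (see :func:`_log_marginals` for
    the stopping rule).
    """
    h1, h2 = _log_marginals(tree, xp, x1, x2)
    if hypothesis == "H1":
        return h1
    if hypothesis == "H2":
        return h2
    raise ValueError("hypothesis must be 'H1' or 'H2'")


def _resolve_prior(prior_h1, x1: ScoreSample, x2: ScoreSample) -> float:
    if isinstance(prior_h1, str):
        if prior_h1 != "from-class-sizes":
            raise ValueError(f"unknown prior spec {prior_h1!r}")
        return len(x1) / (len(x1) + len(x2))
    p = float(prior_h1)
    if not 0.0 < p < 1.0:
        raise ValueError("prior_h1 must lie strictly in (0, 1)")
    return p


def posterior(
    xp: float,
    x1: ScoreSample,
    x2: ScoreSample,
    prior_h1="from-class-sizes",
    max_level: int = DEFAULT_MAX_LEVEL,
) -> HypothesisResult:
    """Posterior probability that ``xp`` came from the parent of ``x1``.

    Builds the partition from both training samples plus the test score,
    evaluates both log marginals, and combines them with the class priors
    by stable log-sum-exp normalisation.  ``prior_h1="from-class-sizes"``
    uses |X1| / (|X1| + |X2|).
    """
    if not np.isfinite(xp):
        raise ValueError("non-finite score")
    p1 = _resolve_prior(prior_h1, x1, x2)
    tree = build_partition([x1, x2], [xp], max_level=max_level)
    llh1, llh2 = _log_marginals(tree, float(xp), x1, x2)
    d = (llh2 + np.log1p(-p1)) - (llh1 + np.log(p1))
    # posterior_h1 = 1 / (1 + exp(d)); exp underflows harmlessly for d << 0,
    # the cap prevents overflow for d >> 0 (posterior rounds to 0)
    post = 1.0 / (1.0 + np.exp(min(d, 745.0)))
    return HypothesisResult(
        log_lik_h1=llh1,
        log_lik_h2=llh2,
        prior_h1=p1,
        prior_h2=1.0 - p1,
        posterior_h1=float(post),
    )
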