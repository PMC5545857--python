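"""Unit and property tests for the Polya-tree partition and posterior."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.stats import beta as beta_dist

from polyacal import (
    CountTriple,
    PartitionTree,
    ScoreSample,
    build_partition,
    count_node,
    level_log_likelihood,
    log_marginal,
    posterior,
)


# ---------------------------------------------------------------- partition
class TestBuildPartition:
    def test_symmetric_about_median(self):
        tree = build_partition(ScoreSample([0, 1, 2, 3]))
        center = 0.5 * (tree.lower + tree.upper)
        assert center == pytest.approx(1.5, abs=1e-12)
        assert tree.lower <= 0 and tree.upper > 3
        assert tree.upper - 1.5 == pytest.approx(1.5, rel=1e-8)

    def test_degenerate_spread_floor(self):
        tree = build_partition(ScoreSample([5.0]), [5.0])
        assert tree.lower < 5.0 < tree.upper
        assert tree.upper - tree.lower >= 2e-6

    def test_outlying_test_point_expands_bounds(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            train = ScoreSample(rng.normal(0, 1, 200))
            tree = build_partition(train, [4.0])
            assert tree.contains(4.0)
            assert all(tree.contains(v) for v in train.values)

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError, match="no training scores"):
            build_partition([], [1.0])

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            ScoreSample([0.0, np.nan])
        with pytest.raises(ValueError, match="non-finite"):
            build_partition(ScoreSample([0.0, 1.0]), [np.inf])

    def test_bins_tile_each_level(self):
        tree = PartitionTree(0.0, 8.0, max_level=4)
        for level in range(1, 5):
            nodes = [format(k, f"0{level}b") for k in range(2**level)]
            edges = [tree.node_bin(s) for s in nodes]
            assert edges[0][0] == tree.lower and edges[-1][1] == tree.upper
            for (_, b), (a2, _) in zip(edges, edges[1:]):
                assert b == a2


# ---------------------------------------------------------------- counting
class TestCountNode:
    def setup_method(self):
        self.tree = PartitionTree(0.0, 4.0, max_level=6)

    def test_direct_count(self):
        x1 = ScoreSample([0.5, 1.0, 3.0], 1)
        x2 = ScoreSample([7.7], 2)  # outside the root bin: counts as nothing
        c = count_node(self.tree, "", 3.9, x1, x2)
        assert (c.m0, c.m1) == (2, 1)
        assert (c.n0, c.n1) == (0, 0)
        assert (c.l0, c.l1) == (0, 1)

    def test_midpoint_tie_goes_right(self):
        x1 = ScoreSample([0.5], 1)
        c = count_node(self.tree, "", 2.0, x1, ScoreSample([3.0], 2))
        assert (c.l0, c.l1) == (0, 1)

    def test_children_sum_to_parent_halves(self):
        rng = np.random.default_rng(5)
        x1 = ScoreSample(rng.uniform(0, 4, 50), 1)
        x2 = ScoreSample(rng.uniform(0, 4, 50), 2)
        xp = float(rng.uniform(0, 4))
        for level in range(5):
            for k in range(2**level):
                node = format(k, f"0{level}b") if level else ""
                parent = count_node(self.tree, node, xp, x1, x2)
                left = count_node(self.tree, node + "0", xp, x1, x2)
                right = count_node(self.tree, node + "1", xp, x1, x2)
                assert left.m0 + left.m1 == parent.m0
                assert right.m0 + right.m1 == parent.m1
                assert left.n0 + left.n1 == parent.n0
                assert right.n0 + right.n1 == parent.n1
                assert left.l0 + left.l1 == parent.l0
                assert right.l0 + right.l1 == parent.l1

    def test_node_beyond_cap_rejected(self):
        with pytest.raises(ValueError):
            count_node(self.tree, "0" * 6, 1.0, ScoreSample([1.0]), ScoreSample([2.0], 2))


# ------------------------------------------------------- split likelihood
def beta_binomial_integral(u0, u1, alpha, _cache={}):
    """Independent oracle: numeric Beta-weighted binomial-product integral."""
    key = (u0, u1, alpha)
    if key not in _cache:
        _cache[key] = quad(
            lambda t: beta_dist.pdf(t, alpha, alpha) * t**u0 * (1 - t) ** u1,
            0, 1, epsabs=1e-14, epsrel=1e-12,
        )[0]
    return _cache[key]


class TestLevelLogLikelihood:
    def test_single_point_splits_evenly_under_uniform_prior(self):
        c = CountTriple("", 1, 0, 0, 0, 0, 0)
        assert level_log_likelihood(c, 1.0, "H1") == pytest.approx(math.log(0.5))

    def test_empty_counts_normalise_to_one(self):
        c = CountTriple("", 0, 0, 0, 0, 0, 0)
        for alpha in (1.0, 2.5, 9.0):
            for hyp in ("H1", "H2"):
                assert level_log_likelihood(c, alpha, hyp) == pytest.approx(0.0, abs=1e-12)

    def test_known_closed_form_value(self):
        # pooled factor Γ(5)Γ(2)/Γ(7) = 1/30, lone factor Γ(2)Γ(4)/Γ(6) = 1/20
        c = CountTriple("", 1, 0, 3, 1, 1, 3)
        assert math.exp(level_log_likelihood(c, 1.0, "H1")) == pytest.approx(1 / 600, rel=1e-12)

    @pytest.mark.parametrize("alpha", [1.0, 4.0])
    @pytest.mark.parametrize("counts", [
        (1, 0, 2, 3, 0, 1), (0, 1, 5, 0, 2, 2), (1, 0, 0, 0, 4, 4), (0, 0, 3, 3, 3, 3),
    ])
    def test_matches_integration_oracle(self, counts, alpha):
        c = CountTriple("", *counts)
        for hyp in ("H1", "H2"):
            got = math.exp(level_log_likelihood(c, alpha, hyp))
            if hyp == "H1":
                want = (beta_binomial_integral(c.l0 + c.m0, c.l1 + c.m1, alpha)
                        * beta_binomial_integral(c.n0, c.n1, alpha))
            else:
                want = (beta_binomial_integral(c.l0 + c.n0, c.l1 + c.n1, alpha)
                        * beta_binomial_integral(c.m0, c.m1, alpha))
            assert got == pytest.approx(want, rel=1e-6)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            CountTriple("", -1, 0, 0, 0, 0, 0)
        with pytest.raises(ValueError):
            level_log_likelihood(CountTriple("", 1, 0, 0, 0, 0, 0), 0.0)
        with pytest.raises(ValueError):
            level_log_likelihood(CountTriple("", 1, 0, 0, 0, 0, 0), 1.0, "H3")


# ----------------------------------------------------------- log marginal
class TestLogMarginal:
    def test_identical_samples_give_equal_marginals(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(0, 1, 30)
        x1, x2 = ScoreSample(vals, 1), ScoreSample(vals.copy(), 2)
        tree = build_partition([x1, x2], [0.37])
        assert log_marginal(tree, 0.37, x1, x2, "H1") == log_marginal(tree, 0.37, x1, x2, "H2")

    def test_single_level_tree_is_root_split(self):
        x1 = ScoreSample([0.2, 0.4, 2.5], 1)
        x2 = ScoreSample([1.2, 3.1], 2)
        tree = PartitionTree(0.0, 4.0, max_level=1)
        counts = count_node(PartitionTree(0.0, 4.0, max_level=2), "", 0.9, x1, x2)
        for hyp in ("H1", "H2"):
            assert log_marginal(tree, 0.9, x1, x2, hyp) == pytest.approx(
                level_log_likelihood(counts, 1.0, hyp), rel=1e-12
            )

    def test_depth_cap_cannot_shift_the_hypothesis_contrast(self):
        """Levels past the stopping depth only ever split lone or paired
        stragglers, which multiply both hypotheses' marginals by the same
        factor — the H1/H2 contrast (and hence the posterior) is
        depth-cap invariant."""
        for s in range(10):
            rng = np.random.default_rng(100 + s)
            x1 = ScoreSample(rng.normal(0, 1, 30), 1)
            x2 = ScoreSample(rng.normal(1, 1, 30), 2)
            tree18 = build_partition([x1, x2], [0.5], max_level=18)
            tree25 = build_partition([x1, x2], [0.5], max_level=25)
            c18 = (log_marginal(tree18, 0.5, x1, x2, "H1")
                   - log_marginal(tree18, 0.5, x1, x2, "H2"))
            c25 = (log_marginal(tree25, 0.5, x1, x2, "H1")
                   - log_marginal(tree25, 0.5, x1, x2, "H2"))
            assert c18 == pytest.approx(c25, abs=1e-10)

    def test_point_outside_bounds_rejected(self):
        x1, x2 = ScoreSample([0.0, 1.0], 1), ScoreSample([2.0, 3.0], 2)
        tree = build_partition([x1, x2])
        with pytest.raises(ValueError, match="outside partition space"):
            log_marginal(tree, 99.0, x1, x2, "H1")


# --------------------------------------------------------------- posterior
class TestPosterior:
    def test_identical_samples_recover_the_prior(self):
        vals = np.linspace(-1, 1, 25)
        x1, x2 = ScoreSample(vals, 1), ScoreSample(vals.copy(), 2)
        assert posterior(0.1, x1, x2, 0.5).posterior_h1 == 0.5
        assert posterior(0.1, x1, x2, 0.3).posterior_h1 == pytest.approx(0.3, abs=1e-12)

    def test_class_size_prior(self):
        x1 = ScoreSample(np.arange(161, dtype=float), 1)
        x2 = ScoreSample(np.arange(153, dtype=float) + 0.5, 2)
        r = posterior(80.0, x1, x2, "from-class-sizes")
        assert r.prior_h1 == pytest.approx(161 / 314)
        assert r.prior_h1 + r.prior_h2 == pytest.approx(1.0, abs=1e-15)

    @given(st.integers(0, 2**32 - 1), st.floats(0.05, 0.95))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_label_swap_antisymmetry(self, seed, prior):
        rng = np.random.default_rng(seed)
        x1 = ScoreSample(rng.normal(0, 1, 15), 1)
        x2 = ScoreSample(rng.normal(0.8, 1.2, 12), 2)
        xp = float(rng.normal(0.4, 1))
        p = posterior(xp, x1, x2, prior).posterior_h1
        q = posterior(xp, ScoreSample(x2.values, 1), ScoreSample(x1.values, 2),
                      1 - prior).posterior_h1
        assert p + q == pytest.approx(1.0, abs=1e-12)
        assert 0.0 <= p <= 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_translation_and_reflection_equivariance(self, seed):
        rng = np.random.default_rng(seed)
        x1 = ScoreSample(rng.normal(0, 1, 20), 1)
        x2 = ScoreSample(rng.normal(1.5, 1, 20), 2)
        xp = float(rng.normal(0.7, 1))
        base = posterior(xp, x1, x2, 0.5).posterior_h1
        shifted = posterior(xp + 10.0, x1.shifted(10.0), x2.shifted(10.0), 0.5).posterior_h1
        mirrored = posterior(-xp, ScoreSample(-x1.values, 1),
                             ScoreSample(-x2.values, 2), 0.5).posterior_h1
        assert shifted == pytest.approx(base, abs=1e-6)
        assert mirrored == pytest.approx(base, abs=1e-6)

    def test_midpoint_of_balanced_gaussians_is_uncertain(self):
        rng = np.random.default_rng(42)
        x1 = ScoreSample(rng.normal(0, 1, 1000), 1)
        x2 = ScoreSample(rng.normal(2, 1, 1000), 2)
        # analytic posterior at the midpoint of the two means is exactly 1/2
        r = posterior(1.0, x1, x2, 0.5)
        assert r.posterior_h1 == pytest.approx(0.5, abs=0.1)

    def test_bad_prior_rejected(self):
        x1, x2 = ScoreSample([0.0, 1.0], 1), ScoreSample([2.0, 3.0], 2)
        for bad in (0.0, 1.0, -0.2, "quantile"):
            with pytest.raises(ValueError):
                posterior(1.0, x1, x2, bad)
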