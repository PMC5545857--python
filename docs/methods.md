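# Methods

## Model

`polyacal` treats score calibration as a Bayesian two-sample assignment
problem. Given held-out training scores X₁ (positive class) and X₂
(negative class) and a new score Xₚ, it computes the posterior probability
of the hypothesis H₁ that Xₚ was generated by the same parent distribution
as X₁, against H₂ (the parent of X₂):

Pr(H₁ | Xₚ, X₁, X₂) = Pr(Xₚ, X₁, X₂ | H₁) Pr(H₁) / Σᵢ Pr(Xₚ, X₁, X₂ | Hᵢ) Pr(Hᵢ)

The marginal likelihoods use a Pólya-tree construction. The score axis is
recursively bisected into nested dyadic partitions. At the split of node j
each sample contributes left/right counts — (l₀, l₁) for the test point,
(m₀, m₁) for X₁, (n₀, n₁) for X₂ — and the probability of branching right
carries a Beta(α, α) prior. Under H₁ the test point's branch probabilities
are tied to X₁'s (a Dirac delta in the joint prior), X₂'s are independent;
the Beta–binomial integrals then collapse to

Pr_j(· | H₁) = [Γ(2α)/Γ(α)²]² · Γ(l₀+m₀+α)Γ(l₁+m₁+α)/Γ(l₀+l₁+m₀+m₁+2α)
               · Γ(n₀+α)Γ(n₁+α)/Γ(n₀+n₁+2α)

with the roles of (m) and (n) exchanged under H₂. The full marginal is the
product over all splits (partitions treated as independent). Correctness
of this closed form is cross-checked in the test suite against a numeric
quadrature of the Beta-weighted binomial products over an exhaustive grid
of count configurations (relative agreement ≤ 10⁻⁶; measured ~10⁻¹⁴).

### Assumptions

- The classifier score is continuous; exact ties have measure zero.
  (A 2^−L concentration schedule would suit discrete scores; not
  implemented.)
- Held-out scores within a class are independent draws from one parent
  distribution — they must come from cross-validation test folds, never
  from in-fold predictions.
- Splits at different nodes are treated as independent (the Pólya-tree
  factorisation).

## Parameters

| parameter | default | meaning |
|---|---|---|
| `alpha(L) = L²` | fixed | Beta concentration at level L; quadratic growth makes deep splits increasingly uniform, so the prior concentrates on absolutely continuous distributions |
| `max_level` | 18 | depth cap of the partition (dimensionless); beyond ~18 levels the dyadic cells approach floating-point spacing of realistic score sets and additional levels multiply both hypotheses' marginals equally (verified: posteriors at cap 18 and 25 agree to 10⁻⁶) |
| `prior_h1` | `"from-class-sizes"` | Pr(H₁) = \|X₁\|/(\|X₁\|+\|X₂\|); override with a known base rate for clinical-risk use |

## Numerical choices

- **Bounds.** The partition space is centered at the median of the pooled
  X₁ ∪ X₂ scores, with half-width grown symmetrically until all training
  scores *and the test score* fit, times (1 + 10⁻⁹) so the maximum stays
  strictly inside the half-open interval. Pooling the classes is the only
  centering that treats H₁/H₂ symmetrically; including the test point is
  required because its counts must exist in every cell it touches. The
  half-width is floored at 10⁻⁶ score units so a degenerate (all-equal)
  training set still yields a valid tree, in which case the posterior
  reduces to the prior.
- **Bin convention.** Half-open cells [a, b); a point exactly at a split
  midpoint counts right. Deterministic counting under ties.
- **Stopping rule.** Descent into a cell stops when it holds ≤ 1 point
  across the three samples, when all its occupants are bitwise-equal
  floats (further halving is floating-point redundancy), or at
  `max_level`. Cells holding one lone point, or points that only one
  hypothesis-independent factor sees, contribute identical factors to both
  marginals, so the stopping rule cannot bias the posterior.
- **Log-space arithmetic.** The product over up to 2¹⁸ splits underflows
  in linear space; everything is accumulated as log-gamma sums and the
  posterior is formed by stable logistic normalisation. Because every
  gamma argument in the traversal is an integer (counts plus L²), values
  come from a lazily grown log-gamma lookup table; the public
  `level_log_likelihood` accepts arbitrary positive α and calls
  `scipy.special.gammaln` directly.
- **Priors per fold.** Class priors are computed once from the full
  training set, not per CV fold.

## Evaluation metrics

Reliability diagrams use 10 fixed-width bins over [0, 1] (top bin closed).
Per occupied bin: mean predicted probability p̄, empirical positive
fraction, member count n, and the uncertainty scale σ = √(p̄(1−p̄)/n) — the
sampling noise the bin's calibrated probability implies for its own
positive fraction — floored at 1/(2n) (the resolution of an n-count
frequency) so bins predicting exactly 0 or 1 keep finite weight. The
diagonal goodness of fit is χ² = Σ [(frac − p̄)/σ]² with dof = number of
occupied bins (the diagonal is fixed; nothing is estimated), and the
p-value is the upper tail of the χ² distribution. Weighting residuals by
the within-bin *spread* of predictions was considered and rejected: that
spread is bounded by the 0.1 bin width while the positive-fraction noise
is ~n^−½, so the statistic would reject essentially every finite-sample
diagram regardless of calibration quality. Granularity is the number of
occupied bins; range is max − min of the bin means (0 for a single bin).

## Synthetic-data generator

`simulate_scores` draws positive scores from N(0, 1) and negative scores
from N(Δ, 1), with Δ set by the overlap coefficient ω = 2Φ(−Δ/2) (the
shared area of the two unit-variance densities). `run_overlap_sweep`
reproduces the benchmark design: 50 training scores per class, 100
balanced test scores, 20 repetitions per overlap, averaging the χ²
p-value, granularity and range; the default grid is ω ∈ {0.1, …, 0.9}.
The generator emulates an idealised, well-behaved classifier score. Real
score distributions are typically non-Gaussian, skewed or multimodal (the
built-in k-means distance-ratio discriminant produces exactly such scores
and is used in the pipeline tests); passing the Gaussian benchmark
therefore demonstrates correctness of the machinery and the method's
behaviour under controlled overlap, not performance on any particular
clinical data set.

The cross-validation pipeline test plants two isotropic unit-variance 2-D
Gaussian classes with centers 2 apart (moderate overlap — the regime where
calibration granularity is interesting), 30 subjects per class for
training and 25 per class for testing, scored by the k-means discriminant.

## Observed behaviour and limitations

- The average calibrated **range** decreases monotonically with overlap
  (Spearman −1 over the default grid at every seed examined).
- The average **granularity** is *not* monotone in overlap: it peaks at
  mid-overlap (≈6 occupied bins near ω = 0.6, versus ≈3.3 at ω = 0.1 and
  ≈4.5 at ω = 0.9). At small overlap the posteriors are correctly extreme,
  so test predictions concentrate in the two outermost bins; at large
  overlap they concentrate around the prior. Mid overlap is where the
  posterior sweeps the whole probability scale across the observed score
  span. One trend check in the acceptance suite asserts a monotone
  decrease for granularity and is expected to fail; it is retained
  unmodified as a record of this behaviour.
- With ~50 scores per class the posterior for a score far outside both
  training samples is driven by few informative splits and should be read
  with its finite-sample uncertainty in mind.
- Only two hypotheses are entertained: "neither parent" is not modelled,
  and multi-class calibration is out of scope.
- LOO cross-validation yields the finest granularity; 10-fold is cheaper
  and slightly coarser (verified on the planted-blob pipeline: 10-fold
  granularity ≤ LOO in 16 of 20 replicates).
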