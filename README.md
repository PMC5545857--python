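# polyacal

Nonparametric Bayesian calibration of binary-classifier scores to
probabilities, built for clinical decision support: instead of "the model
says positive", report "this patient has a 79% probability of belonging to
the case class".

## The method

Most classifiers emit a real-valued score that is thresholded into a class.
`polyacal` converts a new score *X*ₚ into the posterior probability that it
was generated by the positive class, by comparing it against the held-out
score distributions of the two training classes, X₁ (cases) and X₂
(controls):

    Pr(H₁ | Xₚ, X₁, X₂) ∝ Pr(Xₚ, X₁, X₂ | H₁) Pr(H₁)

where H₁ is the hypothesis that *X*ₚ and X₁ share a parent distribution and
H₂ that *X*ₚ came from the parent of X₂. The likelihoods are evaluated with
a Pólya-tree prior: the score axis is recursively halved into nested dyadic
partitions, each split carries a Beta(α_L, α_L) prior on its left/right
branch probability with α_L = L² at level L, and the Beta–binomial
integrals over the split counts (l, m, n for *X*ₚ, X₁, X₂) collapse into a
closed-form product of gamma-function ratios — under H₁ the test point's
counts are pooled with X₁, under H₂ with X₂. Because the approach is
nonparametric it needs no binning scheme and it naturally propagates the
statistical uncertainty of a finite training sample, which yields finer
granularity and a wider dynamic range of calibrated probabilities than
quantile-binning calibrators, especially when the classes overlap heavily.

Everything is computed in log-space (log-gamma, log-sum-exp); partitions
are centered on the pooled training median and capped at 18 levels, with
descent stopping once a cell holds at most one point or only numerically
identical values.

Calibration quality is measured with 10-bin reliability diagrams: the
weighted χ² goodness of fit to the diagonal (residuals weighted by the
binomial noise each bin's calibrated probability implies), the number of
calibrated points (occupied bins = granularity), and the range of bin-mean
probabilities.

## Worked example

Calibrate simulated classifier scores from two unit-variance Gaussians with
overlap coefficient 0.5 (mean separation ≈ 1.35):

```python
import numpy as np
from polyacal import PolyaTreeCalibrator, simulate_scores

x1, x2 = simulate_scores(0.5, 50, 50, seed=7)   # cases ~ N(0,1), controls ~ N(1.35,1)
res = PolyaTreeCalibrator(x1, x2).fit()
print(res.summary())
print(res.predict([-1.0, 0.3, 0.7, 2.5]).to_string(index=False))
```

```
Polya-tree score calibration
============================================
positive-class scores (X1)                50
negative-class scores (X2)                50
prior Pr(H1)                          0.5000
partition depth cap                       18
X1 score range          [  -2.5170,    2.0000]
X2 score range          [  -0.6863,    2.8731]
============================================
 score  posterior_h1  log_lik_h1  log_lik_h2
  -1.0      0.831588 -555.513745 -557.110668
   0.3      0.827574 -558.110787 -559.679316
   0.7      0.228351 -554.917269 -553.699625
   2.5      0.116770 -558.529930 -556.506552
```

A score of −1.0 (deep in case territory) calibrates to an 83% case
probability; 2.5 calibrates to 12%. The log marginal likelihoods under each
hypothesis are reported alongside. Evaluating 100 fresh labelled test
scores builds the reliability diagram:

```python
t1, t2 = simulate_scores(0.5, 50, 50, seed=8)
d = res.evaluate(np.r_[t1.values, t2.values], np.r_[np.ones(50), np.zeros(50)])
print(f"chi2={d.chi2:.3f} dof={d.dof} p={d.p_value:.3f} "
      f"points={d.n_calibrated_points} range={d.range:.3f}")
```

```
chi2=6.876 dof=4 p=0.143 points=4 range=0.732
```

Four probability bins are occupied spanning a 0.73-wide probability range,
and the diagonal fit is acceptable (p = 0.14).

The same workflow is available from the shell:

```sh
polyacal simulate --overlaps 0.1,0.5,0.9 --reps 20 --seed 1 --out sweep.csv
polyacal fit --scores train.csv --out model.json
polyacal predict --model model.json --scores test.csv --out preds.csv
polyacal evaluate --model model.json --scores test.csv --out-prefix eval
```

Raw feature tables can be scored with the built-in k-means discriminant
(the distance-ratio score of a point to the two class-labelled cluster
centroids) via leave-one-out or stratified k-fold cross-validation:

```python
model = PolyaTreeCalibrator.from_cv(features, labels,
                                    KMeansDiscriminantScorer(seed=0), cv="loo")
```

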