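# sparsefa

Penalized maximum-likelihood factor analysis for one or several groups, with
automatic tuning-parameter estimation.

Confirmatory and exploratory factor models rarely yield loading matrices
with exact zeros: rotations and modification indices leave the analyst to
threshold small loadings by hand, and multi-group invariance testing
requires long sequences of nested comparisons. `sparsefa` addresses both
problems with penalized estimation. A sparsity penalty (lasso, adaptive
lasso, scad or mcp) shrinks small loadings to zero; with several groups,
fusion penalties additionally shrink the pairwise cross-group differences of
loadings and intercepts, so non-invariant parameters are detected
automatically instead of tested one by one.

## Method

For group g the model is x_g = τ_g + Λ_g f_g + ε_g with f_g ~ N(κ_g, Φ_g)
and diagonal Ψ_g, giving μ_g = τ_g + Λ_g κ_g and Σ_g = Λ_g Φ_g Λ_gᵀ + Ψ_g.
The penalized log-likelihood

    ℓ_p(θ) = ℓ(θ) − N · Σ_j P_{η_j}(θ)

is maximized by a trust-region algorithm with analytic score and expected
Fisher information. The non-differentiable |t| in each penalty is replaced
by √(t² + c̄) (c̄ = 1e-8), which makes the objective smooth and allows a
principled definition of model complexity: with penalty matrix E and
F = I(θ̂), the influence matrix A_η = F½(F + N E)⁻¹F½ yields the effective
degrees of freedom edf = tr(A_η) ∈ [m − r*, m]. Models are compared by
GBIC = −2ℓ̂ + log(N)·edf. For lasso/alasso penalties the tuning vector η
(one sparsity parameter, plus two fusion parameters with several groups) is
estimated automatically by Newton minimization of the un-biased risk
criterion V(η) = ‖K − A_η K‖²/N + 2γ·tr(A_η)/N − 1, alternated with
θ-updates; γ ≥ 1 is an influence factor favoring sparser fits. Inference
uses the Bayesian posterior covariance (F + N E)⁻¹. See `docs/methods.md`
for the full account.

## Worked example

```python
import numpy as np
from sparsefa import PenalizedFactorAnalysis, generate_dataset, make_preset

preset = make_preset("sim1")            # 9 indicators, 3 correlated factors
X, _ = generate_dataset(preset, 500, np.random.default_rng(7))

est = PenalizedFactorAnalysis(model=preset.spec, penalty="alasso",
                              eta="auto", a=2.0, gamma=4.5).fit(X)
print(np.round(est.eta_, 5), round(est.edf_, 2), round(est.gbic_, 2))
print(np.round(est.loadings_, 2))
```

prints

```
[0.00264] 23.73 10806.56
[[ 0.86  0.    0.  ]
 [ 0.72  0.    0.  ]
 [ 0.65  0.3  -0.  ]
 [ 0.    0.83  0.  ]
 [ 0.    0.73 -0.  ]
 [ 0.    0.58  0.26]
 [ 0.    0.    0.8 ]
 [-0.   -0.    0.77]
 [ 0.26  0.    0.71]]
```

The automatic procedure selected η̂ ≈ 0.0026; the fitted model spends 23.7
effective degrees of freedom out of m = 33, having shrunk all nine
truly-zero cross-loadings to exact (machine-level) zeros while retaining the
three genuine 0.30 cross-loadings. `est.summary()` lists per-parameter
estimates, per-parameter edf (≈ 0 for the suppressed loadings, ≈ 1 for
unpenalized parameters) and 95% posterior intervals.

The same API handles several groups — pass `groups=` to `fit`, and the
estimator penalizes cross-group loading and intercept differences with two
extra automatically tuned parameters — and a command line mirrors it
(`sparsefa fit|grid|simulate|report`, see `--help`).

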