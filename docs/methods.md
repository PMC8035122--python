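# Methods

## Model

`sparsefa` estimates normal linear factor models. With one group the model
for the p observed variables is x = Λf + ε with f ~ N(0, Φ), ε ~ N(0, Ψ)
diagonal, so Σ(θ) = ΛΦΛᵀ + Ψ; variables are treated as deviations from
their means. With G groups the model gains intercepts and factor means,
x_g = τ_g + Λ_g f_g + ε_g, f_g ~ N(κ_g, Φ_g), with implied moments
μ_g = τ_g + Λ_g κ_g and Σ_g = Λ_g Φ_g Λ_gᵀ + Ψ_g. The log-likelihood uses
sufficient statistics only; the multi-group version works with
W_g = S_g + (x̄_g − μ_g)(x̄_g − μ_g)ᵀ. Identification is by unit factor
variances plus r−1 fixed zeros per column (one group) or marker variables —
one fixed nonzero loading per factor with a fixed zero intercept (several
groups).

Every free entry of θ is tagged fixed, free, or penalized. The flat ordering
is group-major; within a group penalized loadings come first, then remaining
free loadings (column-stacking order), intercepts (penalized first), unique
variances, vech(Φ), and factor means. This ordering is what makes the
penalty index sets well defined.

## Penalties and their smooth approximation

Sparsity penalties act on the penalized loadings; with several groups two
fusion penalties additionally shrink the pairwise cross-group differences of
loadings and of intercepts toward zero (measurement invariance). Families:
lasso, adaptive lasso (weights 1/|θ̂_MLE|^a, exponent a > 0), scad (a > 2)
and mcp (a > 1) in their standard forms. Each absolute value is replaced by
√(t² + c̄), c̄ = 1e-8 by default; the deviation from |t| is √c̄ at zero and
< c̄ elsewhere, so the objective is twice continuously differentiable while
remaining numerically indistinguishable from the exact penalty. Around an
expansion point θ̃ the approximated penalty is represented by the quadratic
form ½θᵀEθ with a penalty matrix E: diagonal shrinkage weights
m_q = P′(√(θ̃_q²+c̄))/√(θ̃_q²+c̄) for sparsity terms and a graph-Laplacian
pattern (+w, −w) per cross-group pair for fusion terms. E·θ̃ is the exact
gradient of the approximated penalty at θ̃, which the tests verify by finite
differences. Estimates are never hard-thresholded inside the optimizer
(at θ̃ = 0 the weight is η/√c̄, large but finite); zero classification
happens only at reporting time.

With G > 2 groups a fused parameter has C(G,2) pairwise differences; the
penalty is applied to the summed approximated magnitudes, which reduces to
the single absolute difference for G = 2. Each pairwise difference is
counted once. Adaptive weights for fusion terms use the L1 norm of the MLE
differences; weights are capped at 1e8 so a ~0 reference cannot overflow
the curvature matrix.

## Optimization

For fixed tuning values the penalized log-likelihood
ℓ_p(θ) = ℓ(θ) − N·P(θ) is maximized by a trust-region algorithm. The local
model uses the penalized score g_p = g − N·E·θ and curvature
H_p = I(θ) + N·E, where I is the expected Fisher information (an observed,
finite-difference Hessian is available for single-group models; the two give
the same optimum to ~1e-4 on simulated replicates and Fisher is the default
for its stability). E is rebuilt at every accepted step. The dense
subproblem min_s {−g_pᵀs + ½sᵀH_p s : ‖s‖ ≤ Δ} is solved exactly by an
eigenvalue-safeguarded (Moré–Sorensen style) method — appropriate because
m ≲ 100 — with the hard case handled explicitly. Radius rules are the
textbook defaults: accept when the actual/predicted ratio r > 0, expand
(Δ ← min(2Δ, 100)) when r > 0.75 on a boundary step, shrink (Δ ← Δ/4) when
r < 0.25; Δ₀ = 1. Convergence: max|g_p| < 1e-6·N or relative objective
change < 1e-9; iteration cap 500. A trial point with an indefinite implied
covariance is simply rejected (objective −∞), which keeps iterates in the
feasible region without constraints.

## Degrees of freedom, selection, uncertainty

With F = I(θ̂) and F_p = F + N·E, the influence matrix is
A = F^{1/2} F_p^{-1} F^{1/2} (square roots by eigendecomposition, with
relative eigenvalue flooring at 1e-12 flagged in metadata). edf = tr(A)
equals m at η = 0 and falls to m − r* as η → ∞, where r* counts penalized
elements; per-parameter edf = diag(F_p^{-1}F) ∈ [0,1]. Model selection uses
GBIC = −2ℓ̂ + log(N)·edf (AIC variant replaces log N by 2).

Automatic tuning (lasso/alasso only, since it requires E to be linear in η)
minimizes the un-biased risk estimator
V(η) = ‖K − A_η K‖²/N + 2γ·tr(A_η)/N − 1 with K = F^{1/2}θ + F^{-1/2}g
built at the current estimate, alternating trust-region θ-updates with
Newton steps for log η (analytic gradient, finite-difference Hessian
ridge-regularized to positive definite, step halving, η clipped to
[1e-8, 1e8]) until |Δℓ|/(0.1 + |ℓ|) < 1e-7. The starting value is
η = 0.01 per term; the joint fixed point was checked to be insensitive to
this choice (θ̂ agrees to ~1e-5 from starts two orders of magnitude apart).
The influence factor γ ≥ 1 inflates the complexity term and trades fit for
sparsity; the simulation defaults use the adaptive lasso with a = 2 and
γ = 4.5, the configuration with the best selection performance. scad/mcp
tuning goes through the GBIC grid search with warm starts along the path.

Uncertainty uses the Bayesian posterior covariance V_θ = F_p^{-1}
(θ | data, η ~ N(θ̂, V_θ)), which reduces to the usual F^{-1} at η = 0;
a frequentist sandwich F_p^{-1} F F_p^{-1} is available via `vcov="sandwich"`.
95% intervals are θ̂ ± 1.96·√diag(V_θ).

## Synthetic data and the Monte-Carlo harness

The generator draws i.i.d. multivariate-normal rows from preset population
models; it emulates exactly the data-generating process the estimators
assume (normal factors and uniquenesses, independent rows, correctly
specified pattern). It does not emulate features of real measurement data —
ordinal or skewed indicators, missingness, model misspecification — so
passing tests demonstrate the estimation and selection machinery, not
robustness to those features.

Two designs are built in. `sim1`: one group, p = 9, r = 3 correlated
factors (Φ off-diagonals 0.3, unit variances), primary loadings
0.85/0.75/0.65, three cross-loadings of 0.30, six fixed zeros for rotational
uniqueness, and Ψ = I − diag(ΛΦΛᵀ) so indicators have unit variance; all 21
free loadings are penalized (12 truly nonzero, 9 truly zero; m = 33).
`sim2-{null,small,medium,large}`: two groups, p = 12, r = 2, markers x1/x7
fixed at 0.85 in both groups during estimation (their tabulated population
values), group-2 deviations of 0.1/0.2/0.3 on the primary loading and the
intercept of x6 and x12, invariant structural parameters
(vech(Φ) = (1, .3, 1), κ = 0); per group 20 penalized loadings and 10
penalized intercepts (m = 94).

Replicate seeds derive from a master seed by a counter scheme
(`default_rng([seed, replicate, attempt])`), so replicates whose unpenalized
fit is inadmissible (a unique variance ≤ 0, Φ̂ not positive definite, or
non-convergence) are regenerated reproducibly rather than dropped.
Estimates are sign-aligned per factor against the population primaries
before scoring; an estimate counts as zero iff it rounds to 0.0 at one
decimal. Metrics: MSE (replicate-average squared distance over the full
θ), squared bias of the replicate mean, TPR/FPR over truly nonzero/zero
penalized loadings, and PCTM — the share of replicates recovering the exact
loading sparsity pattern. For multi-group studies the primary PCTM counts
the loading pattern only; a stricter variant that additionally requires the
cross-group loading/intercept differences to be classified correctly is
reported as `pctm_full`. The loadings-only variant is primary because the
reference results for the two-group design are essentially constant across
difference scenarios, which is only consistent with that reading — a
difference of 0.3 whose estimate carries a sampling SD of ~0.1 at N = 300
cannot be detected ~95% of the time by any method.

## Numerical choices and degenerate inputs

- Sample covariances use the maximum-likelihood divisor N.
- Non-PSD information matrices are repaired by relative eigenvalue flooring
  (flagged, never silent).
- A non-PSD input covariance raises immediately; a singular implied Σ raises
  a numeric error naming the offending group.
- Default starting values: 0.3 for free loadings, half the sample variances
  for uniquenesses, sample means for intercepts, zero factor covariances.
- Default identification when no model is given: echelon zeros (λ_ij = 0
  fixed for i < j) with unit factor variances; users wanting a specific
  confirmatory pattern pass model syntax or a `ModelSpec`.

## Known limitations

- With a penalty strong enough to null *every* loading, the factor
  covariance block loses identification and edf/GBIC are not meaningful;
  grid searches should stay within the regime where the model remains
  identified.
- At N = 300 the automatic procedure, run to its exact joint fixed point,
  is slightly sparser than published reference implementations of the same
  criterion (false-positive rate ~0.004 vs ~0.008); at N = 1000 the results
  coincide to the printed precision. Relatedly, the tuning criterion with
  γ = 4.5 prefers fusing a cross-group difference whenever its z-ratio is
  ≲ 3, so under strong true non-invariance the fully optimized criterion
  fuses true differences in a substantial fraction of replicates, inflating
  MSE relative to reference values obtained with less exhaustive η searches.
- Ordinal/categorical indicators, missing-data likelihoods, penalties on
  unique variances, and N < p regimes are out of scope.
- The automatic procedure requires lasso or alasso penalties in every term;
  mixing in scad/mcp forces grid search.

## Monte-Carlo problem sizes used in the checks

The test suite runs the single-group conditions at L = 1000 replicates and
the two-group conditions at L = 120; `scripts/acceptance.py` defaults to
L = 300 (single-group) and L = 60 (two-group). These sizes are the package's
own balance between Monte-Carlo error and runtime; the comparison bands in
the tests scale with the replicate counts actually used.
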