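# Methods

## The model

A Gaussian graphical model (GGM) represents a set of `p` standardized
variables as a network whose edges are partial correlations.  It is encoded
by a hollow symmetric matrix `Ω` (zero diagonal, partial correlations
off-diagonal) with implied correlation matrix

    P = Δ (I − Ω)⁻¹ Δ,      Δ = vec2diag(diag((I − Ω)⁻¹))^(−1/2),

where the diagonal scaling `Δ` guarantees a unit diagonal.  A zero in `Ω`
means the two variables are conditionally independent given all others, i.e.
no edge.  `corr_to_ggm` inverts the map via `ω_ij = −κ_ij / √(κ_ii κ_jj)`
with `κ = P⁻¹`; the sign convention makes edges equal partial correlations
and is pinned down by the round-trip test `Ω → P → Ω`.

## The estimator

Every model is fit by minimizing a discrepancy `F` proportional to `−2/n`
times the log-likelihood, through the chain `F(φ(θ(ψ)))`: distribution
parameters `φ` (all correlations, or study-level means and covariances),
model parameters `θ` (all potential edges), free parameters `ψ`.  The
gradient is the product of three Jacobians — distribution, model, and a
sparse 0/1 *manual* Jacobian `M = ∂θ/∂ψ` that encodes fixed-to-zero and
equality constraints (a column with several ones ties parameters together).
At the optimum the unit Fisher information is

    𝓘(ψ̂) = ½ Mᵀ Jᵀ E[H_φ] J M,   𝓥 = 𝓘⁻¹ / n,

and standard errors are the square roots of `diag(𝓥)`.  The covariance is
computed per independent block of the information matrix; a block that is
not numerically positive definite (typically the heterogeneity Cholesky
block at small numbers of studies) yields NaN standard errors for its
parameters only, leaving inference on the identified block intact, while
exact rank deficiency (such as duplicated free parameters) raises an error
naming the non-identified parameters.  Wald z-tests on the
edges drive *pruning*: all edges with `p ≥ α` are removed simultaneously and
the model refit once (a recursive variant repeats until stable; single-pass
is the default because it reproduces the `1 − α` specificity calibration).

All distribution-level derivatives (standardized Gaussian on correlation
matrices, weighted least squares, and the study-level Gaussian used for
random effects) are analytic; the GGM model Jacobian `∂vechs(P)/∂vechs(Ω)`
was derived from the differential of `P = ΔΩ*Δ` (`Ω* = (I−Ω)⁻¹`), with the
`−3/2` power applied only to the diagonal entries of the diagonal matrix.
Every analytic derivative is checked against central finite differences in
the test suite (relative error below 1e−5); this is the package's primary
defense against the error-proneness of these formulas.

### Optimization

Minimization uses analytic gradients with L-BFGS-B, followed when needed by
a damped Newton phase that uses the *expected* (Fisher) Hessian — cheap to
assemble from the same blocks as the information matrix, positive
semi-definite by construction, and equal to the true curvature at the
optimum.  The polish phase matters for random-effects fits, where the
Cholesky heterogeneity factor contributes `q(q+1)/2` weakly identified
parameters (406 for `p = 8`) and quasi-Newton methods crawl.  Proposals
outside the admissible region — `I − Ω` singular, a non-positive diagonal of
`(I − Ω)⁻¹`, or a non-PD `Σ` — return a large finite value so line searches
can back off; the likelihood itself is never modified.  A fit that does not
reach the gradient tolerance (default `1e−5`, configurable) is flagged
`converged=False`, never silently accepted.

### Fit indices

With `F̂_sat` the saturated discrepancy, `χ² = n (F̂ − F̂_sat)` and
`df = (#modeled distribution parameters) − (#free parameters)`.  Absolute
log-likelihoods restore the Gaussian constant, `ℓ = −(n/2)(p ln 2π + F̂)`,
giving `AIC = −2ℓ + 2q` and `BIC = −2ℓ + q ln n`; these may differ from
other software by an additive constant, so model *orderings* are what the
tests rely on.  RMSEA uses the common multi-group convention
`√k · √(max(0, χ² − df) / (df · n))`.  No fit indices are reported for
random-effects fits: their discrepancy is not a likelihood of the raw data,
so derived fit measures are not meaningful there.

### Modification indices

The partial-pruning search needs a score statistic for the expected fit
improvement from freeing one constrained parameter.  The package uses the
Lagrange-multiplier form

    MI_j = (n/4) g_j² / s_jj,

with `g_j` the discrepancy gradient of the candidate parameter and `s_jj`
its information Schur complement after partialling out the current free
parameters.  The defining property — `MI_j` approximates the χ² drop from
freeing parameter `j` alone — is what the tests assert (within 20% under
moderate misfit), together with the null χ²(1) behavior.

## Aggregating datasets

**Fixed effects.**  `k` datasets sharing a variable set are modeled jointly
with `F = Σ (n_i/n) F_i`; Jacobians and Hessians are block-structured per
dataset and equality constraints live in the manual Jacobian.  Two routes:

* *two-stage*: stage 1 estimates pooled correlations `ρ̂` by ML (the
  weighted likelihood depends on the data only through the `n`-weighted mean
  correlation matrix, so the solution is closed-form) with Fisher
  information `𝓘`; stage 2 fits the network to `z = ρ̂` by WLS with
  `W = 𝓘` (diagonal-W and identity-W variants are available);
* *multi-dataset*: the network is estimated directly under cross-dataset
  equality constraints.

For a saturated network both routes provably give identical estimates and
standard errors; the tests assert agreement to 1e−6.

**Partial pruning** searches for partial invariance across datasets:
(1) prune each dataset separately; (2) pool the union of retained edges with
equality constraints; (3) repeatedly free the edge with the largest
modification-index *sum over datasets* (one index per equality-constrained
edge), accepting a step only if BIC strictly decreases; (4) final pruning at
`α = 0.05`.  Freeing an edge dissolves its equality constraint into `k`
group-specific parameters at once.

**Random effects.**  Study correlation vectors `r_i` are themselves modeled
as Gaussian with mean the network-implied correlations and covariance
`Σ_i = V_i + T Tᵀ`: known sampling variation plus a heterogeneity covariance
kept positive semi-definite through its Cholesky factor `T` (all `τ`
entries free in sign; reported random-effect SDs are `√diag(TTᵀ)`).  The
sampling covariances are estimated first — per study from saturated-model
information matrices (*individual*) or from the pooled fit scaled as
`V_i = (n̄/n_i) · k𝓥_pooled` (*pooled*) — and then treated as known.  The
likelihood is evaluated either on the mean vector and scatter matrix of the
`k` rows with a single `Σ` (*averaged*; every study weighted equally, as
the averaged form is defined), or study-by-study with `Σ_i` (*per-study*),
which also supports studies missing whole variables by subsetting `μ` and
`Σ_i`.  Missing variables are supported only per-study; the averaged form
requires complete rows.  Effective sample size for standard errors is the
number of studies `k`.  Pruning applies to edges only; `τ` is never pruned.
Starting values: `Ω` from the pooled correlation structure, `T = 0.05 I`
(a small positive start avoids the boundary saddle at `T = 0`).

## The synthetic-data generator

The generator emulates the estimators' intended regime: several
moderately sized cross-sectional studies measuring the same variables.

* *True networks*: Watts–Strogatz ring lattice, each node connected to its
  four nearest neighbors (`nei = 2`), each edge rewired with probability
  0.25 preserving the edge count — hence exactly 16/28 edges at `p = 8` and
  32/120 at `p = 16` for every seed.  Edge weighting goes through a
  diagonally dominant precision matrix: off-diagonal magnitudes uniform on
  (0.5, 1), diagonal 1.5 × absolute row sums, rows scaled by the diagonal,
  symmetrized, negated off-diagonal.  Signs are assigned on the
  partial-correlation scale so 90% of network edges are positive (a positive
  partial correlation is a negative precision entry).  Measured mean
  |edge weight| is ≈ 0.167 over 500 networks.
* *Heterogeneity*: per-study correlation vectors are the true implied
  correlations plus Gaussian noise with covariance `re_sd² ×` a random
  correlation matrix from the vine construction at unit concentration;
  draws are repeated until the implied matrix is positive definite, and a
  budget overrun advises a smaller `re_sd`.
* *Observed data*: sample correlations of `n_i` standard-Gaussian vectors,
  `n_i` uniform on [250, 1000].

What the generator does **not** emulate: ordinal (Likert-type) measurement,
case-level missingness, non-Gaussian tails, and unequal variable sets drawn
from real instruments.  Passing tests therefore certify calibration and
recovery under the multivariate-normal, complete-data regime, not
robustness to those violations.

## Problem sizes used in the checks

Simulation-based checks run at desk scale, chosen so the full suite
completes on one CPU while keeping Monte-Carlo error well inside the stated
tolerances: specificity calibration uses 50 replications (`p=8, k=8`), the
heterogeneity contrast 30 fixed-effects and 6 random-effects replications
(`k=32`), and the recovery check 5 replications each at `k = 8` and
`k = 32`.  The acceptance script regenerates its quantities at 100 networks
per edge-count check, 500 networks for the weight scale, and 50
replications for the specificity calibration.

## Known limitations

* Random-effects fits with `p ≳ 16` nodes are computationally heavy (the
  Cholesky block grows as `q²/2` with `q = p(p−1)/2` correlations).
* Only study-level missing *variables* are handled; case-level missingness
  within a study is out of scope (supply the study's correlation matrix and
  a representative `n` instead).
* Fixed-effects fit indices assume all groups share `p` variables.
* The Wald-based pruning tests are asymptotic; at very small `n` or `k`
  the stated α-calibration degrades, as the simulations with `k = 4`
  illustrate.
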