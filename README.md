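# ggmagna

Maximum-likelihood estimation of Gaussian graphical models (GGMs) — networks
whose edges are partial correlations — from one or many sample correlation
matrices, with fixed-effects and random-effects meta-analytic aggregation
across studies.

Psychological and epidemiological network studies typically estimate a GGM
from a single few-hundred-case dataset, which is too little data for a model
with `p(p−1)/2` edge parameters.  This package is for researchers who want
to aggregate correlation matrices from several studies into one network —
with honest standard errors, significance-based edge selection, tests of
cross-study invariance, and an explicit model of between-study
heterogeneity — and for methodologists who want a reproducible simulation
harness for these estimators.

## The model

A GGM on `p` standardized variables is a hollow symmetric matrix `Ω` of
partial correlations with implied correlation matrix

    P = Δ (I − Ω)⁻¹ Δ,        Δ = vec2diag(diag((I − Ω)⁻¹))^(−1/2).

Estimation minimizes `F ∝ −(2/n) log L` through the chain
`F(φ(θ(ψ)))` with analytic Jacobians at every stage and a sparse 0/1
"manual" Jacobian encoding fixed and equality constraints.  Standard errors
come from the Fisher information `𝓘 = ½ Mᵀ Jᵀ E[H] J M`, `𝓥 = 𝓘⁻¹/n`.
Modes:

* **single study** — ML fit of `Ω` to one correlation matrix, Wald tests,
  significance pruning, fit indices (χ², AIC, BIC, RMSEA), modification
  indices;
* **fixed-effects aggregation** — a pooled network across `k` studies,
  either two-stage (pooled ML correlations, then WLS with the Fisher
  information as weight matrix) or directly with cross-dataset equality
  constraints; *partial pruning* searches for edges that differ between
  studies (BIC-guided, modification-index driven);
* **random-effects aggregation** — study correlation vectors modeled as
  Gaussian with network-implied mean and covariance
  `Σ_i = V_i + TTᵀ`: known sampling variation plus a Cholesky-parameterized
  heterogeneity covariance, in four variants (individual/pooled sampling
  covariance × averaged/per-study likelihood), including studies that
  are missing whole variables;
* **simulation harness** — small-world true networks, heterogeneity
  injection, finite-sample correlation sampling, and
  sensitivity/specificity/recovery metrics.

See `docs/methods.md` for assumptions, parameter defaults, and numerical
choices.

## Worked example

Simulate four homogeneous studies from one 8-node network, aggregate them
with the two-stage fixed-effects estimator, and prune at α = 0.05:

```python
import numpy as np
import ggmagna as gg
from ggmagna import multigroup as mg

rng = np.random.default_rng(2024)
net = gg.generate_true_network(8, seed=rng)
datasets = gg.simulate_studies(net, np.zeros((28, 28)), k=4,
                               n_range=(250, 1000), seed=rng)

fit = mg.two_stage_fixed(datasets, alpha=0.05)
Omega = mg.omega_from_fit(fit)
metrics = gg.evaluate(net, Omega)

print(f"true edges: {net.n_edges} / 28")
print(f"estimated edges: {int((Omega[np.triu_indices(8, 1)] != 0).sum())}")
print(f"sensitivity: {metrics['sensitivity']:.3f}")
print(f"specificity: {metrics['specificity']:.3f}")
print(f"|weight| correlation: {metrics['correlation']:.3f}")
print(f"chi2 = {fit.chi2:.1f} on df = {fit.df}, RMSEA = {fit.rmsea:.4f}")
```

prints

```
true edges: 16 / 28
estimated edges: 17
sensitivity: 1.000
specificity: 0.917
|weight| correlation: 0.983
chi2 = 2.8 on df = 11, RMSEA = 0.0000
```

All 16 true edges were recovered; one of the 12 truly absent edges was
falsely included (specificity 11/12 ≈ 0.917 — a single replication of a
procedure calibrated so that *on average* 95% of absent edges are excluded
at α = 0.05).  The estimated weights correlate 0.98 with the truth, and the
pruned model fits the pooled correlations well (χ² below its degrees of
freedom, RMSEA 0).

A command-line interface covers the same modes on CSV/YAML inputs:

```sh
ggmagna fixed --manifest manifest.yaml --method two_stage
ggmagna random --manifest manifest.yaml --sampling pooled --estimation averaged
ggmagna simulate --nodes 8 --k 8 --re-sd 0.1 --reps 10 --seed 1 --out sim.csv
```

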