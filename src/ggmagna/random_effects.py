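"""Random-effects meta-analytic aggregation of Gaussian graphical models.

Study-level sample correlation vectors r_i are modeled as multivariate
Gaussian with mean equal to the network-implied correlations,

    mu = vechs( Delta (I - Omega)^{-1} Delta ),

and covariance decomposed into known sampling variation plus heterogeneity,

    Sigma_i = V_i + Sigma_ran,    Sigma_ran = T T',

with T lower triangular so that the heterogeneity covariance is positive
semi-definite by construction.  The sampling covariances V_i are estimated
first (from saturated correlation fits per study, or from a pooled fit) and
then treated as known.

Four variants arise from crossing how V is built (``individual`` vs
``pooled``) with how the likelihood is evaluated (``averaged``: a single
Gaussian on the mean correlation vector and scatter matrix; ``per_study``:
one Gaussian per study, which also supports study-level missing variables).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .fit_engine import FitResult, ModelSpec, ParameterTable, fit_ml, prune
from .gaussian_family import (
    CorrelationData,
    MetaRow,
    meta_gauss_fit,
    meta_gauss_hessian,
    meta_gauss_jacobian,
    std_gauss_hessian,
)
from .ggm_model import cholesky_model_jacobian, corr_to_ggm, ggm_model_jacobian, ggm_to_corr
from .matcalc import vech, vech_indices, vechs, vechs_indices
from .multigroup import _nearest_pd_corr, _omega_matrix, pool_correlations

__all__ = [
    "SamplingCov",
    "RandomEffectsFit",
    "build_rows",
    "estimate_sampling_cov",
    "fit_random_effects",
    "prune_random_effects",
]


# ---------------------------------------------------------------------------
# study rows
# ---------------------------------------------------------------------------

def build_rows(
    datasets: list[CorrelationData],
    master_labels: list[str] | None = None,
) -> tuple[list[MetaRow], list[str]]:
    """Align per-study correlations to a master variable list.

    Entries for variable pairs a study did not measure are NaN.  The master
    list defaults to the union of study labels in order of first appearance.
    """
    if master_labels is None:
        master_labels = []
        for d in datasets:
            for lab in d.labels:
                if lab not in master_labels:
                    master_labels.append(lab)
    p = len(master_labels)
    q = p * (p - 1) // 2
    rows_idx, cols_idx = vechs_indices(p)
    pair_pos = {(int(i), int(j)): e for e, (i, j) in enumerate(zip(rows_idx, cols_idx))}

    rows = []
    for d in datasets:
        if sum(lab in master_labels for lab in d.labels) < 2:
            raise ValueError(
                f"study {d.study_id or '?'} shares fewer than two variables "
                "with the master list"
            )
        pos = {lab: master_labels.index(lab) for lab in d.labels}
        r = np.full(q, np.nan)
        for a in range(d.p):
            for b in range(a + 1, d.p):
                i, j = pos[d.labels[a]], pos[d.labels[b]]
                e = pair_pos[(max(i, j), min(i, j))]
                r[e] = d.R[a, b]
        rows.append(MetaRow(r=r, n=d.n, study_id=d.study_id))
    return rows, master_labels


# ---------------------------------------------------------------------------
# sampling covariance of sample correlations
# ---------------------------------------------------------------------------

@dataclass
class SamplingCov:
    """Known sampling covariances of study correlation vectors."""

    method: str                    # "individual" or "pooled"
    V_star: np.ndarray             # averaged q x q estimate
    V_i: list[np.ndarray]          # per-study estimates (aligned to master order)
    nbar: float


def estimate_sampling_cov(
    datasets: list[CorrelationData], method: str = "pooled"
) -> SamplingCov:
    """Estimate per-study and averaged sampling covariances.

    ``individual``: invert each study's saturated-model Fisher information
    (V_i = I_i^{-1} / n_i) and average.  ``pooled``: fit the pooled
    correlation model once; V_star = k * V_pooled and V_i = (nbar / n_i)
    V_star.  Both require every study to measure all master variables;
    studies with missing variables are supported downstream by subsetting
    V_i inside the per-study likelihood.
    """
    if not datasets:
        raise ValueError("at least one dataset required")
    k = len(datasets)
    n_total = sum(d.n for d in datasets)
    nbar = n_total / k
    p = datasets[0].p
    for d in datasets:
        if d.p != p:
            raise ValueError(
                "sampling-covariance estimation requires full variable overlap"
            )
    if method == "individual":
        V_list = []
        for d in datasets:
            info = 0.5 * std_gauss_hessian(d.R)
            V_list.append(scipy.linalg.inv(info) / d.n)
        V_star = sum(V_list) / k
    elif method == "pooled":
        pooled = pool_correlations(datasets)
        V_star = k * pooled.covariance
        V_list = [(nbar / d.n) * V_star for d in datasets]
    else:
        raise ValueError(f"unknown method {method!r}")
    return SamplingCov(method=method, V_star=V_star, V_i=V_list, nbar=nbar)


# ---------------------------------------------------------------------------
# random-effects fit
# ---------------------------------------------------------------------------

@dataclass
class RandomEffectsFit:
    """Pooled network with Cholesky-parameterized heterogeneity."""

    Omega_hat: np.ndarray
    T_hat: np.ndarray
    fit: FitResult = field(repr=False)
    variant: dict = field(default_factory=dict)

    @property
    def SigmaRan_hat(self) -> np.ndarray:
        return self.T_hat @ self.T_hat.T

    @property
    def re_sd(self) -> np.ndarray:
        """Per-correlation random-effect standard deviations."""
        return np.sqrt(np.diag(self.SigmaRan_hat))

    @property
    def omega_p_values(self) -> np.ndarray:
        spec = self.fit.spec
        q = spec.meta["q"]
        pv = np.full(q, np.nan)
        for row in range(q):
            j = spec.table.psi_index[row]
            if j >= 0:
                pv[row] = self.fit.p_values[j]
        return pv


def _re_table(
    q: int, pattern: np.ndarray | None, start_omega: np.ndarray, start_tau: np.ndarray
) -> ParameterTable:
    # omega rows labeled by the master pair index, tau rows by T indices
    labels: list[tuple[str, int, int, int]] = []
    psi_index = []
    start = []
    next_col = 0
    for e in range(q):
        labels.append(("omega", e, e, 0))
        if pattern is None or pattern[e]:
            psi_index.append(next_col)
            next_col += 1
        else:
            psi_index.append(-1)
        start.append(start_omega[e])
    n_omega_free = next_col
    t_rows, t_cols = vech_indices(q)
    for t, (i, j) in enumerate(zip(t_rows, t_cols)):
        labels.append(("tau", int(i), int(j), 0))
        psi_index.append(next_col)
        next_col += 1
        start.append(start_tau[t])
    prunable = np.zeros(next_col, dtype=bool)
    prunable[:n_omega_free] = True  # tau is never pruned
    return ParameterTable(
        labels, np.array(psi_index), start=np.array(start), prunable=prunable
    )


def _subset_indices(present: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map a study's present entries into (mu positions, vech(Sigma) positions)."""
    q = present.size
    mu_pos = np.nonzero(present)[0]
    full_pos = {}
    t_rows, t_cols = vech_indices(q)
    for t, (i, j) in enumerate(zip(t_rows, t_cols)):
        full_pos[(int(i), int(j))] = t
    sig_pos = []
    for b_idx, b in enumerate(mu_pos):
        for a in mu_pos[b_idx:]:
            sig_pos.append(full_pos[(int(max(a, b)), int(min(a, b)))])
    return mu_pos, np.array(sig_pos, dtype=int)


def fit_random_effects(
    rows: list[MetaRow],
    sampling_cov: SamplingCov,
    pattern: np.ndarray | None = None,
    estimation: str = "averaged",
    start_omega: np.ndarray | None = None,
    tau_start_scale: float = 0.05,
    gtol: float = 1e-5,
    maxiter: int = 500,
) -> RandomEffectsFit:
    """Fit the random-effects model to study correlation vectors.

    ``estimation="averaged"`` uses the mean correlation vector and scatter
    matrix with a single Sigma (all rows must be complete);
    ``estimation="per_study"`` evaluates one Gaussian per study with
    study-specific Sigma_i and supports missing entries.  Free parameters
    are the (optionally pattern-restricted) network edges plus the full
    Cholesky factor of the heterogeneity covariance.
    """
    k = len(rows)
    if k < 2:
        raise ValueError("random-effects aggregation requires at least two studies")
    q = rows[0].r.size
    p = int(round((1 + np.sqrt(1 + 8 * q)) / 2))
    if p * (p - 1) // 2 != q:
        raise ValueError("row length is not a valid vechs dimension")
    qt = q * (q + 1) // 2
    R_rows = np.array([row.r for row in rows])

    if estimation == "averaged":
        if np.isnan(R_rows).any():
            raise ValueError(
                "averaged estimation requires complete rows; use per_study "
                "estimation for studies with missing variables"
            )
        rbar = R_rows.mean(axis=0)
        S = np.zeros((q, q))
        for r in R_rows:
            d = r - rbar
            S += np.outer(d, d)
        S /= k
    elif estimation == "per_study":
        rbar = np.nanmean(R_rows, axis=0)
    else:
        raise ValueError(f"unknown estimation {estimation!r}")

    if start_omega is None:
        Pbar = np.eye(p)
        ri, ci = vechs_indices(p)
        Pbar[ri, ci] = rbar
        Pbar[ci, ri] = rbar
        start_omega = vechs(corr_to_ggm(_nearest_pd_corr(Pbar)))
    start_tau = vech(tau_start_scale * np.eye(q))
    table = _re_table(q, pattern, start_omega, start_tau)

    t_rows, t_cols = vech_indices(q)

    def unpack(theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        Om = _omega_matrix(theta[:q], p)
        T = np.zeros((q, q))
        T[t_rows, t_cols] = theta[q:]
        return Om, T

    def mu_of(Om: np.ndarray) -> np.ndarray:
        return vechs(ggm_to_corr(Om))

    if estimation == "averaged":
        V_star = sampling_cov.V_star

        def fit_fun(theta):
            Om, T = unpack(theta)
            return meta_gauss_fit(rbar, S, mu_of(Om), V_star + T @ T.T)

        def dist_jacobian(theta):
            Om, T = unpack(theta)
            return meta_gauss_jacobian(rbar, S, mu_of(Om), V_star + T @ T.T)

        def dist_hessian(theta):
            _, T = unpack(theta)
            return meta_gauss_hessian(V_star + T @ T.T)

    else:
        present_list = [row.present for row in rows]
        subsets = [_subset_indices(pres) for pres in present_list]
        V_list = sampling_cov.V_i
        n_phi = q + qt

        def fit_fun(theta):
            Om, T = unpack(theta)
            mu = mu_of(Om)
            Sran = T @ T.T
            total = 0.0
            for row, V_i, (mu_pos, _) in zip(rows, V_list, subsets):
                Sig = (V_i + Sran)[np.ix_(mu_pos, mu_pos)]
                r_i = row.r[mu_pos]
                total += meta_gauss_fit(
                    r_i, np.zeros((mu_pos.size,) * 2), mu[mu_pos], Sig
                )
            return total / k

        def dist_jacobian(theta):
            Om, T = unpack(theta)
            mu = mu_of(Om)
            Sran = T @ T.T
            out = np.zeros(n_phi)
            for row, V_i, (mu_pos, sig_pos) in zip(rows, V_list, subsets):
                Sig = (V_i + Sran)[np.ix_(mu_pos, mu_pos)]
                r_i = row.r[mu_pos]
                jac = meta_gauss_jacobian(
                    r_i, np.zeros((mu_pos.size,) * 2), mu[mu_pos], Sig
                )
                m = mu_pos.size
                out[mu_pos] += jac[:m]
                out[q + sig_pos] += jac[m:]
            return out / k

        def dist_hessian(theta):
            _, T = unpack(theta)
            Sran = T @ T.T
            H = np.zeros((n_phi, n_phi))
            for V_i, (mu_pos, sig_pos) in zip(V_list, subsets):
                Sig = (V_i + Sran)[np.ix_(mu_pos, mu_pos)]
                Hi = meta_gauss_hessian(Sig)
                m = mu_pos.size
                idx = np.concatenate([mu_pos, q + sig_pos])
                H[np.ix_(idx, idx)] += Hi
            return H / k

    def model_jacobian(theta):
        Om, T = unpack(theta)
        return scipy.linalg.block_diag(
            ggm_model_jacobian(Om), cholesky_model_jacobian(T)
        )

    spec = ModelSpec(
        table=table,
        n=k,
        fit_fun=fit_fun,
        dist_jacobian=dist_jacobian,
        dist_hessian=dist_hessian,
        model_jacobian=model_jacobian,
        df_phi=q + qt,
        # no saturated fit: fit indices are not meaningful for this model
        meta={"model": "random_effects", "p": p, "q": q, "k": k,
              "estimation": estimation, "sampling": sampling_cov.method},
    )
    fit = fit_ml(spec, gtol=gtol, maxiter=maxiter)
    if not fit.converged:
        warnings.warn(
            f"random-effects fit did not reach gradient tolerance "
            f"(|g|={fit.gradient_norm:.2e})",
            stacklevel=2,
        )
    return _wrap_re_fit(fit)


def _wrap_re_fit(fit: FitResult) -> RandomEffectsFit:
    spec = fit.spec
    p, q = spec.meta["p"], spec.meta["q"]
    theta = spec.theta(fit.psi_hat)
    Om = _omega_matrix(theta[:q], p)
    t_rows, t_cols = vech_indices(q)
    T = np.zeros((q, q))
    T[t_rows, t_cols] = theta[q:]
    return RandomEffectsFit(
        Omega_hat=Om,
        T_hat=T,
        fit=fit,
        variant={"estimation": spec.meta["estimation"],
                 "sampling": spec.meta["sampling"]},
    )


def prune_random_effects(
    re_fit: RandomEffectsFit, alpha: float = 0.05
) -> RandomEffectsFit:
    """Remove non-significant network edges; heterogeneity parameters (tau)
    are never pruned."""
    pruned = prune(re_fit.fit.spec, alpha=alpha, fit=re_fit.fit)
    return _wrap_re_fit(pruned)
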