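"""Fixed-effects meta-analytic aggregation of Gaussian graphical models.

Several datasets measured on the same variables are modeled jointly by the
weighted sum of per-dataset fit functions, ``F = sum_i (n_i / n) F_i``.  The
distribution Jacobian/Hessian and the model Jacobian are block-structured
per dataset; equality constraints across datasets live entirely in the
manual Jacobian, so a single pooled network is one column per edge shared by
all groups.

Two estimation routes are provided:

* **two-stage**: estimate a pooled correlation vector (with its Fisher
  information) by maximum likelihood, then fit the network to the pooled
  correlations by weighted least squares with the Fisher information as
  weight matrix;
* **multi-dataset**: estimate the network directly under cross-dataset
  equality constraints.

For a saturated network both routes give identical estimates and standard
errors.  ``partial_prune`` searches for partial invariance: edges are freed
across datasets one at a time, guided by summed modification indices, as
long as BIC improves, followed by a final significance pruning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

from .fit_engine import (
    FitResult,
    ModelSpec,
    ParameterTable,
    fit_ml,
    modification_indices,
    prune,
)
from .gaussian_family import (
    CorrelationData,
    std_gauss_fit,
    std_gauss_hessian,
    std_gauss_jacobian,
    wls_fit,
    wls_hessian,
    wls_jacobian,
)
from .ggm_model import corr_to_ggm, ggm_model_jacobian, ggm_to_corr
from .matcalc import vechs, vechs_indices

__all__ = [
    "MultiDatasetSpec",
    "PooledCorrelation",
    "PartialPruneResult",
    "build_multidataset_table",
    "multidataset_spec",
    "combined_fit",
    "combined_gradient",
    "combined_hessian",
    "pool_correlations",
    "two_stage_fixed",
    "multidataset_ggm",
    "partial_prune",
    "omega_from_fit",
]


def _check_aligned(datasets: list[CorrelationData]) -> tuple[int, list[str]]:
    if not datasets:
        raise ValueError("at least one dataset is required")
    p = datasets[0].p
    labels = datasets[0].labels
    for d in datasets[1:]:
        if d.p != p or d.labels != labels:
            raise ValueError(
                "all datasets must share the same variables in the same order; "
                f"got {d.labels} vs {labels}"
            )
    return p, labels


# ---------------------------------------------------------------------------
# parameter tables for multi-dataset GGMs
# ---------------------------------------------------------------------------

def build_multidataset_table(
    p: int,
    k: int,
    edge_status: dict[int, str] | str = "pooled",
    start_omega: np.ndarray | None = None,
) -> ParameterTable:
    """Parameter table for k datasets of a p-variable network.

    ``edge_status`` maps each edge index (vechs order) to ``"pooled"`` (one
    parameter shared by all datasets), ``"unique"`` (one parameter per
    dataset) or ``"zero"`` (fixed to zero everywhere); a plain string applies
    the same status to every edge.  Rows are ordered group-major.
    """
    q = p * (p - 1) // 2
    if isinstance(edge_status, str):
        edge_status = {e: edge_status for e in range(q)}
    rows_idx, cols_idx = vechs_indices(p)

    # assign psi columns deterministically, edge by edge
    col_of: dict[tuple[int, int], int] = {}  # (edge, group or -1 for shared)
    next_col = 0
    for e in range(q):
        status = edge_status.get(e, "zero")
        if status == "pooled":
            col_of[(e, -1)] = next_col
            next_col += 1
        elif status == "unique":
            for g in range(k):
                col_of[(e, g)] = next_col
                next_col += 1
        elif status != "zero":
            raise ValueError(f"unknown edge status {status!r}")

    labels, psi_index, start = [], [], []
    if start_omega is None:
        start_omega = np.zeros(q)
    for g in range(k):
        for e in range(q):
            labels.append(("omega", int(rows_idx[e]), int(cols_idx[e]), g))
            status = edge_status.get(e, "zero")
            if status == "pooled":
                psi_index.append(col_of[(e, -1)])
            elif status == "unique":
                psi_index.append(col_of[(e, g)])
            else:
                psi_index.append(-1)
            start.append(start_omega[e])
    return ParameterTable(labels, np.array(psi_index), start=np.array(start))


# ---------------------------------------------------------------------------
# multi-dataset specs
# ---------------------------------------------------------------------------

@dataclass
class MultiDatasetSpec:
    """Bundle of aligned datasets with their joint model specification."""

    datasets: list[CorrelationData]
    spec: ModelSpec

    @property
    def k(self) -> int:
        return len(self.datasets)


def _omega_matrix(theta_g: np.ndarray, p: int) -> np.ndarray:
    rows, cols = vechs_indices(p)
    Om = np.zeros((p, p))
    Om[rows, cols] = theta_g
    Om[cols, rows] = theta_g
    return Om


def multidataset_spec(
    datasets: list[CorrelationData],
    model: str = "ggm",
    table: ParameterTable | str = "pooled",
) -> MultiDatasetSpec:
    """Joint spec over k datasets; ``model`` is ``"ggm"`` or ``"corr"``.

    ``table`` may be a ready :class:`ParameterTable` or the shorthand
    ``"pooled"`` / ``"unique"`` / ``"saturated"`` (= unique for k = 1).
    """
    p, labels = _check_aligned(datasets)
    k = len(datasets)
    q = p * (p - 1) // 2
    n_total = sum(d.n for d in datasets)
    weights = np.array([d.n / n_total for d in datasets])

    if isinstance(table, str):
        status = "unique" if (table == "saturated" or (table == "unique")) else "pooled"
        if model == "ggm":
            # start from the pooled sample partial correlations
            Rbar = sum(w * d.R for w, d in zip(weights, datasets))
            start = vechs(corr_to_ggm(_nearest_pd_corr(Rbar)))
        else:
            start = vechs(sum(w * d.R for w, d in zip(weights, datasets)))
        table = build_multidataset_table(p, k, status, start_omega=start)
    if table.n_theta != k * q:
        raise ValueError("parameter table does not span all datasets")

    def per_group(theta: np.ndarray) -> list[np.ndarray]:
        return [theta[g * q : (g + 1) * q] for g in range(k)]

    if model == "ggm":
        def implied_P(theta_g: np.ndarray) -> np.ndarray:
            return ggm_to_corr(_omega_matrix(theta_g, p))

        def model_jac_block(theta_g: np.ndarray) -> np.ndarray:
            return ggm_model_jacobian(_omega_matrix(theta_g, p))
    elif model == "corr":
        rows_idx, cols_idx = vechs_indices(p)

        def implied_P(theta_g: np.ndarray) -> np.ndarray:
            P = np.eye(p)
            P[rows_idx, cols_idx] = theta_g
            P[cols_idx, rows_idx] = theta_g
            return P

        def model_jac_block(theta_g: np.ndarray) -> np.ndarray:
            return np.eye(q)
    else:
        raise ValueError(f"unknown model {model!r}")

    def fit_fun(theta: np.ndarray) -> float:
        return float(
            sum(
                w * std_gauss_fit(d.R, implied_P(tg))
                for w, d, tg in zip(weights, datasets, per_group(theta))
            )
        )

    def dist_jacobian(theta: np.ndarray) -> np.ndarray:
        return np.concatenate(
            [
                w * std_gauss_jacobian(d.R, implied_P(tg))
                for w, d, tg in zip(weights, datasets, per_group(theta))
            ]
        )

    def dist_hessian(theta: np.ndarray) -> np.ndarray:
        return scipy.linalg.block_diag(
            *[
                w * std_gauss_hessian(implied_P(tg))
                for w, tg in zip(weights, per_group(theta))
            ]
        )

    def model_jacobian(theta: np.ndarray) -> np.ndarray:
        return scipy.linalg.block_diag(
            *[model_jac_block(tg) for tg in per_group(theta)]
        )

    saturated = float(
        sum(w * std_gauss_fit(d.R, d.R) for w, d in zip(weights, datasets))
    )
    spec = ModelSpec(
        table=table,
        n=n_total,
        fit_fun=fit_fun,
        dist_jacobian=dist_jacobian,
        dist_hessian=dist_hessian,
        model_jacobian=model_jacobian,
        df_phi=k * q,
        saturated_fit=saturated,
        loglik_const=p * np.log(2 * np.pi),
        k_groups=k,
        meta={"model": model, "p": p, "k": k, "labels": labels},
    )
    return MultiDatasetSpec(datasets=datasets, spec=spec)


def _nearest_pd_corr(R: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Project a symmetric unit-diagonal matrix to the PD cone if needed."""
    w, V = np.linalg.eigh((R + R.T) / 2.0)
    if w.min() > floor:
        return R
    w = np.maximum(w, floor)
    S = (V * w) @ V.T
    d = np.sqrt(np.diag(S))
    S = S / np.outer(d, d)
    np.fill_diagonal(S, 1.0)
    return S


def combined_fit(mspec: MultiDatasetSpec, psi: np.ndarray) -> float:
    from .fit_engine import full_fit

    return full_fit(mspec.spec, psi)


def combined_gradient(mspec: MultiDatasetSpec, psi: np.ndarray) -> np.ndarray:
    from .fit_engine import full_jacobian

    return full_jacobian(mspec.spec, psi)


def combined_hessian(mspec: MultiDatasetSpec, psi: np.ndarray) -> np.ndarray:
    from .fit_engine import _expected_hessian_psi

    return _expected_hessian_psi(mspec.spec, psi)


# ---------------------------------------------------------------------------
# two-stage estimation
# ---------------------------------------------------------------------------

@dataclass
class PooledCorrelation:
    """Stage-1 result: pooled correlations with their Fisher information."""

    rho_hat: np.ndarray
    information: np.ndarray
    covariance: np.ndarray
    n: int
    p: int
    labels: list[str]
    fit: FitResult = field(repr=False, default=None)

    @property
    def P(self) -> np.ndarray:
        rows, cols = vechs_indices(self.p)
        P = np.eye(self.p)
        P[rows, cols] = self.rho_hat
        P[cols, rows] = self.rho_hat
        return P


def pool_correlations(datasets: list[CorrelationData]) -> PooledCorrelation:
    """ML pooled correlation vector and its Fisher information (stage 1)."""
    p, labels = _check_aligned(datasets)
    mspec = multidataset_spec(datasets, model="corr", table="pooled")
    fit = fit_ml(mspec.spec, gtol=1e-8)
    if fit.information is None:
        raise ValueError("pooled correlation model is not identified")
    if np.linalg.eigvalsh(PooledCorrelation(
        fit.psi_hat, fit.information, fit.covariance, mspec.spec.n, p, labels
    ).P).min() <= 0:
        import warnings

        warnings.warn("pooled correlation matrix is not positive definite", stacklevel=2)
    return PooledCorrelation(
        rho_hat=fit.psi_hat,
        information=fit.information,
        covariance=fit.covariance,
        n=int(mspec.spec.n),
        p=p,
        labels=labels,
        fit=fit,
    )


def _wls_ggm_spec(
    pooled: PooledCorrelation,
    W: np.ndarray,
    table: ParameterTable,
    k_datasets: int,
) -> ModelSpec:
    p = pooled.p
    q = p * (p - 1) // 2

    def fit_fun(theta: np.ndarray) -> float:
        P = ggm_to_corr(_omega_matrix(theta, p))
        return wls_fit(pooled.rho_hat, vechs(P), W)

    def dist_jacobian(theta: np.ndarray) -> np.ndarray:
        P = ggm_to_corr(_omega_matrix(theta, p))
        return wls_jacobian(pooled.rho_hat, vechs(P), W)

    return ModelSpec(
        table=table,
        n=pooled.n,
        fit_fun=fit_fun,
        dist_jacobian=dist_jacobian,
        dist_hessian=lambda theta: wls_hessian(W),
        model_jacobian=lambda theta: ggm_model_jacobian(_omega_matrix(theta, p)),
        df_phi=q,
        saturated_fit=0.0,
        k_groups=k_datasets,
        meta={"model": "two_stage_ggm", "p": p, "k": k_datasets,
              "labels": pooled.labels},
    )


def two_stage_fixed(
    datasets: list[CorrelationData],
    pattern: np.ndarray | None = None,
    alpha: float | None = None,
    weights: str = "fisher",
) -> FitResult:
    """Two-stage fixed-effects aggregation: pooled ML correlations, then a
    WLS network fit with the stage-1 Fisher information as weight matrix.

    ``pattern`` is a boolean vector over edges (vechs order) marking free
    edges (default: all).  ``weights`` may be ``"fisher"`` (full weight
    matrix), ``"dwls"`` (its diagonal) or ``"uls"`` (identity).  When
    ``alpha`` is given, edges non-significant at that level are removed in a
    single pass and the model refit.
    """
    pooled = pool_correlations(datasets)
    p, q = pooled.p, pooled.p * (pooled.p - 1) // 2
    if weights == "fisher":
        W = pooled.information
    elif weights == "dwls":
        W = np.diag(np.diag(pooled.information))
    elif weights == "uls":
        W = np.eye(q)
    else:
        raise ValueError(f"unknown weights {weights!r}")

    start = vechs(corr_to_ggm(_nearest_pd_corr(pooled.P)))
    status = {e: ("pooled" if (pattern is None or pattern[e]) else "zero")
              for e in range(q)}
    table = build_multidataset_table(p, 1, status, start_omega=start)
    spec = _wls_ggm_spec(pooled, W, table, k_datasets=len(datasets))
    fit = fit_ml(spec, gtol=1e-6)
    if alpha is not None:
        fit = prune(spec, alpha=alpha, fit=fit, gtol=1e-6)
    return fit


# ---------------------------------------------------------------------------
# multi-dataset estimation
# ---------------------------------------------------------------------------

def multidataset_ggm(
    datasets: list[CorrelationData],
    parameter_table: ParameterTable | str = "pooled",
    alpha: float | None = None,
) -> FitResult:
    """Direct multi-dataset network fit with cross-dataset constraints.

    ``parameter_table`` may be ``"pooled"`` (all edges equal across
    datasets), ``"unique"`` (independent networks) or an explicit
    :class:`ParameterTable` for partial equality.  With ``alpha`` set,
    non-significant edges are pruned in a single pass.
    """
    mspec = multidataset_spec(datasets, model="ggm", table=parameter_table)
    fit = fit_ml(mspec.spec, gtol=1e-6)
    if alpha is not None:
        fit = prune(mspec.spec, alpha=alpha, fit=fit, gtol=1e-6)
    return fit


def omega_from_fit(fit: FitResult, group: int = 0) -> np.ndarray:
    """Reconstruct a group's partial-correlation matrix from a fit."""
    spec = fit.spec
    p = spec.meta["p"]
    q = p * (p - 1) // 2
    theta = spec.theta(fit.psi_hat)
    k = spec.meta.get("k", 1)
    if theta.size == q:  # two-stage: one block regardless of k
        block = theta
    else:
        if not 0 <= group < k:
            raise ValueError(f"group {group} out of range")
        block = theta[group * q : (group + 1) * q]
    return _omega_matrix(block, p)


# ---------------------------------------------------------------------------
# partial pruning
# ---------------------------------------------------------------------------

@dataclass
class PartialPruneResult:
    fit: FitResult
    edge_status: dict[int, str]          # pooled / unique / zero after search
    per_group_omega: list[np.ndarray]
    history: list[dict]

    def summary(self) -> pd.DataFrame:
        spec = self.fit.spec
        p = spec.meta["p"]
        rows, cols = vechs_indices(p)
        return pd.DataFrame(
            {
                "node_i": rows + 1,
                "node_j": cols + 1,
                "status": [self.edge_status[e] for e in range(len(rows))],
            }
        )


def partial_prune(
    datasets: list[CorrelationData],
    alpha: float = 0.05,
    max_steps: int = 50,
) -> PartialPruneResult:
    """Search for a partially invariant network across datasets.

    1. prune a saturated network in each dataset separately;
    2. fit a pooled model containing every edge retained in at least one
       dataset, all equal across datasets;
    3. repeatedly free (make dataset-specific) the equality-constrained edge
       with the largest modification-index sum over datasets, keeping the
       step only while BIC improves;
    4. remove all non-significant edge weights at ``alpha`` and refit.
    """
    if len(datasets) < 2:
        raise ValueError("partial pruning requires at least two datasets")
    p, _ = _check_aligned(datasets)
    k = len(datasets)
    q = p * (p - 1) // 2

    # step 1: per-dataset pruned models
    union = np.zeros(q, dtype=bool)
    for d in datasets:
        single = multidataset_ggm([d], "unique", alpha=alpha)
        theta = single.spec.theta(single.psi_hat)
        union |= theta != 0
    history: list[dict] = [{"step": "per_dataset_union", "edges": int(union.sum())}]

    # step 2: pooled model with the union of edges
    edge_status = {e: ("pooled" if union[e] else "zero") for e in range(q)}
    current = multidataset_ggm(datasets, _status_table(datasets, edge_status))
    history.append({"step": "pooled_union", "bic": current.bic})

    # step 3: BIC-guided freeing of equality constraints
    for _ in range(max_steps):
        pooled_edges = [e for e, s in edge_status.items() if s == "pooled"]
        if not pooled_edges:
            break
        spec = current.spec
        # candidate theta rows: every group copy of each pooled edge
        cand_rows = [g * q + e for e in pooled_edges for g in range(k)]
        mi = modification_indices(spec, current, cand_rows)
        mi["edge"] = [r % q for r in mi["theta_index"]]
        summed = mi.groupby("edge")["mi"].sum()
        best_edge = int(summed.idxmax())
        trial_status = dict(edge_status)
        trial_status[best_edge] = "unique"
        trial = multidataset_ggm(datasets, _status_table(datasets, trial_status))
        history.append(
            {
                "step": "free_edge",
                "edge": best_edge,
                "mi_sum": float(summed.max()),
                "bic_before": current.bic,
                "bic_after": trial.bic,
            }
        )
        if trial.bic is not None and current.bic is not None and trial.bic < current.bic:
            edge_status = trial_status
            current = trial
        else:
            break

    # step 4: final significance pruning
    final = prune(current.spec, alpha=alpha, fit=current, gtol=1e-6)

    theta = final.spec.theta(final.psi_hat)
    per_group = [_omega_matrix(theta[g * q : (g + 1) * q], p) for g in range(k)]
    for e in range(q):
        vals = theta[[g * q + e for g in range(k)]]
        if np.all(vals == 0):
            edge_status[e] = "zero"
    return PartialPruneResult(
        fit=final, edge_status=edge_status, per_group_omega=per_group, history=history
    )


def _status_table(
    datasets: list[CorrelationData], edge_status: dict[int, str]
) -> ParameterTable:
    p = datasets[0].p
    q = p * (p - 1) // 2
    n_total = sum(d.n for d in datasets)
    Rbar = sum((d.n / n_total) * d.R for d in datasets)
    start = vechs(corr_to_ggm(_nearest_pd_corr(Rbar)))
    return build_multidataset_table(p, len(datasets), edge_status, start_omega=start)
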