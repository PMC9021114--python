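"""General maximum-likelihood estimator for structured multivariate models.

Every model in this package is estimated through the same chain:

    F(phi(theta(psi)))

where ``phi`` are distribution parameters (e.g. all correlations), ``theta``
model parameters (e.g. all potential network edges) and ``psi`` the free
parameters.  The full Jacobian is the product of the distribution Jacobian,
the model Jacobian, and a sparse 0/1 *manual Jacobian* M = d theta / d psi
that encodes fixed-to-zero and equality constraints.  The Fisher information
at the optimum is

    I(psi) = 0.5 M' J' E[H_phi] J M,

with parameter covariance V = I^{-1} / n, from which Wald tests, pruning,
fit indices and modification indices follow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize
import scipy.sparse as sp
import scipy.stats

from .gaussian_family import (
    CorrelationData,
    SingularModelError,
    std_gauss_fit,
    std_gauss_hessian,
    std_gauss_jacobian,
)
from .ggm_model import ParameterizationError

__all__ = [
    "ParameterTable",
    "ModelSpec",
    "FitResult",
    "full_fit",
    "full_jacobian",
    "fit_ml",
    "fisher_information",
    "param_covariance",
    "wald_tests",
    "prune",
    "fit_indices",
    "lrt",
    "modification_indices",
    "saturated_correlation_spec",
]

_BIG = 1e12  # rejection value for inadmissible proposals


class ParameterTable:
    """Mapping from model parameters theta to free parameters psi.

    Each row corresponds to one model parameter, identified by a matrix
    name, element indices and a group id.  ``psi_index[row] = j`` maps the
    row to free parameter j (several rows sharing a column encode an
    equality constraint); ``psi_index[row] = -1`` marks a fixed parameter
    with value ``fixed_values[row]``.
    """

    def __init__(
        self,
        labels: Sequence[tuple[str, int, int, int]],
        psi_index: np.ndarray,
        fixed_values: np.ndarray | None = None,
        start: np.ndarray | None = None,
        prunable: np.ndarray | None = None,
    ) -> None:
        self.labels = list(labels)
        self.psi_index = np.asarray(psi_index, dtype=int)
        n_theta = len(self.labels)
        if self.psi_index.shape != (n_theta,):
            raise ValueError("psi_index must have one entry per model parameter")
        self.fixed_values = (
            np.zeros(n_theta) if fixed_values is None else np.asarray(fixed_values, float)
        )
        self.start = np.zeros(n_theta) if start is None else np.asarray(start, float)
        used = self.psi_index[self.psi_index >= 0]
        self.n_psi = int(used.max()) + 1 if used.size else 0
        if used.size and set(used) != set(range(self.n_psi)):
            raise ValueError("psi indices must be consecutive integers starting at 0")
        if prunable is None:
            prunable = np.ones(self.n_psi, dtype=bool)
        self.prunable = np.asarray(prunable, dtype=bool)

    @property
    def n_theta(self) -> int:
        return len(self.labels)

    @property
    def M(self) -> sp.csr_matrix:
        """Sparse 0/1 manual Jacobian of shape (n_theta, n_psi)."""
        rows = np.nonzero(self.psi_index >= 0)[0]
        cols = self.psi_index[rows]
        return sp.csr_matrix(
            (np.ones(rows.size), (rows, cols)), shape=(self.n_theta, self.n_psi)
        )

    def theta(self, psi: np.ndarray) -> np.ndarray:
        out = self.fixed_values.copy()
        free = self.psi_index >= 0
        out[free] = np.asarray(psi)[self.psi_index[free]]
        return out

    def start_psi(self) -> np.ndarray:
        """Starting psi: average of starting theta values mapped to each column."""
        psi = np.zeros(self.n_psi)
        counts = np.zeros(self.n_psi)
        for row, j in enumerate(self.psi_index):
            if j >= 0:
                psi[j] += self.start[row]
                counts[j] += 1
        return psi / np.maximum(counts, 1)

    def drop_psi(self, remove: Sequence[int]) -> "ParameterTable":
        """Return a new table with the given psi columns fixed to zero."""
        remove = set(int(j) for j in remove)
        new_index = np.full(self.n_theta, -1, dtype=int)
        mapping: dict[int, int] = {}
        keep_prunable = []
        for row, j in enumerate(self.psi_index):
            if j < 0 or j in remove:
                continue
            if j not in mapping:
                mapping[j] = len(mapping)
                keep_prunable.append(self.prunable[j])
            new_index[row] = mapping[j]
        fixed = self.fixed_values.copy()
        fixed[np.isin(self.psi_index, list(remove))] = 0.0
        return ParameterTable(
            self.labels, new_index, fixed, self.start, np.array(keep_prunable, bool)
        )

    def as_frame(self, fit: "FitResult | None" = None) -> pd.DataFrame:
        df = pd.DataFrame(self.labels, columns=["matrix", "row", "col", "group"])
        df["psi"] = [j if j >= 0 else pd.NA for j in self.psi_index]
        df["fixed_value"] = self.fixed_values
        df["start"] = self.start
        if fit is not None:
            theta = self.theta(fit.psi_hat)
            df["estimate"] = theta
            se = np.full(self.n_theta, np.nan)
            pval = np.full(self.n_theta, np.nan)
            free = self.psi_index >= 0
            se[free] = fit.se[self.psi_index[free]]
            pval[free] = fit.p_values[self.psi_index[free]]
            df["se"] = se
            df["p_value"] = pval
        return df


@dataclass
class ModelSpec:
    """A concrete model: distribution + model map + parameter table.

    All callables take the model parameter vector theta.  ``n`` is the
    effective sample size entering V = I^{-1} / n (total cases for
    correlation-matrix models, number of studies for study-level models).
    """

    table: ParameterTable
    n: float
    fit_fun: Callable[[np.ndarray], float]
    dist_jacobian: Callable[[np.ndarray], np.ndarray]
    dist_hessian: Callable[[np.ndarray], np.ndarray]
    model_jacobian: Callable[[np.ndarray], np.ndarray]
    df_phi: int
    saturated_fit: float | None = None
    loglik_const: float | None = None  # additive constant c in l = -(n/2)(c + F)
    k_groups: int = 1
    meta: dict = field(default_factory=dict)

    def theta(self, psi: np.ndarray) -> np.ndarray:
        return self.table.theta(psi)


@dataclass
class FitResult:
    psi_hat: np.ndarray
    F_hat: float
    gradient_norm: float
    converged: bool
    iterations: int
    information: np.ndarray | None = None
    covariance: np.ndarray | None = None
    se: np.ndarray | None = None
    z_values: np.ndarray | None = None
    p_values: np.ndarray | None = None
    chi2: float | None = None
    df: int | None = None
    aic: float | None = None
    bic: float | None = None
    rmsea: float | None = None
    spec: ModelSpec | None = None

    @property
    def n_free(self) -> int:
        return self.psi_hat.size

    def parameters(self) -> pd.DataFrame:
        if self.spec is None:
            raise ValueError("fit carries no model specification")
        return self.spec.table.as_frame(self)


# ---------------------------------------------------------------------------
# chain rule
# ---------------------------------------------------------------------------

def full_fit(spec: ModelSpec, psi: np.ndarray) -> float:
    """Fit function F(psi); inadmissible proposals return a large value."""
    theta = spec.theta(psi)
    try:
        return spec.fit_fun(theta)
    except (ParameterizationError, SingularModelError):
        return _BIG


def full_jacobian(spec: ModelSpec, psi: np.ndarray) -> np.ndarray:
    """Row vector dF/dpsi = (dF/dphi)(dphi/dtheta)(dtheta/dpsi)."""
    theta = spec.theta(psi)
    dist = spec.dist_jacobian(theta)
    model = spec.model_jacobian(theta)
    if dist.shape[-1] != model.shape[0]:
        raise ValueError(
            f"distribution Jacobian length {dist.shape[-1]} does not match "
            f"model Jacobian rows {model.shape[0]}"
        )
    return np.asarray((dist @ model) @ spec.table.M).ravel()


def _fit_and_grad(spec: ModelSpec, psi: np.ndarray) -> tuple[float, np.ndarray]:
    theta = spec.theta(psi)
    try:
        f = spec.fit_fun(theta)
        g = np.asarray(
            (spec.dist_jacobian(theta) @ spec.model_jacobian(theta)) @ spec.table.M
        ).ravel()
    except (ParameterizationError, SingularModelError):
        return _BIG, np.zeros(psi.size)
    if not np.isfinite(f) or not np.all(np.isfinite(g)):
        return _BIG, np.zeros(psi.size)
    return f, g


def _expected_hessian_psi(spec: ModelSpec, psi: np.ndarray) -> np.ndarray:
    """Expected Hessian of F with respect to psi: M' J' H J M (= 2 I)."""
    theta = spec.theta(psi)
    J = spec.model_jacobian(theta)
    H = spec.dist_hessian(theta)
    M = spec.table.M
    JM = J @ M
    return np.asarray(JM.T @ H @ JM)


# ---------------------------------------------------------------------------
# estimation
# ---------------------------------------------------------------------------

def fit_ml(
    spec: ModelSpec,
    start: np.ndarray | None = None,
    gtol: float = 1e-5,
    maxiter: int = 1000,
    method: str = "auto",
) -> FitResult:
    """Minimize the fit function and assemble inference quantities.

    ``method="auto"`` uses Fisher-scoring via a trust-region Newton solver
    (the expected Hessian is cheap and positive definite near the optimum),
    falling back to BFGS if that stalls.  The convergence flag is honest:
    a fit whose gradient norm exceeds ``gtol`` is flagged, not hidden.
    """
    psi0 = spec.table.start_psi() if start is None else np.asarray(start, float)
    if psi0.size == 0:
        f = full_fit(spec, psi0)
        res = FitResult(psi0, f, 0.0, True, 0, spec=spec)
        _finalize(res, spec)
        return res

    methods = ["L-BFGS-B", "fisher", "BFGS"] if method == "auto" else [method]
    best = None
    x0 = psi0
    for m in methods:
        if m == "fisher":
            opt = _fisher_scoring(spec, x0, gtol=gtol, maxiter=maxiter)
        else:
            kwargs: dict = {"jac": True}
            if m in ("trust-ncg", "trust-exact", "Newton-CG"):
                kwargs["hess"] = lambda psi: _regularized(
                    _expected_hessian_psi(spec, psi)
                )
                options = {"maxiter": maxiter}
            elif m == "L-BFGS-B":
                options = {"maxiter": maxiter, "gtol": gtol, "ftol": 1e-14,
                           "maxcor": 25}
            else:
                options = {"maxiter": maxiter, "gtol": gtol}
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                opt = scipy.optimize.minimize(
                    lambda psi: _fit_and_grad(spec, psi),
                    x0,
                    method=m,
                    options=options,
                    **kwargs,
                )
        gnorm = float(np.max(np.abs(_fit_and_grad(spec, opt.x)[1])))
        cand = (gnorm, opt)
        if best is None or gnorm < best[0]:
            best = cand
        if gnorm < gtol:
            break
        x0 = best[1].x  # warm-start the next method from the best point so far

    gnorm, opt = best
    res = FitResult(
        psi_hat=np.atleast_1d(opt.x),
        F_hat=float(opt.fun),
        gradient_norm=gnorm,
        converged=bool(gnorm < gtol),
        iterations=int(getattr(opt, "nit", 0)),
        spec=spec,
    )
    _finalize(res, spec)
    return res


def _fisher_scoring(spec: ModelSpec, x0: np.ndarray, gtol: float, maxiter: int):
    """Damped Newton iteration using the expected (Fisher) Hessian.

    Near the optimum the expected Hessian matches the true curvature, giving
    fast final convergence where quasi-Newton methods crawl along weakly
    identified directions.
    """
    from types import SimpleNamespace

    psi = np.asarray(x0, float).copy()
    f, g = _fit_and_grad(spec, psi)
    lam = 1e-6
    nit = 0
    eye = np.eye(psi.size)
    for _ in range(maxiter):
        if np.max(np.abs(g)) < gtol:
            break
        H = _expected_hessian_psi(spec, psi)
        H = (H + H.T) / 2.0
        step = None
        for _ in range(40):
            try:
                c = scipy.linalg.cho_factor(H + lam * eye, lower=True)
                step = -scipy.linalg.cho_solve(c, g)
                break
            except scipy.linalg.LinAlgError:
                lam *= 10.0
        if step is None:
            break
        slope = float(g @ step)
        if slope >= 0:  # damping too weak to give a descent direction
            lam *= 10.0
            continue
        t, accepted = 1.0, False
        for _ in range(40):
            f_new, g_new = _fit_and_grad(spec, psi + t * step)
            if f_new <= f + 1e-4 * t * slope:
                psi = psi + t * step
                f, g = f_new, g_new
                lam = max(lam / 10.0, 1e-10)
                accepted = True
                break
            t /= 2.0
        nit += 1
        if not accepted:
            lam *= 100.0
            if lam > 1e10:
                break
    return SimpleNamespace(x=psi, fun=f, nit=nit)


def _regularized(H: np.ndarray, eps: float = 1e-10) -> np.ndarray:
    # keep the expected Hessian usable as a trust-region model even when
    # slightly indefinite far from the optimum
    H = (H + H.T) / 2.0
    w = np.linalg.eigvalsh(H)
    if w.min() < eps:
        H = H + (eps - w.min()) * np.eye(H.shape[0])
    return H


def _finalize(res: FitResult, spec: ModelSpec) -> None:
    if res.n_free:
        res.information = fisher_information(spec, res.psi_hat)
        res.covariance = _blockwise_covariance(spec, res.information)
        with np.errstate(invalid="ignore"):
            res.se = np.sqrt(np.maximum(np.diag(res.covariance), 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            res.z_values = np.where(res.se > 0, res.psi_hat / res.se, 0.0)
        res.z_values = np.where(np.isnan(res.se), np.nan, res.z_values)
        res.p_values = 2.0 * scipy.stats.norm.sf(np.abs(res.z_values))
    else:
        res.information = np.zeros((0, 0))
        res.covariance = np.zeros((0, 0))
        res.se = np.zeros(0)
        res.z_values = np.zeros(0)
        res.p_values = np.zeros(0)
    if spec.saturated_fit is not None:
        _attach_indices(res, spec)


def fisher_information(spec: ModelSpec, psi: np.ndarray) -> np.ndarray:
    """Unit Fisher information 0.5 M' J' E[H_phi] J M at psi."""
    return 0.5 * _expected_hessian_psi(spec, psi)


def param_covariance(spec: ModelSpec, information: np.ndarray) -> np.ndarray:
    """Parameter covariance V = I^{-1} / n; singular I names the defect.

    Rank deficiency (e.g. duplicate free-parameter columns) raises an error
    listing the non-identified parameters.  Weakly identified but numerically
    positive definite information passes through, yielding honestly large
    variances.
    """
    I_sym = (information + information.T) / 2.0
    try:
        c, low = scipy.linalg.cho_factor(I_sym, lower=True)
        inv = scipy.linalg.cho_solve((c, low), np.eye(I_sym.shape[0]))
    except (scipy.linalg.LinAlgError, ValueError) as exc:
        bad = _null_space_params(spec, I_sym)
        raise SingularModelError(
            "Fisher information is singular; non-identified parameters: " + bad
        ) from exc
    return inv / spec.n


def _blockwise_covariance(spec: ModelSpec, information: np.ndarray) -> np.ndarray:
    """Covariance computed per independent block of the information matrix.

    The information is exactly block-diagonal between parameter groups whose
    distribution and model Jacobian blocks do not mix (e.g. network edges
    versus heterogeneity Cholesky entries).  Blocks that are not numerically
    positive definite — a weakly identified heterogeneity factor at small
    numbers of studies — yield NaN variances for their parameters only,
    leaving inference on the identified block intact.
    """
    from scipy.sparse.csgraph import connected_components

    I_sym = (information + information.T) / 2.0
    m = I_sym.shape[0]
    scale = max(np.abs(I_sym).max(), 1.0)
    adjacency = sp.csr_matrix(np.abs(I_sym) > 1e-14 * scale)
    n_comp, labels_ = connected_components(adjacency, directed=False)
    V = np.full((m, m), np.nan)
    for c in range(n_comp):
        idx = np.nonzero(labels_ == c)[0]
        block = I_sym[np.ix_(idx, idx)]
        try:
            ch, low = scipy.linalg.cho_factor(block, lower=True)
            V[np.ix_(idx, idx)] = scipy.linalg.cho_solve(
                (ch, low), np.eye(idx.size)
            ) / spec.n
        except (scipy.linalg.LinAlgError, ValueError):
            pass  # block stays NaN: not identified at this sample
    return V


def _null_space_params(spec: ModelSpec, information: np.ndarray) -> str:
    w, v = np.linalg.eigh((information + information.T) / 2.0)
    bad = np.nonzero(np.abs(w) < 1e-8 * max(1.0, np.abs(w).max()))[0]
    idx = sorted({int(i) for j in bad for i in np.nonzero(np.abs(v[:, j]) > 0.3)[0]})
    return ", ".join(f"psi_{i}" for i in idx) or "(undetermined)"


def wald_tests(fit: FitResult) -> pd.DataFrame:
    """z statistics and two-sided normal p-values per free parameter."""
    if fit.se is None:
        raise SingularModelError("fit has no standard errors")
    return pd.DataFrame(
        {
            "estimate": fit.psi_hat,
            "se": fit.se,
            "z": fit.z_values,
            "p_value": fit.p_values,
        }
    )


# ---------------------------------------------------------------------------
# pruning
# ---------------------------------------------------------------------------

def prune(
    spec: ModelSpec,
    alpha: float = 0.05,
    fit: FitResult | None = None,
    recursive: bool = False,
    refit: Callable[[ParameterTable], ModelSpec] | None = None,
    **fit_kwargs,
) -> FitResult:
    """Remove all prunable parameters with p >= alpha simultaneously, refit.

    The default is a single removal round; ``recursive=True`` repeats until
    no parameter is removed.  ``refit`` rebuilds a spec from a reduced
    parameter table (defaults to replacing ``spec.table`` in place, which is
    correct for all specs built in this package).
    """
    if refit is None:
        def refit(tab: ParameterTable) -> ModelSpec:
            import dataclasses

            return dataclasses.replace(spec, table=tab)

    current_spec = spec
    current = fit if fit is not None else fit_ml(current_spec, **fit_kwargs)
    while True:
        if current.p_values is None:
            return current
        removable = np.nonzero(
            current_spec.table.prunable & (current.p_values >= alpha)
        )[0]
        if removable.size == 0:
            return current
        table = current_spec.table.drop_psi(removable)
        table.start = current_spec.theta(current.psi_hat)  # warm-start the refit
        current_spec = refit(table)
        current = fit_ml(current_spec, **fit_kwargs)
        if not recursive:
            return current


# ---------------------------------------------------------------------------
# fit indices, LRT, modification indices
# ---------------------------------------------------------------------------

def _attach_indices(res: FitResult, spec: ModelSpec) -> None:
    n = spec.n
    chi2 = max(0.0, n * (res.F_hat - spec.saturated_fit))
    df = spec.df_phi - res.n_free
    res.chi2 = chi2
    res.df = df
    if spec.loglik_const is not None:
        ll = -(n / 2.0) * (spec.loglik_const + res.F_hat)
        res.aic = -2.0 * ll + 2.0 * res.n_free
        res.bic = -2.0 * ll + res.n_free * np.log(n)
    if df > 0:
        res.rmsea = float(
            np.sqrt(spec.k_groups) * np.sqrt(max(0.0, chi2 - df) / (df * n))
        )
    else:
        res.rmsea = 0.0


def fit_indices(fit: FitResult, saturated_fit: float | None = None) -> dict:
    """chi2, df, AIC, BIC and RMSEA for a converged fit."""
    spec = fit.spec
    if saturated_fit is not None:
        import dataclasses

        spec = dataclasses.replace(spec, saturated_fit=saturated_fit)
        _attach_indices(fit, spec)
    return {
        "chi2": fit.chi2,
        "df": fit.df,
        "aic": fit.aic,
        "bic": fit.bic,
        "rmsea": fit.rmsea,
    }


def lrt(fit_constrained: FitResult, fit_free: FitResult) -> dict:
    """Likelihood-ratio test between two nested fits of the same data."""
    sc, sf = fit_constrained.spec, fit_free.spec
    if sc is None or sf is None or sc.n != sf.n or sc.df_phi != sf.df_phi:
        raise ValueError("fits are not comparable (different data or distribution)")
    df = fit_free.n_free - fit_constrained.n_free
    if df <= 0:
        raise ValueError("the first fit must be nested in (more constrained than) the second")
    stat = max(0.0, sc.n * (fit_constrained.F_hat - fit_free.F_hat))
    return {"statistic": stat, "df": df, "p_value": float(scipy.stats.chi2.sf(stat, df))}


def modification_indices(
    spec: ModelSpec,
    fit: FitResult,
    candidates: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Score statistics for freeing constrained model parameters one at a time.

    ``candidates`` are theta row indices whose constraint (fixed value or
    equality with other rows) would be released; by default every fixed row.
    Each index approximates the chi-square drop from freeing that parameter
    alone.  Requesting an index for an unconstrained parameter (a free row
    that shares its column with no other row) is an error.
    """
    table = spec.table
    if candidates is None:
        candidates = [int(r) for r in np.nonzero(table.psi_index < 0)[0]]
    candidates = list(candidates)
    col_counts = np.bincount(
        table.psi_index[table.psi_index >= 0], minlength=table.n_psi
    )
    for r in candidates:
        j = table.psi_index[r]
        if j >= 0 and col_counts[j] <= 1:
            raise ValueError(f"model parameter {r} is already freely estimated")

    theta = spec.theta(fit.psi_hat)
    dist = spec.dist_jacobian(theta)
    J = spec.model_jacobian(theta)
    g_theta = np.asarray(dist @ J).ravel()
    B = 0.5 * np.asarray(J.T @ spec.dist_hessian(theta) @ J)  # theta-level Fisher
    M = table.M
    I_free = np.asarray(M.T @ B @ M)

    mi = np.zeros(len(candidates))
    if fit.n_free:
        I_free_inv = scipy.linalg.pinvh(I_free)
    else:
        I_free_inv = np.zeros((0, 0))
    cross_all = np.asarray(M.T @ B)  # n_psi x n_theta
    for idx, r in enumerate(candidates):
        cross = cross_all[:, r]
        schur = B[r, r] - cross @ I_free_inv @ cross
        if schur <= 1e-12:
            mi[idx] = 0.0
        else:
            mi[idx] = (spec.n / 4.0) * g_theta[r] ** 2 / schur
    rows = [table.labels[r] for r in candidates]
    out = pd.DataFrame(rows, columns=["matrix", "row", "col", "group"])
    out["theta_index"] = candidates
    out["mi"] = mi
    return out


# ---------------------------------------------------------------------------
# concrete builder: saturated correlation model for one dataset
# ---------------------------------------------------------------------------

def saturated_correlation_spec(data: CorrelationData) -> ModelSpec:
    """Saturated correlation model: phi = theta = psi = vechs(P).

    Both the model and manual Jacobians are identities; the ML estimate is
    the sample correlation matrix itself.
    """
    from .matcalc import vechs_indices

    p = data.p
    q = p * (p - 1) // 2
    rows, cols = vechs_indices(p)
    labels = [("rho", int(i), int(j), 0) for i, j in zip(rows, cols)]
    table = ParameterTable(labels, np.arange(q), start=data.r.copy())

    def to_P(theta: np.ndarray) -> np.ndarray:
        P = np.eye(p)
        P[rows, cols] = theta
        P[cols, rows] = theta
        return P

    return ModelSpec(
        table=table,
        n=data.n,
        fit_fun=lambda th: std_gauss_fit(data.R, to_P(th)),
        dist_jacobian=lambda th: std_gauss_jacobian(data.R, to_P(th)),
        dist_hessian=lambda th: std_gauss_hessian(to_P(th)),
        model_jacobian=lambda th: np.eye(q),
        df_phi=q,
        saturated_fit=std_gauss_fit(data.R, data.R),
        loglik_const=p * np.log(2 * np.pi),
        meta={"model": "saturated_correlation", "labels": data.labels},
    )
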