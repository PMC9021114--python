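"""Fit functions and distribution-level derivatives for the Gaussian families.

Three likelihood families are used throughout the package, all expressed on
the -2/n log-likelihood scale (dropping distribution constants, which are
restored explicitly when absolute AIC/BIC values are reported):

* the standardized Gaussian on correlation matrices,
  ``F = trace(R K) - ln|K|`` with ``K = P^{-1}``;
* weighted least squares, ``F = (z - phi)' W (z - phi)``;
* the Gaussian on study-level correlation vectors used by random-effects
  meta-analytic aggregation,
  ``F = trace(S K) + (rbar - mu)' K (rbar - mu) - ln|K|`` with
  ``K = Sigma^{-1}``.

Analytic Jacobians are returned as row vectors (the gradient is the
transpose), and "Hessians" are the expected second derivatives used for
Fisher information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .matcalc import build_structural_matrices, vechs

__all__ = [
    "CorrelationData",
    "MetaRow",
    "SingularModelError",
    "sym_inverse",
    "std_gauss_fit",
    "std_gauss_jacobian",
    "std_gauss_hessian",
    "wls_fit",
    "wls_jacobian",
    "wls_hessian",
    "meta_gauss_fit",
    "meta_gauss_jacobian",
    "meta_gauss_hessian",
]


class SingularModelError(ValueError):
    """A model covariance matrix is singular or not positive definite."""


@dataclass
class CorrelationData:
    """One study's sample correlation matrix with its sample size.

    The matrix must be symmetric with a unit diagonal.  Pairwise-complete
    empirical matrices may be slightly indefinite; this is reported as a
    warning (not an error) since estimation may still proceed.
    """

    R: np.ndarray
    n: int
    labels: list[str] = field(default_factory=list)
    study_id: str = ""

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float)
        p = self.p
        if self.R.ndim != 2 or self.R.shape != (p, p):
            raise ValueError("R must be a square matrix")
        if not np.allclose(self.R, self.R.T, atol=1e-8):
            raise ValueError("R must be symmetric")
        if np.max(np.abs(np.diag(self.R) - 1.0)) > 1e-8:
            raise ValueError("R must have a unit diagonal")
        if self.n < p + 1:
            raise ValueError(f"sample size n={self.n} too small for p={p} variables")
        if not self.labels:
            self.labels = [f"V{i + 1}" for i in range(p)]
        if len(self.labels) != p:
            raise ValueError("number of labels must match the matrix dimension")
        self.min_eigenvalue = float(np.linalg.eigvalsh(self.R).min())
        if self.min_eigenvalue <= 0:
            warnings.warn(
                f"sample correlation matrix ({self.study_id or 'unnamed'}) is not "
                f"positive definite (min eigenvalue {self.min_eigenvalue:.3g})",
                stacklevel=2,
            )

    @property
    def p(self) -> int:
        return self.R.shape[0]

    @property
    def r(self) -> np.ndarray:
        """Strict half-vectorized sample correlations."""
        return vechs(self.R)


@dataclass
class MetaRow:
    """A study's correlation vector in the master vechs ordering.

    Entries may be NaN when a study did not measure one of the master
    variables; at least one entry must be present.
    """

    r: np.ndarray
    n: int
    study_id: str = ""

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        present = self.present
        if not present.any():
            raise ValueError("a study row must contain at least one correlation")
        vals = self.r[present]
        if np.any(np.abs(vals) >= 1):
            raise ValueError("correlations must lie in (-1, 1)")

    @property
    def present(self) -> np.ndarray:
        return ~np.isnan(self.r)


def sym_inverse(M: np.ndarray, name: str = "matrix") -> tuple[np.ndarray, float]:
    """Inverse and log-determinant of a symmetric PD matrix via Cholesky.

    Raises :class:`SingularModelError` naming the offending matrix if the
    factorization fails, rather than returning non-finite values.
    """
    M = np.asarray(M, dtype=float)
    try:
        c, low = scipy.linalg.cho_factor(M, lower=True)
    except (scipy.linalg.LinAlgError, ValueError) as exc:
        raise SingularModelError(f"{name} is singular or not positive definite") from exc
    logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
    inv = scipy.linalg.cho_solve((c, low), np.eye(M.shape[0]))
    return inv, logdet


# ---------------------------------------------------------------------------
# standardized Gaussian on correlation matrices
# ---------------------------------------------------------------------------

def std_gauss_fit(R: np.ndarray, P: np.ndarray) -> float:
    """-2/n log-likelihood (up to a constant) of R under model correlations P."""
    K, logdet_K = _inv_with_logdet(P, "model correlation matrix P")
    return float(np.trace(R @ K) - logdet_K)


def _inv_with_logdet(P: np.ndarray, name: str) -> tuple[np.ndarray, float]:
    inv, logdet = sym_inverse(P, name)
    return inv, -logdet  # ln|K| = -ln|P|


def std_gauss_jacobian(R: np.ndarray, P: np.ndarray) -> np.ndarray:
    """Row vector dF/drho over rho = vechs(P)."""
    p = P.shape[0]
    K, _ = sym_inverse(P, "model correlation matrix P")
    sm = build_structural_matrices(p)
    inner = K @ (R - P) @ K
    return -(inner.flatten(order="F") @ sm.Dstar)


def std_gauss_hessian(P: np.ndarray) -> np.ndarray:
    """Expected Hessian Dstar' (K kron K) Dstar over rho = vechs(P)."""
    p = P.shape[0]
    K, _ = sym_inverse(P, "model correlation matrix P")
    sm = build_structural_matrices(p)
    KK = np.kron(K, K)
    return np.asarray(sm.Dstar.T @ KK @ sm.Dstar)


# ---------------------------------------------------------------------------
# weighted least squares
# ---------------------------------------------------------------------------

def wls_fit(z: np.ndarray, phi: np.ndarray, W: np.ndarray) -> float:
    z, phi, W = _check_wls(z, phi, W)
    d = z - phi
    return float(d @ W @ d)


def wls_jacobian(z: np.ndarray, phi: np.ndarray, W: np.ndarray) -> np.ndarray:
    z, phi, W = _check_wls(z, phi, W)
    return -2.0 * (z - phi) @ W


def wls_hessian(W: np.ndarray) -> np.ndarray:
    return 2.0 * np.asarray(W, dtype=float)


def _check_wls(z, phi, W):
    z = np.asarray(z, dtype=float)
    phi = np.asarray(phi, dtype=float)
    W = np.asarray(W, dtype=float)
    if z.shape != phi.shape or W.shape != (z.size, z.size):
        raise ValueError("dimension mismatch between z, phi and W")
    return z, phi, W


# ---------------------------------------------------------------------------
# Gaussian on study-level correlation vectors
# ---------------------------------------------------------------------------

def meta_gauss_fit(
    rbar: np.ndarray, S: np.ndarray, mu: np.ndarray, Sigma: np.ndarray
) -> float:
    """Fit of the study-level Gaussian: trace(S K) + (rbar-mu)'K(rbar-mu) - ln|K|.

    With ``S = O`` this is the per-study (FIML) form.
    """
    K, logdet_K = _inv_with_logdet(Sigma, "Sigma")
    d = rbar - mu
    return float(np.trace(S @ K) + d @ K @ d - logdet_K)


def meta_gauss_jacobian(
    rbar: np.ndarray, S: np.ndarray, mu: np.ndarray, Sigma: np.ndarray
) -> np.ndarray:
    """Row vector over (mu, sigma = vech(Sigma))."""
    q = Sigma.shape[0]
    K, _ = sym_inverse(Sigma, "Sigma")
    d = rbar - mu
    j_mu = -2.0 * d @ K
    inner = K @ (S + np.outer(d, d) - Sigma) @ K
    if q == 1:
        j_sigma = -inner.ravel()
    else:
        sm = build_structural_matrices(q)
        j_sigma = -(inner.flatten(order="F") @ sm.D)
    return np.concatenate([np.atleast_1d(j_mu), np.asarray(j_sigma).ravel()])


def meta_gauss_hessian(Sigma: np.ndarray) -> np.ndarray:
    """Block-diagonal expected Hessian: blocks 2K and D'(K kron K)D."""
    q = Sigma.shape[0]
    K, _ = sym_inverse(Sigma, "Sigma")
    H_mu = 2.0 * K
    if q == 1:
        H_sigma = np.kron(K, K)
    else:
        sm = build_structural_matrices(q)
        H_sigma = np.asarray(sm.D.T @ np.kron(K, K) @ sm.D)
    return scipy.linalg.block_diag(H_mu, H_sigma)
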