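"""The Gaussian graphical model parameterization and model-level Jacobians.

A GGM is encoded by a hollow symmetric matrix ``Omega`` whose off-diagonal
entries are partial correlations.  The implied correlation matrix is

    P = Delta (I - Omega)^{-1} Delta,

where ``Delta`` is the diagonal scaling that gives P a unit diagonal:
``Delta = vec2diag(diag((I - Omega)^{-1}))^{-1/2}``.

This module provides the forward map, its inverse (partial correlations from
a correlation matrix), the analytic model Jacobian d vechs(P) / d vechs(Omega),
and the Jacobian of the Cholesky parameterization ``Sigma = T T'`` used for
the heterogeneity covariance in random-effects aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .matcalc import build_structural_matrices, vechs

__all__ = [
    "ParameterizationError",
    "GGMStructure",
    "CholeskyRE",
    "ggm_to_corr",
    "corr_to_ggm",
    "ggm_delta",
    "ggm_model_jacobian",
    "cholesky_model_jacobian",
]


class ParameterizationError(ValueError):
    """Omega lies outside the admissible region of the GGM parameterization."""


def _check_hollow_symmetric(Omega: np.ndarray) -> np.ndarray:
    Omega = np.asarray(Omega, dtype=float)
    p = Omega.shape[0]
    if Omega.ndim != 2 or Omega.shape != (p, p):
        raise ValueError("Omega must be square")
    if not np.allclose(Omega, Omega.T, atol=1e-10):
        raise ValueError("Omega must be symmetric")
    if np.max(np.abs(np.diag(Omega))) > 1e-12:
        raise ValueError("Omega must have a zero diagonal")
    return Omega


def _omega_star(Omega: np.ndarray) -> np.ndarray:
    """(I - Omega)^{-1}, raising ParameterizationError when inadmissible."""
    p = Omega.shape[0]
    try:
        Ostar = scipy.linalg.inv(np.eye(p) - Omega)
    except scipy.linalg.LinAlgError as exc:
        raise ParameterizationError("I - Omega is singular") from exc
    if not np.all(np.isfinite(Ostar)):
        raise ParameterizationError("I - Omega is numerically singular")
    if np.any(np.diag(Ostar) <= 0):
        raise ParameterizationError("(I - Omega)^{-1} has a non-positive diagonal")
    return Ostar


def ggm_delta(Omega: np.ndarray) -> np.ndarray:
    """Diagonal scaling matrix Delta implied by Omega."""
    Ostar = _omega_star(_check_hollow_symmetric(Omega))
    return np.diag(np.diag(Ostar) ** -0.5)


def ggm_to_corr(Omega: np.ndarray) -> np.ndarray:
    """Implied correlation matrix P = Delta (I - Omega)^{-1} Delta."""
    Omega = _check_hollow_symmetric(Omega)
    Ostar = _omega_star(Omega)
    d = np.diag(Ostar) ** -0.5
    P = Ostar * np.outer(d, d)
    # enforce exact symmetry / unit diagonal against rounding
    P = (P + P.T) / 2.0
    np.fill_diagonal(P, 1.0)
    return P


def corr_to_ggm(P: np.ndarray) -> np.ndarray:
    """Partial correlation matrix Omega from a PD correlation matrix P.

    Uses ``omega_ij = -kappa_ij / sqrt(kappa_ii kappa_jj)`` with
    ``kappa = P^{-1}``, the sign convention under which edges are partial
    correlations (verified by the round-trip with :func:`ggm_to_corr`).
    """
    P = np.asarray(P, dtype=float)
    try:
        K = scipy.linalg.inv(P)
    except scipy.linalg.LinAlgError as exc:
        raise ParameterizationError("P is singular") from exc
    d = np.diag(K) ** -0.5
    Omega = -K * np.outer(d, d)
    Omega = (Omega + Omega.T) / 2.0
    np.fill_diagonal(Omega, 0.0)
    return Omega


@dataclass
class GGMStructure:
    """A GGM with its derived scaling and implied correlation matrix."""

    Omega: np.ndarray
    pattern: np.ndarray | None = None  # boolean inclusion matrix for free edges

    def __post_init__(self) -> None:
        self.Omega = _check_hollow_symmetric(self.Omega)
        if self.pattern is None:
            self.pattern = np.ones_like(self.Omega, dtype=bool)
            np.fill_diagonal(self.pattern, False)

    @property
    def p(self) -> int:
        return self.Omega.shape[0]

    @property
    def Delta(self) -> np.ndarray:
        return ggm_delta(self.Omega)

    @property
    def P(self) -> np.ndarray:
        return ggm_to_corr(self.Omega)

    @property
    def omega(self) -> np.ndarray:
        return vechs(self.Omega)


def ggm_model_jacobian(Omega: np.ndarray) -> np.ndarray:
    """Analytic model Jacobian d vechs(P) / d vechs(Omega).

    With ``Ostar = (I - Omega)^{-1}`` and ``Delta`` as above:

        Lstar [ (Delta Ostar kron Delta Ostar)
                - 0.5 ((Delta Ostar kron I) + (I kron Delta Ostar))
                      A dmat(Ostar)^{-3/2} A' (Ostar kron Ostar) ] Dstar,

    where the power -3/2 acts only on the diagonal entries of the diagonal
    matrix.  Square of size p(p-1)/2.
    """
    Omega = _check_hollow_symmetric(Omega)
    p = Omega.shape[0]
    Ostar = _omega_star(Omega)
    d = np.diag(Ostar)
    Delta = np.diag(d ** -0.5)
    DO = Delta @ Ostar

    sm = build_structural_matrices(p)
    A = sm.A.toarray()
    eye = np.eye(p)

    term1 = np.kron(DO, DO)
    middle = A @ np.diag(d ** -1.5) @ A.T
    term2 = 0.5 * (np.kron(DO, eye) + np.kron(eye, DO)) @ middle @ np.kron(Ostar, Ostar)
    return np.asarray(sm.Lstar @ (term1 - term2) @ sm.Dstar)


@dataclass
class CholeskyRE:
    """Cholesky-parameterized heterogeneity covariance Sigma_ran = T T'."""

    T: np.ndarray

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        if not np.allclose(self.T, np.tril(self.T)):
            raise ValueError("T must be lower triangular")

    @property
    def q(self) -> int:
        return self.T.shape[0]

    @property
    def tau(self) -> np.ndarray:
        from .matcalc import vech

        return vech(self.T)

    @property
    def SigmaRan(self) -> np.ndarray:
        return self.T @ self.T.T


def cholesky_model_jacobian(T: np.ndarray) -> np.ndarray:
    """Jacobian d vech(T T') / d vech(T) = L ((I kron I) + C) (T kron I) L'."""
    T = np.asarray(T, dtype=float)
    if not np.allclose(T, np.tril(T)):
        raise ValueError("T must be lower triangular")
    q = T.shape[0]
    if q == 1:
        return np.array([[2.0 * T[0, 0]]])
    # elementwise form of L ((I kron I) + C) (T kron I) L':
    # d(TT')_{ij} / dT_{ab} = delta_{ia} T_{jb} + delta_{ja} T_{ib}
    from .matcalc import vech_indices

    ri, ci = vech_indices(q)
    J = (ri[:, None] == ri[None, :]) * T[np.ix_(ci, ci)] + (
        ci[:, None] == ri[None, :]
    ) * T[np.ix_(ri, ci)]
    return J
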