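"""Vectorization operators and structural 0/1 matrices for matrix calculus.

The analytic derivatives of every model in this package are expressed in
terms of the column-stacked vectorization ``vec`` and its half-vectorized
forms ``vech`` (lower triangle including the diagonal) and ``vechs`` (lower
triangle excluding the diagonal).  The sparse structural matrices built here
convert between these representations:

* duplication matrix ``D``:            ``D @ vech(M) == vec(M)`` for symmetric M
* strict duplication matrix ``Dstar``: ``Dstar @ vechs(M) == vec(M)`` for
  symmetric hollow (zero-diagonal) M
* elimination matrices ``L`` / ``Lstar``: ``L @ vec(M) == vech(M)`` and
  ``Lstar @ vec(M) == vechs(M)`` for any M
* commutation matrix ``C``:            ``C @ vec(M) == vec(M.T)``
* diagonal-selection matrix ``A``:     ``A.T @ vec(M) == diag(M)`` and
  ``A @ v == vec(diag-matrix with v on the diagonal)``

All orderings are column-major ("column-stacked"); vech/vechs enumerate the
lower triangle column by column.  Every parameter ordering elsewhere in the
package inherits this convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import scipy.sparse as sp

__all__ = [
    "vec",
    "vech",
    "vechs",
    "vec2diag",
    "dmat",
    "vech_indices",
    "vechs_indices",
    "StructuralMatrixSet",
    "build_structural_matrices",
]


def _require_square(M: np.ndarray) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {M.shape}")
    return M


def vec(M: np.ndarray) -> np.ndarray:
    """Column-stacked vectorization of a square matrix."""
    return _require_square(M).flatten(order="F")


def vech(M: np.ndarray) -> np.ndarray:
    """Half-vectorization: lower triangle including the diagonal, by column."""
    M = _require_square(M)
    rows, cols = vech_indices(M.shape[0])
    return M[rows, cols]


def vechs(M: np.ndarray) -> np.ndarray:
    """Strict half-vectorization: lower triangle excluding the diagonal."""
    M = _require_square(M)
    rows, cols = vechs_indices(M.shape[0])
    return M[rows, cols]


def vec2diag(v: np.ndarray) -> np.ndarray:
    """Diagonal matrix with the entries of ``v`` on its diagonal."""
    v = np.asarray(v, dtype=float)
    if v.ndim != 1:
        raise ValueError("vec2diag expects a vector")
    return np.diag(v)


def dmat(M: np.ndarray) -> np.ndarray:
    """Zero all off-diagonal entries of a square matrix."""
    M = _require_square(M)
    return np.diag(np.diag(M))


def vech_indices(p: int) -> tuple[np.ndarray, np.ndarray]:
    """(row, col) index arrays of the vech ordering for dimension ``p``."""
    rows, cols = [], []
    for j in range(p):
        for i in range(j, p):
            rows.append(i)
            cols.append(j)
    return np.array(rows), np.array(cols)


def vechs_indices(p: int) -> tuple[np.ndarray, np.ndarray]:
    """(row, col) index arrays of the vechs ordering for dimension ``p``."""
    rows, cols = [], []
    for j in range(p):
        for i in range(j + 1, p):
            rows.append(i)
            cols.append(j)
    return np.array(rows), np.array(cols)


@dataclass(frozen=True)
class StructuralMatrixSet:
    """Sparse structural matrices for dimension ``p`` (see module docstring)."""

    p: int
    D: sp.csr_matrix       # p^2 x p(p+1)/2
    Dstar: sp.csr_matrix   # p^2 x p(p-1)/2
    L: sp.csr_matrix       # p(p+1)/2 x p^2
    Lstar: sp.csr_matrix   # p(p-1)/2 x p^2
    C: sp.csr_matrix       # p^2 x p^2
    A: sp.csr_matrix       # p^2 x p


def _vec_pos(i: int, j: int, p: int) -> int:
    # position of element (i, j) in column-major vec
    return j * p + i


@lru_cache(maxsize=64)
def build_structural_matrices(p: int) -> StructuralMatrixSet:
    """Construct all structural matrices for dimension ``p`` (p >= 2).

    Results are cached; the returned sparse matrices must be treated as
    read-only.
    """
    if p < 2:
        raise ValueError("structural matrices require p >= 2")

    nh = p * (p + 1) // 2
    ns = p * (p - 1) // 2

    # duplication D and elimination L
    d_rows, d_cols, l_rows, l_cols = [], [], [], []
    for col, (i, j) in enumerate(zip(*vech_indices(p))):
        d_rows.append(_vec_pos(i, j, p))
        d_cols.append(col)
        if i != j:
            d_rows.append(_vec_pos(j, i, p))
            d_cols.append(col)
        l_rows.append(col)
        l_cols.append(_vec_pos(i, j, p))
    D = sp.csr_matrix((np.ones(len(d_rows)), (d_rows, d_cols)), shape=(p * p, nh))
    L = sp.csr_matrix((np.ones(len(l_rows)), (l_rows, l_cols)), shape=(nh, p * p))

    # strict duplication Dstar and strict elimination Lstar
    ds_rows, ds_cols, ls_rows, ls_cols = [], [], [], []
    for col, (i, j) in enumerate(zip(*vechs_indices(p))):
        ds_rows.append(_vec_pos(i, j, p))
        ds_cols.append(col)
        ds_rows.append(_vec_pos(j, i, p))
        ds_cols.append(col)
        ls_rows.append(col)
        ls_cols.append(_vec_pos(i, j, p))
    Dstar = sp.csr_matrix((np.ones(len(ds_rows)), (ds_rows, ds_cols)), shape=(p * p, ns))
    Lstar = sp.csr_matrix((np.ones(len(ls_rows)), (ls_rows, ls_cols)), shape=(ns, p * p))

    # commutation C: vec(M) -> vec(M')
    c_rows = [_vec_pos(j, i, p) for j in range(p) for i in range(p)]
    c_cols = [_vec_pos(i, j, p) for j in range(p) for i in range(p)]
    C = sp.csr_matrix((np.ones(p * p), (c_rows, c_cols)), shape=(p * p, p * p))

    # diagonal selection A: A @ v = vec(diag(v))
    a_rows = [_vec_pos(i, i, p) for i in range(p)]
    A = sp.csr_matrix((np.ones(p), (a_rows, range(p))), shape=(p * p, p))

    return StructuralMatrixSet(p=p, D=D, Dstar=Dstar, L=L, Lstar=Lstar, C=C, A=A)
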