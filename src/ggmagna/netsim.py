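"""Synthetic-data generator and simulation harness for network recovery.

True networks are small-world graphs: nodes on a ring connected to their
``2 * nei`` nearest neighbors with each edge rewired with a fixed
probability (rewiring preserves the edge count, so an 8-node network with
``nei = 2`` always has 16 of 28 possible edges and a 16-node network 32 of
120).  Edges are weighted through a diagonally dominant precision matrix:
off-diagonal magnitudes are uniform draws, the diagonal is a constant times
the absolute row sums, rows are scaled by their diagonal and symmetrized,
and the resulting standardized precision matrix is negated off-diagonal to
give partial correlations.  Signs are assigned so that a stated proportion
of network edges (partial correlations) is positive.

Per-study population correlation vectors are the true implied correlations
plus a Gaussian random effect with covariance ``re_sd^2 x (random
correlation matrix)``; observed matrices are sample correlations of
standard-Gaussian draws at study sample sizes uniform on a range.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .gaussian_family import CorrelationData
from .ggm_model import ggm_to_corr
from .matcalc import vechs, vechs_indices

__all__ = [
    "TrueNetwork",
    "SimulationCondition",
    "generate_true_network",
    "generate_re_cov",
    "simulate_studies",
    "evaluate",
    "run_study",
]

METHODS = (
    "fixed_two_stage",
    "fixed_multidataset",
    "re_individual_averaged",
    "re_pooled_averaged",
    "re_individual_per_study",
    "re_pooled_per_study",
)


@dataclass
class TrueNetwork:
    Omega_true: np.ndarray
    adjacency: np.ndarray
    p: int

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.adjacency, 1)))

    @property
    def P(self) -> np.ndarray:
        return ggm_to_corr(self.Omega_true)


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def generate_true_network(
    p: int,
    nei: int = 2,
    rewire_p: float = 0.25,
    constant: float = 1.5,
    prop_positive: float = 0.9,
    par_range: tuple[float, float] = (0.5, 1.0),
    seed=None,
) -> TrueNetwork:
    """Generate a true partial-correlation network (see module docstring)."""
    if p < 2 * nei + 1:
        raise ValueError(f"p={p} too small for nei={nei} (need p >= {2 * nei + 1})")
    rng = _rng(seed)
    graph = nx.watts_strogatz_graph(
        p, 2 * nei, rewire_p, seed=int(rng.integers(2**31))
    )

    kappa = np.zeros((p, p))
    for i, j in graph.edges():
        mag = rng.uniform(*par_range)
        # a positive partial correlation corresponds to a negative
        # precision off-diagonal, so signs are assigned on the final scale
        sign = -1.0 if rng.random() < prop_positive else 1.0
        kappa[i, j] = kappa[j, i] = sign * mag

    diag = constant * np.sum(np.abs(kappa), axis=1)
    diag[diag == 0] = 1.0
    np.fill_diagonal(kappa, diag)
    kappa = kappa / diag[:, None]       # scale each row by its diagonal
    kappa = (kappa + kappa.T) / 2.0

    Omega = -kappa
    np.fill_diagonal(Omega, 0.0)
    adjacency = Omega != 0
    ggm_to_corr(Omega)  # validates admissibility (diagonal dominance => PD)
    return TrueNetwork(Omega_true=Omega, adjacency=adjacency, p=p)


def generate_re_cov(q: int, re_sd: float, seed=None) -> np.ndarray:
    """Heterogeneity covariance re_sd^2 x (random correlation matrix).

    The correlation matrix is drawn by the vine construction with unit
    concentration, spreading mass broadly over the space of positive
    definite correlation matrices.
    """
    if q < 1 or re_sd < 0:
        raise ValueError("q >= 1 and re_sd >= 0 required")
    rng = _rng(seed)
    if re_sd == 0:
        return np.zeros((q, q))
    return re_sd**2 * _random_corr(q, rng)


def _random_corr(d: int, rng: np.random.Generator, eta: float = 1.0) -> np.ndarray:
    if d == 1:
        return np.eye(1)
    partial = np.zeros((d, d))
    S = np.eye(d)
    beta = eta + (d - 1) / 2.0
    for k in range(d - 1):
        beta -= 0.5
        for i in range(k + 1, d):
            partial[k, i] = 2.0 * rng.beta(beta, beta) - 1.0
            rho = partial[k, i]
            for ell in range(k - 1, -1, -1):
                rho = (
                    rho * np.sqrt((1 - partial[ell, i] ** 2) * (1 - partial[ell, k] ** 2))
                    + partial[ell, i] * partial[ell, k]
                )
            S[k, i] = S[i, k] = rho
    return S


def simulate_studies(
    net: TrueNetwork,
    re_cov: np.ndarray,
    k: int,
    n_range: tuple[int, int] = (250, 1000),
    seed=None,
    max_tries: int = 200,
) -> list[CorrelationData]:
    """Simulate k studies: perturbed population correlations, then sample
    correlation matrices of standard-Gaussian draws."""
    rng = _rng(seed)
    p = net.p
    q = p * (p - 1) // 2
    re_cov = np.asarray(re_cov, dtype=float)
    if re_cov.shape != (q, q):
        raise ValueError(f"re_cov must be {q}x{q}")
    rho_true = vechs(net.P)
    rows, cols = vechs_indices(p)
    re_chol = None
    if np.any(re_cov):
        re_chol = np.linalg.cholesky(re_cov + 1e-12 * np.eye(q))

    datasets = []
    for i in range(k):
        for attempt in range(max_tries):
            rho_i = rho_true.copy()
            if re_chol is not None:
                rho_i = rho_i + re_chol @ rng.standard_normal(q)
            P_i = np.eye(p)
            P_i[rows, cols] = rho_i
            P_i[cols, rows] = rho_i
            if np.all(np.abs(rho_i) < 1) and np.linalg.eigvalsh(P_i).min() > 1e-8:
                break
        else:
            raise RuntimeError(
                "could not draw a positive definite study correlation matrix; "
                "use a smaller random-effect standard deviation"
            )
        n_i = int(rng.integers(n_range[0], n_range[1] + 1))
        Y = rng.standard_normal((n_i, p)) @ np.linalg.cholesky(P_i).T
        R_i = np.corrcoef(Y, rowvar=False)
        R_i = (R_i + R_i.T) / 2.0
        np.fill_diagonal(R_i, 1.0)
        datasets.append(CorrelationData(R=R_i, n=n_i, study_id=f"study{i + 1}"))
    return datasets


def evaluate(
    net: TrueNetwork,
    Omega_est: np.ndarray,
    true_re_sd: float | None = None,
    est_re_sd: np.ndarray | None = None,
) -> dict:
    """Edge-recovery metrics of an estimated network against the truth.

    sensitivity = TP / (TP + FN), specificity = TN / (TN + FP), and the
    Pearson correlation between absolute true and estimated weights over all
    potential edges.  ``re_bias`` is the mean absolute deviation between
    estimated and true random-effect standard deviations.
    """
    true_w = vechs(net.Omega_true)
    est_w = vechs(np.asarray(Omega_est))
    if true_w.size != est_w.size:
        raise ValueError("dimension mismatch between true and estimated networks")
    true_edge = true_w != 0
    est_edge = est_w != 0

    tp = int(np.sum(true_edge & est_edge))
    fn = int(np.sum(true_edge & ~est_edge))
    tn = int(np.sum(~true_edge & ~est_edge))
    fp = int(np.sum(~true_edge & est_edge))

    sensitivity = tp / (tp + fn) if (tp + fn) else np.nan
    specificity = tn / (tn + fp) if (tn + fp) else np.nan
    a, b = np.abs(true_w), np.abs(est_w)
    if a.std() > 0 and b.std() > 0:
        correlation = float(np.corrcoef(a, b)[0, 1])
    else:
        correlation = np.nan
    out = {
        "sensitivity": sensitivity,
        "specificity": specificity,
        "correlation": correlation,
    }
    if true_re_sd is not None and est_re_sd is not None:
        out["re_bias"] = float(np.mean(np.abs(np.asarray(est_re_sd) - true_re_sd)))
    return out


@dataclass
class SimulationCondition:
    """One cell of the simulation design."""

    p: int = 8
    k: int = 8
    re_sd: float = 0.0
    n_range: tuple[int, int] = (250, 1000)
    methods: tuple[str, ...] = ("fixed_two_stage",)
    reps: int = 100
    seed: int = 0
    alpha: float = 0.05


def _fit_method(method: str, datasets, net: TrueNetwork, alpha: float):
    """Run one estimation method; returns (Omega_est, est_re_sd or None)."""
    from . import multigroup, random_effects

    if method == "fixed_two_stage":
        fit = multigroup.two_stage_fixed(datasets, alpha=alpha)
        return multigroup.omega_from_fit(fit), None
    if method == "fixed_multidataset":
        fit = multigroup.multidataset_ggm(datasets, "pooled", alpha=alpha)
        return multigroup.omega_from_fit(fit), None
    if method.startswith("re_"):
        _, sampling, estimation = method.split("_", 2)
        rows, _ = random_effects.build_rows(datasets)
        scov = random_effects.estimate_sampling_cov(datasets, method=sampling)
        re_fit = random_effects.fit_random_effects(
            rows, scov, estimation=estimation
        )
        re_fit = random_effects.prune_random_effects(re_fit, alpha=alpha)
        return re_fit.Omega_hat, re_fit.re_sd
    raise ValueError(f"unknown method {method!r}")


def run_study(condition: SimulationCondition) -> pd.DataFrame:
    """Run all replications of a condition; returns a long results table.

    Per-replication fit failures are recorded (``error`` column) rather than
    raised, so a single degenerate draw does not abort a study.
    """
    records = []
    ss = np.random.SeedSequence(condition.seed)
    children = ss.spawn(condition.reps)
    q = condition.p * (condition.p - 1) // 2
    for rep, child in enumerate(children):
        rng = np.random.default_rng(child)
        net = generate_true_network(condition.p, seed=rng)
        re_cov = generate_re_cov(q, condition.re_sd, seed=rng)
        datasets = simulate_studies(
            net, re_cov, condition.k, condition.n_range, seed=rng
        )
        for method in condition.methods:
            rec = {
                "rep": rep,
                "method": method,
                "p": condition.p,
                "k": condition.k,
                "re_sd": condition.re_sd,
                "error": "",
            }
            try:
                Omega_est, est_re_sd = _fit_method(
                    method, datasets, net, condition.alpha
                )
                metrics = evaluate(
                    net,
                    Omega_est,
                    true_re_sd=condition.re_sd if est_re_sd is not None else None,
                    est_re_sd=est_re_sd,
                )
                rec.update(metrics)
            except Exception as exc:  # noqa: BLE001 - recorded, not fatal
                rec.update(
                    {"sensitivity": np.nan, "specificity": np.nan,
                     "correlation": np.nan, "error": f"{type(exc).__name__}: {exc}"}
                )
            records.append(rec)
    return pd.DataFrame.from_records(records)
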