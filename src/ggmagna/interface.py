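"""File I/O, manifests, and the command-line interface.

Correlation matrices are square numeric CSV files with a header row and an
index column of variable labels.  A YAML manifest lists the studies (path,
sample size, optional variable subset) and an analysis block selecting the
mode and its options.  Results are written as plain CSV/JSON: an edge list,
per-group weight matrices, fit indices, random-effect standard deviations,
and a machine-readable run log echoing seed and configuration.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import click
import numpy as np
import pandas as pd
import yaml

from .fit_engine import FitResult
from .gaussian_family import CorrelationData
from .matcalc import vechs_indices

__all__ = [
    "Manifest",
    "read_correlation_csv",
    "read_raw_csv",
    "load_manifest",
    "write_results",
    "cli",
]

MODES = ("single", "fixed_two_stage", "fixed_multidataset", "partial_prune",
         "random_effects")


@dataclass
class Manifest:
    studies: list[dict]
    mode: str = "single"
    alpha: float = 0.05
    method: str = "two_stage"          # fixed-effects variant
    sampling: str = "pooled"           # random-effects V construction
    estimation: str = "averaged"       # random-effects likelihood evaluation
    seed: int = 0
    output_dir: str = "results"
    extra: dict = field(default_factory=dict)

    def load_datasets(self, base: Path | None = None) -> list[CorrelationData]:
        base = Path(base) if base is not None else Path(".")
        datasets = []
        for s in self.studies:
            path = Path(s["path"])
            if not path.is_absolute():
                path = base / path
            if not path.exists():
                raise FileNotFoundError(f"study file not found: {path}")
            if s.get("raw"):
                data = read_raw_csv(path)
            else:
                if "n" not in s:
                    raise ValueError(
                        f"study {s.get('study_id', path.name)}: correlation input "
                        "requires a sample size 'n'"
                    )
                n = int(s["n"])
                if n <= 0:
                    raise ValueError("sample sizes must be positive integers")
                data = read_correlation_csv(path, n=n)
            data.study_id = str(s.get("study_id", path.stem))
            subset = s.get("variables")
            if subset:
                idx = [data.labels.index(v) for v in subset]
                data = CorrelationData(
                    R=data.R[np.ix_(idx, idx)], n=data.n,
                    labels=[data.labels[i] for i in idx], study_id=data.study_id,
                )
            datasets.append(data)
        return datasets


def load_manifest(path: str | Path) -> Manifest:
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    analysis = raw.get("analysis", {})
    mode = analysis.get("mode", "single")
    if mode not in MODES:
        raise ValueError(f"unknown analysis mode {mode!r}; choose from {MODES}")
    known = {"mode", "alpha", "method", "sampling", "estimation", "seed",
             "output_dir"}
    return Manifest(
        studies=raw["studies"],
        mode=mode,
        alpha=float(analysis.get("alpha", 0.05)),
        method=analysis.get("method", "two_stage"),
        sampling=analysis.get("sampling", "pooled"),
        estimation=analysis.get("estimation", "averaged"),
        seed=int(analysis.get("seed", 0)),
        output_dir=analysis.get("output_dir", "results"),
        extra={k: v for k, v in analysis.items() if k not in known},
    )


def read_correlation_csv(path: str | Path, n: int) -> CorrelationData:
    """Read a labeled square correlation matrix; symmetrize with a warning
    if asymmetric beyond 1e-6."""
    df = pd.read_csv(path, index_col=0)
    M = df.to_numpy(dtype=float)
    if M.shape[0] != M.shape[1]:
        raise ValueError(
            f"{path}: correlation matrix must be square, got {M.shape}"
        )
    labels = [str(c).strip() for c in df.columns]
    row_labels = [str(r).strip() for r in df.index]
    if row_labels != labels:
        raise ValueError(f"{path}: row labels do not match column labels")
    asym = float(np.max(np.abs(M - M.T))) if M.size else 0.0
    if asym > 1e-6:
        warnings.warn(f"{path}: asymmetry {asym:.2e}; symmetrizing", stacklevel=2)
    M = (M + M.T) / 2.0
    diag_err = float(np.max(np.abs(np.diag(M) - 1.0)))
    if diag_err > 1e-6:
        warnings.warn(
            f"{path}: diagonal deviates from 1 by {diag_err:.2e}; rescaling",
            stacklevel=2,
        )
    np.fill_diagonal(M, 1.0)
    return CorrelationData(R=M, n=n, labels=labels)


def read_raw_csv(path: str | Path) -> CorrelationData:
    """Read a raw data table (rows = cases) and compute correlations with
    the 1/n convention after standardizing each column."""
    df = pd.read_csv(path)
    if df.isna().any().any():
        raise ValueError(
            f"{path}: missing cells are not supported for raw input; supply a "
            "correlation matrix (with its sample size) instead"
        )
    Y = df.to_numpy(dtype=float)
    n = Y.shape[0]
    Y = Y - Y.mean(axis=0)
    sd = np.sqrt((Y**2).mean(axis=0))
    if np.any(sd == 0):
        raise ValueError(f"{path}: constant column(s) have no correlation")
    Y = Y / sd
    R = (Y.T @ Y) / n
    R = (R + R.T) / 2.0
    np.fill_diagonal(R, 1.0)
    return CorrelationData(R=R, n=n, labels=[str(c) for c in df.columns])


# ---------------------------------------------------------------------------
# result writing
# ---------------------------------------------------------------------------

def _edge_list(fit: FitResult, labels: list[str]) -> pd.DataFrame:
    from .multigroup import omega_from_fit

    spec = fit.spec
    p = spec.meta["p"]
    k = spec.meta.get("k", 1)
    theta = spec.theta(fit.psi_hat)
    q = p * (p - 1) // 2
    n_blocks = theta.size // q
    rows, cols = vechs_indices(p)
    table = spec.table.as_frame(fit)
    records = []
    for g in range(n_blocks):
        block = table.iloc[g * q : (g + 1) * q]
        for e in range(q):
            w = float(block["estimate"].iloc[e]) if "estimate" in block else 0.0
            records.append(
                {
                    "node_i": labels[rows[e]],
                    "node_j": labels[cols[e]],
                    "group": g,
                    "weight": w,
                    "se": block["se"].iloc[e] if "se" in block else np.nan,
                    "p_value": block["p_value"].iloc[e] if "p_value" in block else np.nan,
                    "included": bool(w != 0),
                }
            )
    return pd.DataFrame.from_records(records)


def write_results(
    fit: FitResult,
    out_dir: str | Path,
    labels: list[str] | None = None,
    re_sd: np.ndarray | None = None,
    config: dict | None = None,
) -> list[Path]:
    """Write edge list, weight matrices, fit indices and a run log."""
    from .multigroup import omega_from_fit

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = fit.spec
    p = spec.meta["p"]
    labels = labels or spec.meta.get("labels") or [f"V{i+1}" for i in range(p)]
    written = []

    edges = _edge_list(fit, labels)
    path = out / "edges.csv"
    edges.to_csv(path, index=False)
    written.append(path)

    theta = spec.theta(fit.psi_hat)
    q = p * (p - 1) // 2
    for g in range(theta.size // q):
        Om = omega_from_fit(fit, group=g) if theta.size > q else omega_from_fit(fit)
        path = out / f"weights_group{g}.csv"
        pd.DataFrame(Om, index=labels, columns=labels).to_csv(path)
        written.append(path)

    indices = {
        "chi2": fit.chi2, "df": fit.df, "aic": fit.aic, "bic": fit.bic,
        "rmsea": fit.rmsea, "F_hat": fit.F_hat, "n_free": fit.n_free,
        "converged": bool(fit.converged), "gradient_norm": fit.gradient_norm,
        "iterations": fit.iterations,
    }
    path = out / "fit_indices.json"
    path.write_text(json.dumps(indices, indent=2, default=_json_default))
    written.append(path)

    if re_sd is not None:
        rows, cols = vechs_indices(p)
        df = pd.DataFrame(
            {
                "node_i": [labels[i] for i in rows],
                "node_j": [labels[j] for j in cols],
                "re_sd": re_sd,
            }
        )
        path = out / "re_sd.csv"
        df.to_csv(path, index=False)
        written.append(path)

    log = {"config": config or {}, "fit": indices}
    path = out / "run_log.json"
    path.write_text(json.dumps(log, indent=2, default=_json_default))
    written.append(path)
    return written


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

@click.group()
def cli() -> None:
    """Network models from correlation matrices, single study or pooled."""


def _run_manifest(manifest_path: str, mode_override: str | None = None, **overrides):
    from . import multigroup, random_effects

    m = load_manifest(manifest_path)
    if mode_override:
        m.mode = mode_override
    for key, val in overrides.items():
        if val is not None:
            setattr(m, key, val)
    datasets = m.load_datasets(Path(manifest_path).parent)
    labels = datasets[0].labels
    config = {"mode": m.mode, "alpha": m.alpha, "seed": m.seed,
              "studies": [d.study_id for d in datasets]}

    if m.mode == "single":
        if len(datasets) != 1:
            raise click.UsageError("mode 'single' requires exactly one study")
        fit = multigroup.multidataset_ggm(datasets, "unique", alpha=m.alpha)
        return write_results(fit, m.output_dir, labels, config=config)
    if m.mode == "fixed_two_stage":
        fit = multigroup.two_stage_fixed(datasets, alpha=m.alpha)
        return write_results(fit, m.output_dir, labels, config=config)
    if m.mode == "fixed_multidataset":
        fit = multigroup.multidataset_ggm(datasets, "pooled", alpha=m.alpha)
        return write_results(fit, m.output_dir, labels, config=config)
    if m.mode == "partial_prune":
        result = multigroup.partial_prune(datasets, alpha=m.alpha)
        paths = write_results(result.fit, m.output_dir, labels, config=config)
        status_path = Path(m.output_dir) / "edge_status.csv"
        result.summary().to_csv(status_path, index=False)
        return paths + [status_path]
    if m.mode == "random_effects":
        rows, _ = random_effects.build_rows(datasets)
        scov = random_effects.estimate_sampling_cov(datasets, method=m.sampling)
        re_fit = random_effects.fit_random_effects(
            rows, scov, estimation=m.estimation
        )
        re_fit = random_effects.prune_random_effects(re_fit, alpha=m.alpha)
        config.update(re_fit.variant)
        return write_results(
            re_fit.fit, m.output_dir, labels, re_sd=re_fit.re_sd, config=config
        )
    raise click.UsageError(f"unknown mode {m.mode}")


@cli.command()
@click.option("--manifest", required=True, type=click.Path(exists=True))
@click.option("--alpha", type=float, default=None)
def fit(manifest: str, alpha: float | None) -> None:
    """Single-dataset network estimation with significance pruning."""
    paths = _run_manifest(manifest, "single", alpha=alpha)
    click.echo("\n".join(str(p) for p in paths))


@cli.command()
@click.option("--manifest", required=True, type=click.Path(exists=True))
@click.option("--method", type=click.Choice(["two_stage", "multidataset"]),
              default=None)
@click.option("--alpha", type=float, default=None)
def fixed(manifest: str, method: str | None, alpha: float | None) -> None:
    """Fixed-effects pooled network over several datasets."""
    m = load_manifest(manifest)
    method = method or m.method
    mode = "fixed_two_stage" if method == "two_stage" else "fixed_multidataset"
    paths = _run_manifest(manifest, mode, alpha=alpha)
    click.echo("\n".join(str(p) for p in paths))


@cli.command()
@click.option("--manifest", required=True, type=click.Path(exists=True))
@click.option("--sampling", type=click.Choice(["individual", "pooled"]), default=None)
@click.option("--estimation", type=click.Choice(["averaged", "per_study"]),
              default=None)
@click.option("--alpha", type=float, default=None)
def random(manifest: str, sampling, estimation, alpha) -> None:
    """Random-effects pooled network with heterogeneity estimates."""
    paths = _run_manifest(
        manifest, "random_effects", sampling=sampling, estimation=estimation,
        alpha=alpha,
    )
    click.echo("\n".join(str(p) for p in paths))


@cli.command()
@click.option("--manifest", required=True, type=click.Path(exists=True))
@click.option("--alpha", type=float, default=None)
def partialprune(manifest: str, alpha: float | None) -> None:
    """Search for a partially invariant network across datasets."""
    paths = _run_manifest(manifest, "partial_prune", alpha=alpha)
    click.echo("\n".join(str(p) for p in paths))


@cli.command()
@click.option("--nodes", type=int, default=8, show_default=True)
@click.option("--k", type=int, default=8, show_default=True)
@click.option("--re-sd", type=float, default=0.0, show_default=True)
@click.option("--reps", type=int, default=10, show_default=True)
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--methods", default="fixed_two_stage", show_default=True,
              help="comma-separated method tags")
@click.option("--out", type=click.Path(), default="simulation.csv",
              show_default=True)
def simulate(nodes, k, re_sd, reps, seed, methods, out) -> None:
    """Run a network-recovery simulation and write a long results table."""
    from .netsim import METHODS, SimulationCondition, run_study

    tags = tuple(t.strip() for t in methods.split(",") if t.strip())
    for t in tags:
        if t not in METHODS:
            raise click.UsageError(f"unknown method {t!r}; choose from {METHODS}")
    condition = SimulationCondition(
        p=nodes, k=k, re_sd=re_sd, reps=reps, seed=seed, methods=tags
    )
    table = run_study(condition)
    table.to_csv(out, index=False)
    click.echo(out)
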