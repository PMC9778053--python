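"""Scenario-grid benchmark driver: simulate, fit every method, score.

Reproduces the simulation-study layout: a grid of polygenic-background
multipliers x sample sizes, each cell replicated with seeds derived
deterministically (and order-independently) from a master seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .baselines import MixtureConfig, fit_emba, fit_embc, fit_emml, fit_emrr
from .em_core import EMFit, PriorConfig, fit_embai, predict_gebv
from .exceptions import DataError
from .kinship import KinshipMatrix, compute_grm
from .metrics import coefficient_auc, mae, mse, pearson_r
from .simdata import (
    SimulatedDataset,
    make_scenario_multi_qtn,
    make_scenario_one_qtn,
    simulate_genotypes,
    simulate_phenotype,
)
from .varcomp import apply_whitening, build_whitening, estimate_lambda_g

__all__ = ["BenchmarkGrid", "replicate_seed", "simulate_replicate", "fit_method", "run_benchmark"]

logger = logging.getLogger(__name__)

EXPERIMENTS = ("one-qtn", "multi-qtn")
KNOWN_METHODS = ("emBAI", "emBA", "emRR", "emML", "emBC")


@dataclass(frozen=True)
class BenchmarkGrid:
    """One simulation experiment over sample sizes x background multipliers."""

    experiment: str
    sample_sizes: tuple[int, ...] = (500, 1000, 2000)
    background_multipliers: tuple[float, ...] = (2.0, 5.0, 10.0)
    n_replicates: int = 100
    q: int = 10_000

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise DataError(f"experiment must be one of {EXPERIMENTS}")
        if not self.sample_sizes or not self.background_multipliers:
            raise DataError("grid must be non-empty")
        if self.n_replicates < 1:
            raise DataError("n_replicates must be >= 1")


def replicate_seed(master_seed: int, experiment: str, n: int, m: float, rep: int) -> int:
    """Deterministic per-replicate seed, independent of grid iteration order."""
    ss = np.random.SeedSequence(
        [int(master_seed), EXPERIMENTS.index(experiment), int(n), int(round(m * 1000)), int(rep)]
    )
    return int(ss.generate_state(1, np.uint32)[0] & 0x7FFFFFFF)


def simulate_replicate(
    experiment: str, n: int, q: int, m: float, seed: int
) -> tuple[SimulatedDataset, KinshipMatrix]:
    """One dataset: HWE genotypes, VanRaden GRM, QTN scenario, phenotype."""
    ss_geno, ss_scen = np.random.SeedSequence(seed).spawn(2)
    geno_seed = int(ss_geno.generate_state(1, np.uint32)[0] & 0x7FFFFFFF)
    scen_seed = int(ss_scen.generate_state(1, np.uint32)[0] & 0x7FFFFFFF)
    genotypes = simulate_genotypes(n, q, 0.1, 0.5, seed=geno_seed)
    K = compute_grm(genotypes)
    if experiment == "one-qtn":
        scenario = make_scenario_one_qtn(genotypes, m, seed=scen_seed)
    else:
        scenario = make_scenario_multi_qtn(genotypes, m, seed=scen_seed)
    return simulate_phenotype(genotypes, scenario, K), K


def fit_method(
    method: str,
    dataset: SimulatedDataset,
    K: KinshipMatrix | None = None,
    prior: PriorConfig | None = None,
    mix: MixtureConfig | None = None,
    whiten: bool = False,
) -> EMFit:
    """Dispatch one method on a simulated dataset (intercept-only design).

    ``whiten=True`` pre-applies the stage-1 transform before a baseline fit
    (the background-control variant); emBAI whitens internally by definition.
    """
    y = dataset.phenotype
    n = y.size
    W = np.ones((n, 1))
    Z = dataset.genotypes
    if method == "emBAI":
        if K is None:
            raise DataError("emBAI requires a kinship matrix")
        return fit_embai(y, W, Z, K, prior)
    Zm = Z.dosages
    if whiten:
        if K is None:
            raise DataError("whitening requires a kinship matrix")
        eig = np.linalg.eigh(K.values)
        lam = estimate_lambda_g(y, W, K, eig=eig).lambda_g
        op = build_whitening(K, lam, eig=eig)
        wd = apply_whitening(op, y, W, Zm)
        y, W, Zm = wd.y_c, wd.W_c, wd.Z_c
    if method == "emBA":
        return fit_emba(y, W, Zm, prior)
    if method == "emRR":
        return fit_emrr(y, W, Zm, prior)
    if method == "emML":
        return fit_emml(y, W, Zm, prior)
    if method == "emBC":
        return fit_embc(y, W, Zm, prior, mix)
    raise DataError(f"unknown method {method!r} (choose from {KNOWN_METHODS})")


def score_fit(fit: EMFit, dataset: SimulatedDataset) -> dict:
    pred = predict_gebv(fit, dataset.genotypes, np.ones((dataset.phenotype.size, 1)))
    y = dataset.phenotype
    return {
        "mse": mse(y, pred.fitted),
        "mae": mae(y, pred.fitted),
        "pearson_r": pearson_r(y, pred.gebv),
        "auc": coefficient_auc(fit.gamma, dataset.truth.qtn_indices),
        "n_iter": fit.n_iter,
        "converged": bool(fit.converged),
        "lambda_g_hat": fit.lambda_g if fit.lambda_g is not None else np.nan,
    }


def run_benchmark(
    grid: BenchmarkGrid,
    methods,
    master_seed: int,
    prior: PriorConfig | None = None,
    mix: MixtureConfig | None = None,
    whiten_baselines: bool = False,
    progress=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the grid; returns (per-replicate table, per-cell aggregate table).

    Per-replicate failures are logged and excluded (counted in the aggregate
    ``n_failed`` column), never silently dropped.
    """
    unknown = [m for m in methods if m not in KNOWN_METHODS]
    if unknown:
        raise DataError(f"unknown methods {unknown}")
    rows = []
    n_failed = {}
    for n in grid.sample_sizes:
        for m in grid.background_multipliers:
            for rep in range(grid.n_replicates):
                seed = replicate_seed(master_seed, grid.experiment, n, m, rep)
                dataset, K = simulate_replicate(grid.experiment, n, grid.q, m, seed)
                for method in methods:
                    try:
                        fit = fit_method(method, dataset, K, prior, mix, whiten=whiten_baselines and method != "emBAI")
                        row = score_fit(fit, dataset)
                    except Exception:
                        logger.exception(
                            "replicate failed: %s n=%d m=%g rep=%d", method, n, m, rep
                        )
                        n_failed[(n, m, method)] = n_failed.get((n, m, method), 0) + 1
                        continue
                    row.update(
                        experiment=grid.experiment,
                        n=n,
                        background=m,
                        replicate=rep,
                        method=method,
                        seed=seed,
                    )
                    rows.append(row)
                    if progress is not None:
                        progress(row)
    if not rows:
        raise DataError("every replicate failed; see log")
    per_rep = pd.DataFrame(rows)
    metric_cols = ["mse", "mae", "pearson_r", "auc", "n_iter", "lambda_g_hat"]
    grouped = per_rep.groupby(["experiment", "n", "background", "method"], sort=True)
    agg = grouped[metric_cols].agg(["mean", "sem"])
    agg.columns = [f"{c}_{s}" for c, s in agg.columns]
    agg["n_reps"] = grouped.size()
    agg = agg.reset_index()
    agg["n_failed"] = [
        n_failed.get((r.n, r.background, r.method), 0) for r in agg.itertuples()
    ]
    return per_rep, agg
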