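"""File readers and writers: genotype CSV / PLINK RAW, phenotype TSV,
truth sidecars and fit reports.

Genotype CSV dialect: first column = individual id, header row = marker ids,
entries = allele dosages in {0, 1, 2} (missing allowed, imputed). PLINK RAW
dialect: whitespace-separated with the standard six leading columns
``FID IID PAT MAT SEX PHENOTYPE`` followed by ``<snp>_<allele>`` dosage
columns, ``NA`` for missing.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .em_core import EMFit, GEBVResult
from .exceptions import DataError
from .simdata import GenotypeMatrix, SimulationScenario

__all__ = [
    "read_genotypes",
    "write_genotypes_csv",
    "write_genotypes_plink_raw",
    "read_phenotypes",
    "write_phenotypes",
    "read_truth",
    "write_truth",
    "write_fit_report",
]

logger = logging.getLogger(__name__)

_PLINK_META = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
_MAX_MISSING = 0.2


def _impute_dosages(df: pd.DataFrame, path) -> tuple[np.ndarray, list[str]]:
    vals = df.to_numpy(dtype=np.float64)
    keep, ids = [], []
    n = vals.shape[0]
    n_imputed = 0
    for j, name in enumerate(df.columns):
        col = vals[:, j]
        miss = ~np.isfinite(col)
        if miss.mean() > _MAX_MISSING:
            logger.warning("dropping marker %s: %.0f%% missing", name, 100 * miss.mean())
            continue
        if miss.any():
            fill = float(np.round(col[~miss].mean()))
            col = np.where(miss, fill, col)
            n_imputed += int(miss.sum())
        bad = ~np.isin(col, (0.0, 1.0, 2.0))
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise DataError(
                f"{path}: marker {name} has non-dosage value {col[row]!r} at data row {row + 1}"
            )
        keep.append(col)
        ids.append(str(name))
    if n_imputed:
        logger.info("imputed %d missing dosages in %s", n_imputed, path)
    if not keep:
        raise DataError(f"{path}: no usable marker columns")
    return np.column_stack(keep), ids


def read_genotypes(path, format: str = "auto") -> GenotypeMatrix:
    """Read a dosage matrix from CSV or PLINK RAW.

    ``format='auto'`` sniffs the header: a leading ``FID IID`` pair selects the
    PLINK RAW dialect. Missing entries are imputed to the column-mean dosage
    (rounded); columns with more than 20% missing are dropped with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"genotype file not found: {path}")
    if format == "auto":
        with open(path) as fh:
            head = fh.readline().split()
        format = "plink_raw" if head[:2] == ["FID", "IID"] else "csv"
    if format == "plink_raw":
        try:
            df = pd.read_csv(path, sep=r"\s+", na_values=["NA"])
        except Exception as err:
            raise DataError(f"cannot parse PLINK RAW file {path}: {err}") from err
        missing_meta = [c for c in _PLINK_META if c not in df.columns]
        if missing_meta:
            raise DataError(f"{path}: PLINK RAW header lacks columns {missing_meta}")
        snp_cols = [c for c in df.columns if c not in _PLINK_META]
        body = df[snp_cols].apply(pd.to_numeric, errors="coerce")
        dos, ids = _impute_dosages(body, path)
        ids = [c.rsplit("_", 1)[0] for c in ids]
    elif format == "csv":
        try:
            df = pd.read_csv(path, index_col=0)
        except Exception as err:
            raise DataError(f"cannot parse genotype CSV {path}: {err}") from err
        body = df.apply(pd.to_numeric, errors="coerce")
        has_text = body.isna() & df.notna()
        if has_text.any().any():
            r, c = np.argwhere(has_text.to_numpy())[0]
            raise DataError(
                f"{path}: non-numeric dosage {df.iat[r, c]!r} at row {r + 2} "
                f"(marker {df.columns[c]})"
            )
        dos, ids = _impute_dosages(body, path)
    else:
        raise DataError(f"unknown genotype format {format!r}")
    return GenotypeMatrix(dosages=dos, marker_ids=tuple(ids))


def write_genotypes_csv(genotypes: GenotypeMatrix, path, ids=None) -> None:
    ids = list(ids) if ids is not None else [f"id{i + 1}" for i in range(genotypes.n)]
    pd.DataFrame(
        genotypes.dosages.astype(int), index=ids, columns=list(genotypes.marker_ids)
    ).to_csv(path, index_label="id")


def write_genotypes_plink_raw(genotypes: GenotypeMatrix, path, ids=None) -> None:
    ids = list(ids) if ids is not None else [f"id{i + 1}" for i in range(genotypes.n)]
    df = pd.DataFrame(
        genotypes.dosages.astype(int),
        columns=[f"{m}_A" for m in genotypes.marker_ids],
    )
    for col, val in zip(reversed(_PLINK_META), [-9, 0, 0, 0, ids, ids]):
        df.insert(0, col, val)
    df.to_csv(path, sep=" ", index=False)


def read_phenotypes(path) -> pd.Series:
    """Two-column TSV (id, value) -> Series indexed by id."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"phenotype file not found: {path}")
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as err:
        raise DataError(f"cannot parse phenotype file {path}: {err}") from err
    if df.shape[1] < 2:
        raise DataError(f"{path}: expected two tab-separated columns (id, value)")
    vals = pd.to_numeric(df.iloc[:, 1], errors="coerce")
    if vals.isna().any():
        row = int(vals.isna().idxmax())
        raise DataError(f"{path}: non-numeric phenotype at data row {row + 1}")
    return pd.Series(vals.to_numpy(float), index=df.iloc[:, 0].astype(str), name="phenotype")


def write_phenotypes(values, path, ids=None) -> None:
    values = np.asarray(values, float).ravel()
    ids = list(ids) if ids is not None else [f"id{i + 1}" for i in range(values.size)]
    pd.DataFrame({"id": ids, "phenotype": values}).to_csv(path, sep="\t", index=False)


def write_truth(scenario: SimulationScenario, path) -> None:
    with open(path, "w") as fh:
        json.dump(scenario.to_dict(), fh, indent=2)


def read_truth(path) -> SimulationScenario:
    with open(path) as fh:
        return SimulationScenario(**json.load(fh))


def write_fit_report(
    fit: EMFit,
    marker_ids,
    outdir,
    gebv: GEBVResult | None = None,
    individual_ids=None,
    config_echo: dict | None = None,
) -> None:
    """Serialize one fit: effects.tsv, gebv.tsv (optional) and run_meta.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "marker_id": list(marker_ids),
            "gamma_hat": fit.gamma,
            "sigma_k2_hat": fit.sigma_k2,
        }
    ).to_csv(outdir / "effects.tsv", sep="\t", index=False)
    if gebv is not None:
        ids = (
            list(individual_ids)
            if individual_ids is not None
            else [f"id{i + 1}" for i in range(gebv.gebv.size)]
        )
        pd.DataFrame({"id": ids, "gebv": gebv.gebv, "fitted": gebv.fitted}).to_csv(
            outdir / "gebv.tsv", sep="\t", index=False
        )
    meta = {
        "method": fit.method_tag,
        "lambda_g_hat": fit.lambda_g,
        "sigma2_hat": fit.sigma2,
        "n_iter": fit.n_iter,
        "converged": bool(fit.converged),
        "alpha_hat": list(map(float, np.atleast_1d(fit.alpha))),
        "log_posterior_final": float(fit.log_posterior_trace[-1])
        if len(fit.log_posterior_trace)
        else None,
        "config": config_echo or {},
    }
    with open(outdir / "run_meta.json", "w") as fh:
        json.dump(meta, fh, indent=2)
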