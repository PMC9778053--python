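"""Genomic relationship matrix (GRM) construction and kinship file I/O.

The default kinship is the VanRaden method-1 GRM: columns of the dosage matrix
are centered by twice their allele frequency and the cross-product is scaled by
``2 * sum_k p_k (1 - p_k)``, giving a matrix whose diagonal averages ~1 under
HWE. The GRM is positive semi-definite by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DataError
from .simdata import GenotypeMatrix

__all__ = ["KinshipMatrix", "compute_grm", "read_kinship", "write_kinship"]

logger = logging.getLogger(__name__)

_SYM_TOL = 1e-10


@dataclass(frozen=True)
class KinshipMatrix:
    """Symmetric n x n relatedness matrix K for the polygenic term."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise DataError(f"kinship must be square, got shape {v.shape}")
        if not np.isfinite(v).all():
            raise DataError("kinship contains non-finite entries")
        if np.abs(v - v.T).max() > _SYM_TOL:
            raise DataError("kinship is not symmetric (tolerance 1e-10)")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def check_psd(self, rel_tol: float = 1e-8) -> None:
        """Raise unless the smallest eigenvalue is >= -rel_tol * largest."""
        w = np.linalg.eigvalsh(self.values)
        if w[0] < -rel_tol * max(w[-1], 1e-300):
            raise DataError(
                f"kinship is not positive semi-definite (min eigenvalue {w[0]:.3g})"
            )


def compute_grm(genotypes: GenotypeMatrix) -> KinshipMatrix:
    """VanRaden method-1 GRM from allele dosages.

    K = M M' / (2 sum_k p_k (1 - p_k)) with M the column-centered dosages.
    Monomorphic markers are rejected (they carry no relatedness information
    and would not affect the numerator while still requiring a frequency).
    """
    p = genotypes.allele_freq
    mono = np.flatnonzero((p <= 0.0) | (p >= 1.0))
    if mono.size:
        names = ", ".join(genotypes.marker_ids[k] for k in mono[:5])
        raise DataError(f"monomorphic marker column(s): {names}")
    M = genotypes.dosages - 2.0 * p
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    K = (M @ M.T) / denom
    K = (K + K.T) / 2.0  # exact symmetry despite BLAS rounding
    return KinshipMatrix(values=K)


def read_kinship(path) -> KinshipMatrix:
    """Read a square numeric CSV (optional header row / label column).

    Mild asymmetry (beyond 1e-10) is repaired by (K + K') / 2 with a warning;
    non-square or non-numeric content raises :class:`DataError`.
    """
    try:
        with open(path) as fh:
            first_line = fh.readline()
        tokens = [t.strip() for t in first_line.strip().split(",")]
        has_labels = any(t and not _is_number(t) for t in tokens) or tokens[0] == ""
        if has_labels:
            df = pd.read_csv(path, header=0, index_col=0)
        else:
            df = pd.read_csv(path, header=None)
    except DataError:
        raise
    except Exception as err:
        raise DataError(f"cannot parse kinship file {path}: {err}") from err
    try:
        v = df.to_numpy(dtype=np.float64)
    except (TypeError, ValueError) as err:
        raise DataError(f"non-numeric entries in kinship file {path}") from err
    if v.ndim != 2 or v.shape[0] != v.shape[1]:
        raise DataError(f"kinship file {path} is not square: shape {v.shape}")
    asym = np.abs(v - v.T).max()
    if asym > _SYM_TOL:
        logger.warning(
            "kinship file %s asymmetric by %.3g; symmetrizing as (K + K')/2", path, asym
        )
        v = (v + v.T) / 2.0
    return KinshipMatrix(values=v)


def write_kinship(kinship: KinshipMatrix, path, ids=None) -> None:
    n = kinship.n
    ids = list(ids) if ids is not None else [f"id{i + 1}" for i in range(n)]
    pd.DataFrame(kinship.values, index=ids, columns=ids).to_csv(path)


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False
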