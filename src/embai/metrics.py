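"""Evaluation indicators: MSE, MAE, Pearson r, and coefficient AUC.

AUC scores each marker by |gamma_hat| against binary labels marking the true
QTN positions, via the rank statistic (Mann-Whitney form, ties averaged), and
therefore measures how well a method ranks causal markers above noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

from .exceptions import DataError

__all__ = ["MetricsReport", "mse", "mae", "pearson_r", "coefficient_auc", "evaluate_fit"]


@dataclass(frozen=True)
class MetricsReport:
    mse: float
    mae: float
    pearson_r: float
    auc: float | None
    n_pos: int = 0

    def __post_init__(self) -> None:
        if self.mse < 0 or self.mae < 0:
            raise DataError("MSE/MAE must be non-negative")
        if not -1.0 - 1e-12 <= self.pearson_r <= 1.0 + 1e-12:
            raise DataError("pearson_r outside [-1, 1]")
        if self.auc is not None and not 0.0 <= self.auc <= 1.0:
            raise DataError("auc outside [0, 1]")


def _pair(y, y_hat):
    y = np.asarray(y, float).ravel()
    y_hat = np.asarray(y_hat, float).ravel()
    if y.size == 0 or y.size != y_hat.size:
        raise DataError(f"length mismatch: {y.size} vs {y_hat.size}")
    return y, y_hat


def mse(y, y_hat) -> float:
    """Mean squared difference."""
    y, y_hat = _pair(y, y_hat)
    return float(np.mean((y - y_hat) ** 2))


def mae(y, y_hat) -> float:
    """Mean absolute difference."""
    y, y_hat = _pair(y, y_hat)
    return float(np.mean(np.abs(y - y_hat)))


def pearson_r(y, y_hat) -> float:
    """Sample Pearson correlation (n-1 normalized standard deviations)."""
    y, y_hat = _pair(y, y_hat)
    if y.size < 2:
        raise DataError("need at least two observations")
    dy = y - y.mean()
    dz = y_hat - y_hat.mean()
    sy = float(dy @ dy)
    sz = float(dz @ dz)
    if sy == 0.0 or sz == 0.0:
        raise DataError("correlation undefined for a constant vector")
    return float(dy @ dz / np.sqrt(sy * sz))


def coefficient_auc(gamma_hat, qtn_indices) -> float:
    """AUC of |gamma_hat| for recovering the true QTN positions.

    Labels are 1 at the (1-based) QTN indices and 0 elsewhere; computed by the
    rank statistic with ties averaged, i.e. P(score_pos > score_neg) +
    0.5 P(tie) over all positive/negative marker pairs.
    """
    gamma_hat = np.asarray(gamma_hat, float).ravel()
    q = gamma_hat.size
    idx = np.asarray(list(qtn_indices), dtype=int)
    if idx.size == 0 or idx.size >= q:
        raise DataError("AUC needs at least one positive and one negative marker")
    if idx.min() < 1 or idx.max() > q:
        raise DataError(f"QTN indices must lie in [1, {q}]")
    labels = np.zeros(q, dtype=int)
    labels[idx - 1] = 1
    return float(roc_auc_score(labels, np.abs(gamma_hat)))


def evaluate_fit(phenotype, fitted, gebv, gamma_hat=None, qtn_indices=None) -> MetricsReport:
    """Bundle the four indicators for one fitted method.

    Correlation is between phenotype and GEBV (marker-predicted genetic
    merit), MSE/MAE are in-sample prediction errors of the fitted phenotype,
    and AUC (when the true QTN positions are known) ranks marker-effect
    magnitudes against them.
    """
    auc = None
    n_pos = 0
    if qtn_indices is not None and gamma_hat is not None:
        auc = coefficient_auc(gamma_hat, qtn_indices)
        n_pos = len(list(qtn_indices))
    return MetricsReport(
        mse=mse(phenotype, fitted),
        mae=mae(phenotype, fitted),
        pearson_r=pearson_r(phenotype, gebv),
        auc=auc,
        n_pos=n_pos,
    )
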