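"""Stage 1: variance-ratio estimation and polygenic/residual whitening.

Under the mixed model ``y = W a + Z g + u + eps`` with ``u ~ MVN(0, sigma_g^2 K)``
and ``eps ~ N(0, sigma^2 I)``, the marginal covariance of y (markers treated as
noise, lambda_gamma = 0) is ``sigma^2 (lambda_g K + I)`` with
``lambda_g = sigma_g^2 / sigma^2``.

This module

1. estimates lambda_g by REML on the reduced model (no marker terms), using the
   eigenbasis of K so each candidate lambda costs O(n) after one
   decomposition (the EMMA device), and
2. builds the symmetric inverse square root ``C = Q L^{-1/2} Q'`` of
   ``B = lambda_g K + I`` and applies it to (y, W, Z), after which the combined
   polygenic + residual noise is homoscedastic: Cov(C(u + eps)) = sigma^2 I.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .exceptions import DataError
from .kinship import KinshipMatrix
from .simdata import GenotypeMatrix

__all__ = [
    "VarianceRatios",
    "WhiteningOperator",
    "WhitenedData",
    "estimate_lambda_g",
    "build_whitening",
    "apply_whitening",
]

logger = logging.getLogger(__name__)

_LOG10_BOUNDS = (-5.0, 5.0)
_EIG_FLOOR = 1e-10


def grid_refined_minimum(obj, lo: float, hi: float, n_grid: int = 41):
    """Coarse grid scan followed by bounded Brent on the bracketing interval.

    The 1-D profiles optimized here can be multimodal or flat near the
    bounds, where Brent alone may stall; the grid locates the global basin
    first. Returns (x_min, f_min).
    """
    xs = np.linspace(lo, hi, n_grid)
    vals = [obj(x) for x in xs]
    i = int(np.argmin(vals))
    a = xs[max(i - 1, 0)]
    b = xs[min(i + 1, n_grid - 1)]
    res = minimize_scalar(obj, bounds=(a, b), method="bounded",
                          options={"xatol": 1e-8})
    if res.fun <= vals[i]:
        return float(res.x), float(res.fun)
    return float(xs[i]), float(vals[i])


@dataclass(frozen=True)
class VarianceRatios:
    """REML variance-ratio estimates from the reduced (marker-free) model."""

    lambda_g: float
    sigma2: float
    log_reml: float
    lambda_gamma: float = 0.0

    def __post_init__(self) -> None:
        if self.lambda_g < 0:
            raise DataError("lambda_g must be >= 0")
        if self.sigma2 <= 0:
            raise DataError("sigma2 must be positive")


@dataclass(frozen=True)
class WhiteningOperator:
    """Spectral inverse square root of B = lambda_g K + I."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    transform: np.ndarray
    lambda_g: float
    b_matrix_hash: str

    @property
    def n(self) -> int:
        return self.transform.shape[0]


@dataclass(frozen=True)
class WhitenedData:
    """(y, W, Z) after pre-multiplication by the whitening transform C."""

    y_c: np.ndarray
    W_c: np.ndarray
    Z_c: np.ndarray

    @property
    def n(self) -> int:
        return self.y_c.shape[0]

    @property
    def c(self) -> int:
        return self.W_c.shape[1]

    @property
    def q(self) -> int:
        return self.Z_c.shape[1]


def _reml_neg2_profile(log10_lam: float, d, yt, Wt, n: int, c: int) -> float:
    """-2 x restricted log-likelihood (up to constants) at lambda = 10**log10_lam.

    d are the eigenvalues of K; yt, Wt the phenotype/design rotated into K's
    eigenbasis. The GLS fit and all determinants are O(n c^2).
    """
    lam = 10.0 ** log10_lam
    v = lam * d + 1.0
    Wv = Wt / v[:, None]
    WtVinvW = Wt.T @ Wv
    WtVinvY = Wv.T @ yt
    try:
        alpha = np.linalg.solve(WtVinvW, WtVinvY)
    except np.linalg.LinAlgError as err:
        raise DataError("fixed-effect design is rank deficient") from err
    r = yt - Wt @ alpha
    rss = float(np.sum(r * r / v))
    sign, logdet_w = np.linalg.slogdet(WtVinvW)
    if sign <= 0:
        raise DataError("fixed-effect design is rank deficient")
    return (n - c) * np.log(rss) + float(np.sum(np.log(v))) + logdet_w


def _reml_loglik(neg2_profile: float, n: int, c: int) -> float:
    # full restricted log-likelihood including constants, from the profile value
    nc = n - c
    return -0.5 * (neg2_profile - nc * np.log(nc) + nc * (1.0 + np.log(2.0 * np.pi)))


def estimate_lambda_g(
    y: np.ndarray,
    W: np.ndarray,
    K: KinshipMatrix,
    eig: tuple[np.ndarray, np.ndarray] | None = None,
) -> VarianceRatios:
    """REML estimate of lambda_g = sigma_g^2 / sigma^2 on the reduced model.

    Maximizes the restricted likelihood of ``y = W a + u + eps`` over
    log10(lambda_g) in [-5, 5] by bounded 1-D optimization after a single
    eigendecomposition of K; the boundary solution lambda_g = 0 is compared
    explicitly and reported when it wins. ``sigma2`` is the REML residual
    variance at the optimum.

    When K is (numerically) a multiple of the identity, lambda_g and sigma^2
    are not separately identifiable; the estimate is pinned at 0 with a
    warning.
    """
    y = np.asarray(y, dtype=np.float64).ravel()
    W = np.atleast_2d(np.asarray(W, dtype=np.float64))
    if W.shape[0] != y.size:
        raise DataError(f"W has {W.shape[0]} rows for {y.size} phenotypes")
    n, c = W.shape
    if n <= c:
        raise DataError(f"need n > c, got n={n}, c={c}")
    if np.linalg.matrix_rank(W) < c:
        raise DataError("fixed-effect design W is rank deficient")
    if K.n != n:
        raise DataError(f"kinship is {K.n} x {K.n} for n={n}")

    if eig is None:
        d, U = np.linalg.eigh(K.values)
    else:
        d, U = eig
    d = np.maximum(d, 0.0)

    if d[-1] - d[0] <= 1e-8 * max(d[-1], 1.0):
        logger.warning(
            "kinship is numerically proportional to the identity: lambda_g is not "
            "identifiable; returning lambda_g = 0"
        )
        resid = y - W @ np.linalg.lstsq(W, y, rcond=None)[0]
        sigma2 = float(resid @ resid) / (n - c)
        neg2 = _reml_neg2_profile(-np.inf, d, U.T @ y, U.T @ W, n, c)
        return VarianceRatios(lambda_g=0.0, sigma2=sigma2, log_reml=_reml_loglik(neg2, n, c))

    yt = U.T @ y
    Wt = U.T @ W
    obj = lambda x: _reml_neg2_profile(x, d, yt, Wt, n, c)
    x_best, f_best = grid_refined_minimum(obj, *_LOG10_BOUNDS)
    candidates = [(f_best, 10.0 ** x_best)]
    candidates.append((obj(-np.inf), 0.0))  # lambda = 0 boundary
    best_neg2, best_lam = min(candidates, key=lambda t: t[0])

    def _sigma2_at(lam: float) -> float:
        v = lam * d + 1.0
        Wv = Wt / v[:, None]
        a = np.linalg.solve(Wt.T @ Wv, Wv.T @ yt)
        r = yt - Wt @ a
        return float(np.sum(r * r / v)) / (n - c)

    var_y = float(np.var(y))
    if best_lam >= 10.0 ** (_LOG10_BOUNDS[1] - 0.5) or (
        best_lam > 0 and _sigma2_at(best_lam) < 0.01 * var_y
    ):
        # Degenerate (infinite-heritability) solution: the optimum assigns
        # essentially all variance to the polygenic term (residual share
        # < 1%, or argmin at the upper search bound). The profile is
        # typically flat there over several decades — the data cannot
        # distinguish "almost no residual" from "no residual" — yet such a
        # lambda removes the identity part of B and breaks the whitening
        # model. Report the smallest lambda whose restricted likelihood is
        # not significantly worse than the degenerate optimum
        # (-2 log LR <= 3.84, the chi-square_1 95% point): a profile-
        # likelihood lower confidence limit.
        target = best_neg2 + 3.84
        lo, hi = _LOG10_BOUNDS
        grid = np.arange(lo, hi, 0.1)
        inside = next((x for x in grid if obj(x) <= target), hi)
        a, b = inside - 0.1, inside
        for _ in range(40):  # bisection on the crossing
            mid = 0.5 * (a + b)
            if obj(mid) <= target:
                b = mid
            else:
                a = mid
        best_lam = 10.0 ** b
        best_neg2 = obj(b)
        logger.warning(
            "REML profile is degenerate at the upper boundary; reporting the "
            "profile-likelihood lower confidence limit lambda_g = %.3g", best_lam
        )

    v = best_lam * d + 1.0
    Wv = Wt / v[:, None]
    alpha = np.linalg.solve(Wt.T @ Wv, Wv.T @ yt)
    r = yt - Wt @ alpha
    sigma2 = float(np.sum(r * r / v)) / (n - c)
    return VarianceRatios(
        lambda_g=float(best_lam),
        sigma2=sigma2,
        log_reml=_reml_loglik(best_neg2, n, c),
    )


def build_whitening(
    K: KinshipMatrix,
    lambda_g: float,
    eig: tuple[np.ndarray, np.ndarray] | None = None,
) -> WhiteningOperator:
    """Spectral decomposition of B = lambda_g K + I and its inverse square root.

    B shares K's eigenvectors, so a precomputed ``eig = (d, U)`` of K is reused
    when available. Eigenvalues of B that come out non-positive through
    roundoff are floored at 1e-10 with a warning (cannot happen for PSD K and
    lambda_g >= 0 except through cancellation).
    """
    if lambda_g < 0:
        raise DataError("lambda_g must be >= 0")
    if lambda_g == 0.0:
        # B = I exactly; keep C = I so the unwhitened path is bit-reproducible
        n = K.n
        eye = np.eye(n)
        b_hash = hashlib.sha256(np.ascontiguousarray(eye).tobytes()).hexdigest()
        return WhiteningOperator(
            eigenvalues=np.ones(n),
            eigenvectors=eye,
            transform=eye,
            lambda_g=0.0,
            b_matrix_hash=b_hash,
        )
    if eig is None:
        d, U = np.linalg.eigh(K.values)
    else:
        d, U = eig
    evals = lambda_g * d + 1.0
    if evals[0] < _EIG_FLOOR:
        if lambda_g * d[0] < -1.0 - 1e-6:
            raise DataError("kinship is indefinite: B = lambda_g K + I has negative eigenvalues")
        logger.warning("flooring %d eigenvalue(s) of B at %.0e", int(np.sum(evals < _EIG_FLOOR)), _EIG_FLOOR)
        evals = np.maximum(evals, _EIG_FLOOR)
    C = (U * (evals ** -0.5)) @ U.T
    C = (C + C.T) / 2.0
    B = lambda_g * K.values + np.eye(K.n)
    b_hash = hashlib.sha256(np.ascontiguousarray(B).tobytes()).hexdigest()
    return WhiteningOperator(
        eigenvalues=evals,
        eigenvectors=U,
        transform=C,
        lambda_g=float(lambda_g),
        b_matrix_hash=b_hash,
    )


def apply_whitening(
    op: WhiteningOperator,
    y: np.ndarray,
    W: np.ndarray,
    Z: GenotypeMatrix | np.ndarray,
) -> WhitenedData:
    """Transform (y, W, Z) -> (Cy, CW, CZ).

    If Cov(y) = sigma^2 B then Cov(Cy) = sigma^2 I. Note C is not a
    permutation: structured columns of W (e.g. the intercept) are generally no
    longer constant after the transform, which is expected.
    """
    y = np.asarray(y, dtype=np.float64).ravel()
    W = np.atleast_2d(np.asarray(W, dtype=np.float64))
    Zm = Z.dosages if isinstance(Z, GenotypeMatrix) else np.asarray(Z, dtype=np.float64)
    n = op.n
    if y.size != n or W.shape[0] != n or Zm.shape[0] != n:
        raise DataError(
            f"dimension mismatch: operator n={n}, y={y.size}, W rows={W.shape[0]}, "
            f"Z rows={Zm.shape[0]}"
        )
    C = op.transform
    return WhitenedData(y_c=C @ y, W_c=C @ W, Z_c=C @ Zm)
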