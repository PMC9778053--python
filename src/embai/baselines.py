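"""Baseline EM fitters sharing the em_core data types and sweep machinery.

* ``fit_emba``  — EM-for-BayesA on untransformed data (per-marker variances).
* ``fit_emrr``  — EM Bayesian ridge regression: one shared marker variance.
* ``fit_emml``  — Gaussian maximum likelihood: the equivalent GBLUP covariance
  ``sigma_gamma^2 Z Z' + sigma^2 I`` with the ratio chosen by 1-D profile ML;
  effects recovered as the posterior mean.
* ``fit_embc``  — spike-and-slab (BayesC-style) mean-field variational EM.
* ``fit_emen``  — declared but not implemented (elastic net; see docstring).

Every fitter returns the same :class:`~embai.em_core.EMFit` schema so the
benchmark harness is method-agnostic. For runs with polygenic-background
control, whiten the inputs first (``embai.varcomp``) and pass the transformed
arrays; the fitters themselves are transform-agnostic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import logit as _logit

from ._kernels import spike_slab_sweep
from .em_core import EMFit, PriorConfig, fit_embayesa
from .exceptions import DataError, NumericalError
from .simdata import GenotypeMatrix
from .varcomp import WhitenedData, grid_refined_minimum

__all__ = ["MixtureConfig", "fit_emba", "fit_emrr", "fit_emml", "fit_embc", "fit_emen"]

logger = logging.getLogger(__name__)

_SIGMA2_FLOOR = 1e-12


@dataclass(frozen=True)
class MixtureConfig:
    """Spike-and-slab mixture settings for the BayesC-style fitter."""

    pi_init: float = 0.05
    estimate_pi: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.pi_init < 1.0:
            raise DataError("pi_init must lie in (0, 1)")


def _as_arrays(y, W, Z):
    y = np.asarray(y, float).ravel()
    W = np.atleast_2d(np.asarray(W, float))
    Zm = Z.dosages if isinstance(Z, GenotypeMatrix) else np.asarray(Z, float)
    if W.shape[0] != y.size or Zm.shape[0] != y.size:
        raise DataError("y, W and Z row counts disagree")
    return y, W, Zm


def fit_emba(y, W, Z, prior: PriorConfig | None = None) -> EMFit:
    """EM-for-BayesA without the whitening stage (identical EM updates)."""
    y, W, Zm = _as_arrays(y, W, Z)
    data = WhitenedData(y_c=y, W_c=W, Z_c=Zm)
    return fit_embayesa(data, prior, method_tag="emBA")


def fit_emrr(y, W, Z, prior: PriorConfig | None = None) -> EMFit:
    """EM Bayesian ridge regression: all markers share one variance.

    The shared variance is refreshed each iteration from the posterior-expected
    precision, ``sigma_gamma^2 = (sum_k gamma_k^2 + S) / (q + nu)``, and every
    marker update uses the common shrinkage ratio ``sigma^2 / sigma_gamma^2``.
    The recorded objective is the marginal log-posterior with the shared
    variance integrated out, ``-n/2 log s2 - |r|^2/(2 s2) -
    (q+nu)/2 log(sum gamma^2 + S)``, which the iteration ascends.
    """
    from ._kernels import gauss_seidel_sweep

    prior = prior or PriorConfig()
    y, W, Zm = _as_arrays(y, W, Z)
    Zf = np.asfortranarray(Zm, dtype=np.float64)
    n, q = Zf.shape
    c = W.shape[1]
    ztz = np.einsum("ij,ij->j", Zf, Zf)
    wtw = np.einsum("ij,ij->j", W, W)
    if np.any(ztz == 0.0) or np.any(wtw == 0.0):
        raise DataError("zero-norm column in Z or W")

    alpha = np.linalg.lstsq(W, y, rcond=None)[0]
    resid = y - W @ alpha
    sigma2 = max(float(resid @ resid) / n, _SIGMA2_FLOOR)
    gamma = np.zeros(q)
    # moment-matched start: put half the current residual variance on markers
    sigma_g2 = max(0.5 * sigma2 * n / float(np.sum(ztz)), prior.scale / (q + prior.nu))

    trace = []
    converged = False
    n_iter = prior.max_iter
    prev_delta = np.inf
    for it in range(1, prior.max_iter + 1):
        shrink = np.full(q, sigma2 / sigma_g2)
        _, ssq_delta = gauss_seidel_sweep(Zf, ztz, resid, gamma, shrink)
        rms_delta = float(np.sqrt(ssq_delta / q))
        for j in range(c):
            new = (W[:, j] @ resid) / wtw[j] + alpha[j]
            resid -= (new - alpha[j]) * W[:, j]
            alpha[j] = new
        if it % 25 == 0:
            resid = y - W @ alpha - Zf @ gamma
        ss_gamma = float(gamma @ gamma)
        sigma_g2 = (ss_gamma + prior.scale) / (q + prior.nu)
        rss = float(resid @ resid)
        sigma2 = max(rss / n, _SIGMA2_FLOOR)
        trace.append(
            -0.5 * n * np.log(sigma2) - rss / (2 * sigma2)
            - 0.5 * (q + prior.nu) * np.log(ss_gamma + prior.scale)
        )
        if not np.isfinite(sigma2) or not np.all(np.isfinite(gamma)):
            raise NumericalError(f"non-finite values at iteration {it}")
        if (
            it >= 2
            and rms_delta < prior.tol * (1e-3 + float(np.sqrt(np.mean(gamma ** 2))))
            and rms_delta <= prev_delta
        ):
            converged = True
            n_iter = it
            break
        prev_delta = rms_delta

    return EMFit(
        alpha=alpha,
        gamma=gamma,
        sigma_k2=np.full(q, sigma_g2),
        sigma2=sigma2,
        n_iter=n_iter,
        converged=converged,
        log_posterior_trace=np.asarray(trace),
        method_tag="emRR",
    )


def fit_emml(y, W, Z, prior: PriorConfig | None = None) -> EMFit:
    """Gaussian maximum likelihood over the equivalent GBLUP covariance.

    Marginally ``y ~ N(W a, sigma_gamma^2 Z Z' + sigma^2 I)``; the variance
    ratio ``delta = sigma_gamma^2 / sigma^2`` is found by bounded 1-D
    maximization of the profile log-likelihood on the eigenbasis of Z Z'
    (fixed effects profiled by GLS, sigma^2 in closed form), and the marker
    effects are the conditional posterior mean
    ``gamma = delta Z' (delta Z Z' + I)^{-1} (y - W a)``.
    """
    prior = prior or PriorConfig()
    y, W, Zm = _as_arrays(y, W, Z)
    n, q = Zm.shape
    c = W.shape[1]
    G = Zm @ Zm.T
    d, U = np.linalg.eigh(G)
    d = np.maximum(d, 0.0)
    yt = U.T @ y
    Wt = U.T @ W

    def neg_profile(log10_delta: float) -> float:
        delta = 10.0 ** log10_delta
        v = delta * d + 1.0
        Wv = Wt / v[:, None]
        try:
            a = np.linalg.solve(Wt.T @ Wv, Wv.T @ yt)
        except np.linalg.LinAlgError as err:
            raise DataError("rank-deficient fixed-effect design") from err
        r = yt - Wt @ a
        rss = float(np.sum(r * r / v))
        return n * np.log(rss) + float(np.sum(np.log(v)))

    x_best, f_best = grid_refined_minimum(neg_profile, -8.0, 8.0, n_grid=65)
    candidates = [(f_best, 10.0 ** x_best), (neg_profile(-np.inf), 0.0)]
    best_obj, delta = min(candidates, key=lambda t: t[0])

    v = delta * d + 1.0
    Wv = Wt / v[:, None]
    alpha = np.linalg.solve(Wt.T @ Wv, Wv.T @ yt)
    rt = yt - Wt @ alpha
    rss = float(np.sum(rt * rt / v))
    sigma2 = max(rss / n, _SIGMA2_FLOOR)
    # posterior mean of gamma given the ML variance components
    gamma = delta * (Zm.T @ (U @ (rt / v)))
    loglik = -0.5 * (best_obj - n * np.log(n) + n * (1.0 + np.log(2.0 * np.pi)))
    return EMFit(
        alpha=alpha,
        gamma=gamma,
        sigma_k2=np.full(q, delta * sigma2),
        sigma2=sigma2,
        n_iter=1,  # direct 1-D maximization, not an iterative sweep
        converged=True,
        log_posterior_trace=np.array([loglik]),
        method_tag="emML",
        extras={"delta": float(delta)},
    )


def _xlogy(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    out = np.zeros_like(x)
    mask = x > 0
    out[mask] = x[mask] * np.log(y[mask])
    return out


def fit_embc(
    y,
    W,
    Z,
    prior: PriorConfig | None = None,
    mix: MixtureConfig | None = None,
) -> EMFit:
    """Spike-and-slab EM (BayesC-style): point-mass spike, shared-variance slab.

    Mean-field variational EM: each marker's posterior is a Bernoulli inclusion
    probability ``p_k`` times a slab Gaussian ``N(m_k, v_k)``; the expected
    effect ``p_k m_k`` drives the residual. The slab variance gets the
    scaled-inverse-chi-square prior and is updated by the exact evidence
    -bound maximizer; the inclusion fraction ``pi`` is updated to the mean
    inclusion probability when ``estimate_pi``. ``log_posterior_trace``
    records the evidence lower bound, which every update block ascends.
    """
    prior = prior or PriorConfig()
    mix = mix or MixtureConfig()
    y, W, Zm = _as_arrays(y, W, Z)
    Zf = np.asfortranarray(Zm, dtype=np.float64)
    n, q = Zf.shape
    c = W.shape[1]
    ztz = np.einsum("ij,ij->j", Zf, Zf)
    wtw = np.einsum("ij,ij->j", W, W)
    if np.any(ztz == 0.0) or np.any(wtw == 0.0):
        raise DataError("zero-norm column in Z or W")

    alpha = np.linalg.lstsq(W, y, rcond=None)[0]
    resid = y - W @ alpha
    sigma2 = max(float(resid @ resid) / n, _SIGMA2_FLOOR)
    pi = mix.pi_init
    sigma_g2 = max(
        0.5 * sigma2 * n / (max(pi * q, 1.0) * float(np.mean(ztz))),
        prior.scale / (prior.nu + 2.0),
    )
    e_gamma = np.zeros(q)
    m = np.zeros(q)
    v = np.full(q, sigma_g2)
    p = np.zeros(q)

    trace = []
    converged = False
    n_iter = prior.max_iter
    prev_delta = np.inf
    for it in range(1, prior.max_iter + 1):
        _, ssq_delta = spike_slab_sweep(
            Zf, ztz, resid, e_gamma, m, v, p, sigma2, sigma_g2, _logit(pi)
        )
        rms_delta = float(np.sqrt(ssq_delta / q))
        for j in range(c):
            new = (W[:, j] @ resid) / wtw[j] + alpha[j]
            resid -= (new - alpha[j]) * W[:, j]
            alpha[j] = new
        if it % 25 == 0:
            resid = y - W @ alpha - Zf @ e_gamma
        slab_m2 = p * (m * m + v)
        sigma_g2 = (float(np.sum(slab_m2)) + prior.scale) / (float(np.sum(p)) + prior.nu + 2.0)
        if mix.estimate_pi:
            pi = float(np.clip(np.mean(p), 1e-6, 1.0 - 1e-6))
        var_gamma = slab_m2 - e_gamma ** 2
        erss = float(resid @ resid) + float(ztz @ var_gamma)
        sigma2 = max(erss / n, _SIGMA2_FLOOR)
        trace.append(_embc_elbo(n, sigma2, erss, p, m, v, pi, sigma_g2, prior))
        if not np.isfinite(sigma2) or not np.all(np.isfinite(e_gamma)):
            raise NumericalError(f"non-finite values at iteration {it}")
        if (
            it >= 2
            and rms_delta < prior.tol * (1e-3 + float(np.sqrt(np.mean(e_gamma ** 2))))
            and rms_delta <= prev_delta
        ):
            converged = True
            n_iter = it
            break
        prev_delta = rms_delta

    return EMFit(
        alpha=alpha,
        gamma=e_gamma,
        sigma_k2=p * (m * m + v) - e_gamma ** 2 + 1e-300,
        sigma2=sigma2,
        n_iter=n_iter,
        converged=converged,
        log_posterior_trace=np.asarray(trace),
        method_tag="emBC",
        extras={"pi": float(pi), "inclusion_prob": p.copy(), "sigma_g2": float(sigma_g2)},
    )


def _embc_elbo(n, sigma2, erss, p, m, v, pi, sigma_g2, prior) -> float:
    """Evidence lower bound of the spike-and-slab mean-field posterior."""
    fit_term = -0.5 * n * np.log(2.0 * np.pi * sigma2) - erss / (2.0 * sigma2)
    kl_slab = 0.5 * np.sum(p * ((m * m + v) / sigma_g2 - 1.0 - np.log(v / sigma_g2)))
    ent = np.sum(
        _xlogy(p, np.full_like(p, pi)) - _xlogy(p, p)
        + _xlogy(1.0 - p, np.full_like(p, 1.0 - pi)) - _xlogy(1.0 - p, 1.0 - p)
    )
    prior_sg2 = -(prior.nu / 2.0 + 1.0) * np.log(sigma_g2) - prior.scale / (2.0 * sigma_g2)
    return float(fit_term - kl_slab + ent + prior_sg2)


def fit_emen(y, W, Z, prior: PriorConfig | None = None) -> EMFit:
    """Elastic-net fitter: intentionally not implemented.

    The combined L1/L2-penalized variant is numerically fragile on p >> n
    genomic data (it tends to produce empty or degenerate solutions there) and
    is excluded from this package's supported methods.
    """
    raise NotImplementedError(
        "emEN is not implemented; use emRR for a pure L2 fit or emBC for sparsity"
    )
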