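"""Numba-jitted Gauss-Seidel sweep kernels for the EM marker updates.

These are the only performance-critical loops in the package: one full sweep
touches every marker column once with an incrementally maintained residual,
costing O(n q) per sweep. Arrays are expected Fortran-ordered so each column
is contiguous.
"""

from __future__ import annotations

import numba
import numpy as np


@numba.njit(cache=True, fastmath=False)
def gauss_seidel_sweep(Z, ztz, resid, gamma, shrink):
    """One coordinate-ascent sweep of the ridge-shrunken marker updates.

    Updates ``gamma`` and ``resid`` in place; ``resid`` holds the full current
    residual y - W a - Z g.  ``shrink[k]`` is the per-marker ridge term
    sigma^2 / sigma_k^2.  Returns (max |delta gamma_k|, sum delta gamma_k^2)
    over the sweep.
    """
    n, q = Z.shape
    max_delta = 0.0
    ssq_delta = 0.0
    for k in range(q):
        num = 0.0
        for i in range(n):
            num += Z[i, k] * resid[i]
        num += ztz[k] * gamma[k]
        new = num / (ztz[k] + shrink[k])
        d = new - gamma[k]
        if d != 0.0:
            for i in range(n):
                resid[i] -= d * Z[i, k]
            ad = abs(d)
            if ad > max_delta:
                max_delta = ad
            ssq_delta += d * d
        gamma[k] = new
    return max_delta, ssq_delta


@numba.njit(cache=True, fastmath=False)
def spike_slab_sweep(Z, ztz, resid, e_gamma, m, v, p, sigma2, sigma_g2, logit_pi):
    """One mean-field sweep of the spike-and-slab (BayesC-style) updates.

    For each marker, given the residual with its own expected contribution
    removed, computes the slab posterior N(m_k, v_k), the posterior inclusion
    probability p_k, and the new expected effect p_k * m_k; ``resid`` tracks
    y - W a - Z E[gamma]. Returns (max |delta E[gamma_k]|, sum delta^2).
    """
    n, q = Z.shape
    max_delta = 0.0
    ssq_delta = 0.0
    for k in range(q):
        b = 0.0
        for i in range(n):
            b += Z[i, k] * resid[i]
        b += ztz[k] * e_gamma[k]
        denom = ztz[k] + sigma2 / sigma_g2
        vk = sigma2 / denom
        mk = b / denom
        lo = logit_pi + 0.5 * np.log(vk / sigma_g2) + mk * mk / (2.0 * vk)
        if lo > 35.0:
            pk = 1.0
        elif lo < -35.0:
            pk = 0.0
        else:
            pk = 1.0 / (1.0 + np.exp(-lo))
        new = pk * mk
        d = new - e_gamma[k]
        if d != 0.0:
            for i in range(n):
                resid[i] -= d * Z[i, k]
            ad = abs(d)
            if ad > max_delta:
                max_delta = ad
            ssq_delta += d * d
        e_gamma[k] = new
        m[k] = mk
        v[k] = vk
        p[k] = pk
    return max_delta, ssq_delta
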