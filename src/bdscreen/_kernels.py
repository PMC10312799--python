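"""Numba-compiled moment kernels for fast likelihood evaluation.

These duplicate the closed forms in ``moments`` as tight loops over
primitive arrays; the likelihood functions call them thousands of times per
fit.  The numpy implementations in ``moments`` remain the reference API and
the two are held together by the likelihood oracle tests.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _clone_rates(beta, nu, b, E, m, d):
    """Dose-dependent death and net rates for one clone at one dose."""
    if d > 0.0:
        ratio = (d / E) ** m
    else:
        ratio = 0.0
    h = b + (1.0 - b) / (1.0 + ratio)
    nu_d = nu - np.log(h)
    return nu_d, beta - nu_d


@njit(cache=True)
def _var_per_cell(beta, nu_d, lam, t):
    x = lam * t
    if abs(x) < 1e-12:
        return (beta + nu_d) * t
    return (beta + nu_d) / lam * np.exp(x) * np.expm1(x)


@njit(cache=True)
def moment_matrices(p, beta, nu, b, E, m, t, d, n):
    """Mean (scaled by n) and per-cell variance on the (time, dose) grid."""
    n_t, n_d, S = t.size, d.size, p.size
    mu = np.zeros((n_t, n_d))
    var = np.zeros((n_t, n_d))
    for k in range(S):
        for j in range(n_d):
            nu_d, lam = _clone_rates(beta[k], nu[k], b[k], E[k], m[k], d[j])
            for i in range(n_t):
                mu[i, j] += p[k] * np.exp(lam * t[i])
                var[i, j] += p[k] * _var_per_cell(beta[k], nu_d, lam, t[i])
    return n * mu, var


@njit(cache=True)
def covariance_tensors(p, beta, nu, b, E, m, t, d):
    """Per-cell temporal covariance per dose, shape (n_d, n_t, n_t)."""
    n_t, n_d, S = t.size, d.size, p.size
    cov = np.zeros((n_d, n_t, n_t))
    v = np.empty(n_t)
    for k in range(S):
        for j in range(n_d):
            nu_d, lam = _clone_rates(beta[k], nu[k], b[k], E[k], m[k], d[j])
            for i in range(n_t):
                v[i] = _var_per_cell(beta[k], nu_d, lam, t[i])
            for i in range(n_t):
                for l in range(i, n_t):
                    c = p[k] * np.exp(lam * (t[l] - t[i])) * v[i]
                    cov[j, i, l] += c
                    if l != i:
                        cov[j, l, i] += c
    return cov


@njit(cache=True)
def mvn_sum(counts, mu, cov):
    """Sum of multivariate normal log-densities of trajectory columns.

    ``counts`` is (n_t, n_d, n_r); per dose, each replicate column is a
    draw from N(mu[:, j], cov[j]).  Returns NaN if any dose's covariance
    is not positive definite (caller escalates jitter).
    """
    n_t, n_d, n_r = counts.shape
    log2pi = np.log(2.0 * np.pi)
    chol = np.empty((n_t, n_t))
    z = np.empty(n_t)
    total = 0.0
    for j in range(n_d):
        # lower Cholesky factor of cov[j]
        for a in range(n_t):
            for c in range(a + 1):
                acc = cov[j, a, c]
                for k in range(c):
                    acc -= chol[a, k] * chol[c, k]
                if a == c:
                    if acc <= 0.0:
                        return np.nan
                    chol[a, a] = np.sqrt(acc)
                else:
                    chol[a, c] = acc / chol[c, c]
        logdet = 0.0
        for a in range(n_t):
            logdet += np.log(chol[a, a])
        logdet *= 2.0
        for r in range(n_r):
            # forward solve L z = x - mu
            quad = 0.0
            for a in range(n_t):
                acc = counts[a, j, r] - mu[a, j]
                for k in range(a):
                    acc -= chol[a, k] * z[k]
                z[a] = acc / chol[a, a]
                quad += z[a] * z[a]
            total += -0.5 * (n_t * log2pi + logdet + quad)
    return total


@njit(cache=True)
def gaussian_sum(counts, mu, var):
    """Sum of scalar normal log-densities over a (T, D, R) count block."""
    n_t, n_d, n_r = counts.shape
    log2pi = np.log(2.0 * np.pi)
    total = 0.0
    for i in range(n_t):
        for j in range(n_d):
            lv = np.log(var[i, j])
            inv = 0.5 / var[i, j]
            for r in range(n_r):
                resid = counts[i, j, r] - mu[i, j]
                total += -0.5 * (log2pi + lv) - resid * resid * inv
    return total
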