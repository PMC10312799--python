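"""Gaussian log-likelihoods of the three deconvolution models.

All three treat the observed counts as Gaussian around the mixture mean
curve; they differ in where the variance comes from:

* ``loglik_phenopop`` — deterministic exponential growth with two fixed
  noise levels (high variance for late times at low doses, low otherwise).
* ``loglik_endpoints`` — birth-death central-limit approximation with
  independent scalar observations; variance ``n sigma^2(t, d) + c^2``
  depends on the growth parameters.
* ``loglik_livecell`` — multivariate Gaussian per (dose, replicate)
  trajectory with temporal covariance ``n Sigma(d) + c^2 I``.

Everything is computed in log space; the multivariate form uses a Cholesky
factorization (never an explicit inverse) with a small escalating jitter
because the observation-noise floor ``c`` may sit at 0 during optimization.
"""

from __future__ import annotations

import numpy as np

from . import _kernels
from .dose_response import hill
from .moments import ModelParams, PhenoPopParams
from .simulate import ScreenDataset

__all__ = [
    "loglik_phenopop",
    "loglik_endpoints",
    "loglik_livecell",
    "default_noise_thresholds",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


def _param_arrays(theta: ModelParams):
    """Primitive per-clone arrays consumed by the compiled kernels."""
    p = np.asarray(theta.fractions, dtype=float)
    beta = np.array([sp.beta for sp in theta.subpops])
    nu = np.array([sp.nu for sp in theta.subpops])
    b = np.array([sp.hill.b for sp in theta.subpops])
    e = np.array([sp.hill.E for sp in theta.subpops])
    m = np.array([sp.hill.m for sp in theta.subpops])
    return p, beta, nu, b, e, m


def _design_grids(design):
    return np.asarray(design.times, dtype=float), np.asarray(design.doses, dtype=float)


def default_noise_thresholds(design) -> tuple:
    """Default (T_L, D_L): midpoint of the time grid and median nonzero dose.

    Their precise values have little influence on the two-level-noise fit,
    so they are treated as known constants of the design.
    """
    times = np.asarray(design.times, dtype=float)
    doses = np.asarray(design.doses, dtype=float)
    nonzero = doses[doses > 0]
    d_l = float(np.median(nonzero)) if nonzero.size else 0.0
    return float(0.5 * (times[0] + times[-1])), d_l


def loglik_phenopop(theta: PhenoPopParams, data: ScreenDataset) -> float:
    """Log-likelihood of the deterministic-growth two-noise-level model."""
    design = data.design
    t = np.asarray(design.times, dtype=float)
    d = np.asarray(design.doses, dtype=float)
    if theta.sigma_H <= 0.0 or theta.sigma_L <= 0.0:
        raise ValueError("degenerate model: noise SDs must be > 0")
    # mean surface f(t, d) = n sum_i p_i exp[t (alpha_i + log H_i(d))]
    mean = np.zeros((t.size, d.size))
    for p_i, a_i, h_i in zip(theta.fractions, theta.alphas, theta.hills):
        rate = a_i + np.log(hill(d, h_i))
        mean += p_i * np.exp(np.outer(t, rate))
    mean *= design.n_initial
    high = (t[:, None] >= theta.T_L) & (d[None, :] <= theta.D_L)
    var = np.where(high, theta.sigma_H**2, theta.sigma_L**2)
    resid2 = (data.counts - mean[:, :, None]) ** 2
    ll = -0.5 * (_LOG_2PI + np.log(var)[:, :, None] + resid2 / var[:, :, None])
    return float(ll.sum())


def loglik_endpoints(theta: ModelParams, data: ScreenDataset) -> float:
    """Log-likelihood under independent scalar Gaussian approximations.

    Each observation is N(mu(t, d), n sigma^2(t, d) + c^2) with moments
    from the birth-death model; observations are independent across times,
    doses and replicates.
    """
    design = data.design
    n = design.n_initial
    t, d = _design_grids(design)
    mu, var_cell = _kernels.moment_matrices(*_param_arrays(theta), t, d, float(n))
    var = n * var_cell + theta.noise_c**2
    if np.any(var <= 0.0) or not np.all(np.isfinite(var)):
        raise FloatingPointError(
            "nonpositive or non-finite observation variance; "
            "model is degenerate at these parameters"
        )
    return float(_kernels.gaussian_sum(data.counts, mu, var))


def loglik_livecell(theta: ModelParams, data: ScreenDataset) -> float:
    """Log-likelihood of time-correlated trajectories.

    Per dose and replicate, the trajectory over the time grid is
    N(mu(d), n Sigma(d) + c^2 I); doses and replicates are independent.
    The quadratic forms come from Cholesky factors, never from an explicit
    inverse; an escalating diagonal jitter guards against near-singular
    covariances while c sits at 0 during optimization.
    """
    design = data.design
    n = design.n_initial
    n_t = len(design.times)
    t, d = _design_grids(design)
    arrays = _param_arrays(theta)
    mu, _ = _kernels.moment_matrices(*arrays, t, d, float(n))  # (n_t, n_d)
    cov = n * _kernels.covariance_tensors(*arrays, t, d)
    cov += theta.noise_c**2 * np.eye(n_t)
    if not np.all(np.isfinite(cov)):
        raise FloatingPointError("non-finite trajectory covariance")
    trace = float(np.trace(cov, axis1=-2, axis2=-1).mean())
    for jitter in (0.0, 1e-9, 1e-6):
        ll = _kernels.mvn_sum(data.counts, mu, cov + jitter * trace / n_t * np.eye(n_t))
        if not np.isnan(ll):
            return float(ll)
    raise np.linalg.LinAlgError(
        f"trajectory covariance not positive definite (mean trace={trace:.3g}, "
        f"condition persists after jitter escalation to 1e-6)"
    )
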