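"""Closed-form moments of the multi-type linear birth-death population.

Each clone grows as an independent linear birth-death process started from
``n * p_i`` cells.  Per ancestor cell of clone ``i`` under dose ``d``:

* mean size at time t:      ``mu_i(t, d) = exp(lambda_i(d) t)``
* variance at time t:       ``sigma_i^2(t, d) = (beta_i + nu_i(d)) / lambda_i(d)
  * (exp(2 lambda t) - exp(lambda t))`` (limit ``(beta + nu) t`` at lambda=0)
* autocovariance (s <= t):  ``exp(lambda (t - s)) sigma_i^2(s, d)``

The total population moments are fraction-weighted sums; the large-``n``
Gaussian approximation of the total count vector over a time grid has mean
``n mu(d)`` and covariance ``n Sigma(d)`` with ``Sigma`` assembled here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dose_response import SubpopulationParams, death_rate, net_rate

__all__ = [
    "ModelParams",
    "PhenoPopParams",
    "validate_time_grid",
    "subpop_mean",
    "subpop_variance",
    "total_mean_vector",
    "total_variance",
    "covariance_matrix",
    "mean_matrix",
    "variance_matrix",
    "covariance_tensor",
]


def validate_time_grid(times) -> np.ndarray:
    """Return ``times`` as a strictly increasing array of positive floats."""
    t = np.atleast_1d(np.asarray(times, dtype=float))
    if t.ndim != 1 or t.size == 0:
        raise ValueError("time grid must be a nonempty 1-d sequence")
    if np.any(t <= 0.0):
        raise ValueError("time grid must be strictly positive (t=0 is the known start)")
    if np.any(np.diff(t) <= 0.0):
        raise ValueError("time grid must be strictly increasing")
    return t


@dataclass(frozen=True)
class ModelParams:
    """Full parameter set of the stochastic birth-death mixture model.

    ``fractions`` are the initial clone fractions (sum to 1), ``subpops``
    the per-clone birth-death/Hill parameters, and ``noise_c`` the standard
    deviation (in cells) of the additive Gaussian observation noise.
    """

    fractions: tuple
    subpops: tuple
    noise_c: float = 0.0

    def __post_init__(self) -> None:
        fr = tuple(float(p) for p in self.fractions)
        object.__setattr__(self, "fractions", fr)
        object.__setattr__(self, "subpops", tuple(self.subpops))
        if len(fr) != len(self.subpops) or len(fr) == 0:
            raise ValueError("fractions and subpops must have equal nonzero length")
        if any(p < 0 for p in fr) or abs(sum(fr) - 1.0) > 1e-8:
            raise ValueError(f"fractions must be nonnegative and sum to 1, got {fr}")
        if self.noise_c < 0.0:
            raise ValueError("observation noise SD must be >= 0")

    @property
    def n_populations(self) -> int:
        return len(self.subpops)

    def reordered_by_E(self) -> "ModelParams":
        """Canonical label order: ascending half-effect dose (sensitive first)."""
        order = np.argsort([sp.hill.E for sp in self.subpops], kind="stable")
        return ModelParams(
            fractions=tuple(self.fractions[i] for i in order),
            subpops=tuple(self.subpops[i] for i in order),
            noise_c=self.noise_c,
        )


@dataclass(frozen=True)
class PhenoPopParams:
    """Parameter set of the deterministic-growth two-noise-level model.

    Each clone grows exponentially at rate ``alpha_i + log H_i(d)``;
    observation noise has SD ``sigma_H`` for late times at low doses
    (``t >= T_L`` and ``d <= D_L``) and ``sigma_L`` otherwise.  The
    thresholds are treated as known.
    """

    fractions: tuple
    alphas: tuple
    hills: tuple
    sigma_H: float
    sigma_L: float
    T_L: float
    D_L: float

    def __post_init__(self) -> None:
        fr = tuple(float(p) for p in self.fractions)
        object.__setattr__(self, "fractions", fr)
        object.__setattr__(self, "alphas", tuple(float(a) for a in self.alphas))
        object.__setattr__(self, "hills", tuple(self.hills))
        if not (len(fr) == len(self.alphas) == len(self.hills)) or not fr:
            raise ValueError("fractions, alphas and hills must have equal length")
        if any(p < 0 for p in fr) or abs(sum(fr) - 1.0) > 1e-8:
            raise ValueError(f"fractions must be nonnegative and sum to 1, got {fr}")
        if self.sigma_H < 0 or self.sigma_L < 0:
            raise ValueError("noise SDs must be >= 0")

    @property
    def n_populations(self) -> int:
        return len(self.fractions)


def _variance_per_cell(t, beta: float, nu_d, lam):
    """Per-ancestor variance (beta + nu(d))/lam * (e^{2 lam t} - e^{lam t}).

    Uses expm1 for the difference of exponentials and the L'Hopital limit
    ``(beta + nu(d)) t`` where ``lam`` vanishes, avoiding cancellation for
    ``|lam t| << 1``.
    """
    t = np.asarray(t, dtype=float)
    lam = np.asarray(lam, dtype=float)
    nu_d = np.asarray(nu_d, dtype=float)
    small = np.abs(lam * t) < 1e-12
    lam_safe = np.where(small, 1.0, lam)
    with np.errstate(over="ignore"):
        core = np.exp(lam * t) * np.expm1(lam * t) / lam_safe
    out = (beta + nu_d) * np.where(small, t, core)
    return out


def subpop_mean(t, d, sp: SubpopulationParams, p_i: float, n: float):
    """Expected size of one clone: ``n p_i exp(lambda(d) t)``."""
    lam = net_rate(d, sp)
    out = n * p_i * np.exp(lam * np.asarray(t, dtype=float))
    return out if out.ndim else float(out)


def subpop_variance(t, d, sp: SubpopulationParams, p_i: float, n: float):
    """Variance of one clone's size at time ``t`` under dose ``d`` (cells^2)."""
    out = n * p_i * _variance_per_cell(t, sp.beta, death_rate(d, sp), net_rate(d, sp))
    return out if out.ndim else float(out)


def total_mean_vector(params: ModelParams, times, d, n: float) -> np.ndarray:
    """Expected total count at each grid time: ``sum_i n p_i e^{lambda_i(d) t}``."""
    t = validate_time_grid(times)
    mu = np.zeros_like(t)
    for p_i, sp in zip(params.fractions, params.subpops):
        mu += p_i * np.exp(net_rate(d, sp) * t)
    return n * mu


def total_variance(params: ModelParams, times, d) -> np.ndarray:
    """Per-initial-cell variance ``sigma^2(t, d) = sum_i p_i sigma_i^2(t, d)``.

    Callers scale by ``n`` and add ``c^2`` for the observed-count variance.
    """
    t = validate_time_grid(times)
    var = np.zeros_like(t)
    for p_i, sp in zip(params.fractions, params.subpops):
        var += p_i * _variance_per_cell(t, sp.beta, death_rate(d, sp), net_rate(d, sp))
    return var


def mean_matrix(params: ModelParams, times, doses, n: float) -> np.ndarray:
    """Expected total counts on the (time, dose) grid, shape (n_t, n_d)."""
    t = validate_time_grid(times)
    d = np.asarray(doses, dtype=float)
    mu = np.zeros((t.size, d.size))
    for p_i, sp in zip(params.fractions, params.subpops):
        mu += p_i * np.exp(np.outer(t, net_rate(d, sp)))
    return n * mu


def variance_matrix(params: ModelParams, times, doses) -> np.ndarray:
    """Per-initial-cell variances on the (time, dose) grid, shape (n_t, n_d)."""
    t = validate_time_grid(times)
    d = np.asarray(doses, dtype=float)
    var = np.zeros((t.size, d.size))
    for p_i, sp in zip(params.fractions, params.subpops):
        nu_d = np.asarray(death_rate(d, sp))
        lam = np.asarray(net_rate(d, sp))
        var += p_i * _variance_per_cell(t[:, None], sp.beta, nu_d[None, :], lam[None, :])
    return var


def covariance_tensor(params: ModelParams, times, doses) -> np.ndarray:
    """Per-initial-cell temporal covariance per dose, shape (n_d, n_t, n_t).

    Batched form of ``covariance_matrix`` used by the trajectory
    likelihood.
    """
    t = validate_time_grid(times)
    d = np.asarray(doses, dtype=float)
    earlier = t[:, None] <= t[None, :]
    gap = np.abs(t[:, None] - t[None, :])
    sigma = np.zeros((d.size, t.size, t.size))
    for p_i, sp in zip(params.fractions, params.subpops):
        nu_d = np.asarray(death_rate(d, sp))
        lam = np.asarray(net_rate(d, sp))
        v = _variance_per_cell(t[None, :], sp.beta, nu_d[:, None], lam[:, None])
        v_early = np.where(earlier[None], v[:, :, None], v[:, None, :])
        sigma += p_i * np.exp(lam[:, None, None] * gap[None]) * v_early
    return sigma


def covariance_matrix(params: ModelParams, times, d) -> np.ndarray:
    """Per-initial-cell temporal covariance ``Sigma(d)`` of the total count.

    Entry (i, j) with t_i <= t_j is ``sum_k p_k e^{lambda_k (t_j - t_i)}
    sigma_k^2(t_i, d)`` — the telescoped, algebraically equivalent form of
    the increment double sum.  Symmetric positive semi-definite; its
    diagonal is the marginal variance ``sigma^2(t_i, d)``.
    """
    t = validate_time_grid(times)
    tmin = np.minimum.outer(t, t)
    tmax = np.maximum.outer(t, t)
    sigma = np.zeros((t.size, t.size))
    for p_i, sp in zip(params.fractions, params.subpops):
        lam = net_rate(d, sp)
        v = _variance_per_cell(t, sp.beta, death_rate(d, sp), lam)
        # variance at the earlier of the two grid times
        v_early = np.where(t[:, None] <= t[None, :], v[:, None], v[None, :])
        sigma += p_i * np.exp(lam * (tmax - tmin)) * v_early
    return sigma
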