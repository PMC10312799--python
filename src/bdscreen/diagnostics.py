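"""Goodness-of-fit and study-level comparison utilities.

The central diagnostic asks how well the large-population Gaussian
approximation matches the exact birth-death law: simulate exact total-count
trajectories, sample the matching multivariate normal, and measure the
two-sample empirical energy distance.  The distance shrinks as the initial
cell count grows, which is what licenses the Gaussian likelihoods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import ranksums

from .moments import ModelParams, covariance_matrix, total_mean_vector, validate_time_grid
from .simulate import _total_population_paths

__all__ = [
    "EnergyDistanceResult",
    "empirical_energy_distance",
    "gaussian_approx_experiment",
    "normalized_ci_widths",
    "ci_width_rank_test",
]


def _sum_pairwise_norms(A: np.ndarray, B: np.ndarray, block: int = 2048) -> float:
    """Sum of Euclidean distances over all pairs, accumulated in blocks."""
    total = 0.0
    for i in range(0, A.shape[0], block):
        a = A[i : i + block]
        for j in range(0, B.shape[0], block):
            b = B[j : j + block]
            sq = (
                np.sum(a * a, axis=1)[:, None]
                + np.sum(b * b, axis=1)[None, :]
                - 2.0 * (a @ b.T)
            )
            np.maximum(sq, 0.0, out=sq)
            total += float(np.sqrt(sq, out=sq).sum())
    return total


def empirical_energy_distance(X, Y, block: int = 2048) -> float:
    """Two-sample energy distance V-statistic.

    ``2/(km) sum ||X_i - Y_j|| - 1/k^2 sum ||X_i - X_j|| - 1/m^2 sum
    ||Y_i - Y_j||`` with Euclidean norms and self-pair terms included.
    Nonnegative up to floating point; tiny negative values are clamped to 0
    with a warning.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[1] != Y.shape[1]:
        raise ValueError(f"dimension mismatch: {X.shape[1]} vs {Y.shape[1]}")
    k, m = X.shape[0], Y.shape[0]
    de = (
        2.0 / (k * m) * _sum_pairwise_norms(X, Y, block)
        - _sum_pairwise_norms(X, X, block) / k**2
        - _sum_pairwise_norms(Y, Y, block) / m**2
    )
    if de < 0.0:
        warnings.warn(
            f"energy-distance V-statistic slightly negative ({de:.3g}); clamped to 0",
            stacklevel=2,
        )
        de = 0.0
    return float(de)


@dataclass(frozen=True)
class EnergyDistanceResult:
    estimate: float
    k: int
    m: int
    seed: int | None = None


def gaussian_approx_experiment(
    params: ModelParams,
    times,
    n_list,
    n_samples: int = 10_000,
    n_datasets: int = 10,
    rng=None,
    dose: float = 0.0,
) -> pd.DataFrame:
    """Energy distance between exact and Gaussian trajectory laws vs n.

    For each initial cell count in ``n_list`` (increasing) and each of
    ``n_datasets`` repetitions, draws ``n_samples`` exact birth-death
    total-count trajectories and ``n_samples`` draws from
    N(mu, n Sigma + c^2 I), and records their empirical energy distance.
    Returns a long table with columns ``n_initial, dataset_index,
    energy_distance``.
    """
    t = validate_time_grid(times)
    n_list = [int(n) for n in n_list]
    if any(b <= a for a, b in zip(n_list, n_list[1:])):
        raise ValueError("n_list must be increasing")
    gen = np.random.default_rng(rng)
    rows = []
    for n in n_list:
        mu = total_mean_vector(params, t, dose, n)
        cov = n * covariance_matrix(params, t, dose) + params.noise_c**2 * np.eye(t.size)
        for idx in range(n_datasets):
            bd = _total_population_paths(params, dose, t, gen, n, n_samples).astype(float)
            if params.noise_c > 0:
                bd += gen.normal(0.0, params.noise_c, size=bd.shape)
            gauss = gen.multivariate_normal(mu, cov, size=n_samples, method="cholesky")
            rows.append(
                {
                    "n_initial": n,
                    "dataset_index": idx,
                    "energy_distance": empirical_energy_distance(bd, gauss),
                }
            )
    return pd.DataFrame(rows)


def normalized_ci_widths(widths: dict) -> dict:
    """Normalize per-method CI widths to shares summing to one.

    ``widths`` maps method name -> CI width for the same parameter and
    dataset; at least two finite widths are required and they cannot all
    be zero.
    """
    if len(widths) < 2:
        raise ValueError("need widths from at least two methods")
    vals = np.array([float(v) for v in widths.values()])
    if np.any(~np.isfinite(vals)) or np.any(vals < 0):
        raise ValueError("CI widths must be finite and nonnegative")
    total = vals.sum()
    if total == 0.0:
        raise ValueError("all CI widths are zero; shares undefined")
    return {k: float(v / total) for k, v in zip(widths.keys(), vals)}


def ci_width_rank_test(widths_a, widths_b) -> float:
    """Wilcoxon rank-sum p-value comparing two sets of (normalized) widths.

    Convenience for annotating precision comparisons across datasets; not
    part of the estimation pipeline.
    """
    return float(ranksums(np.asarray(widths_a), np.asarray(widths_b)).pvalue)
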