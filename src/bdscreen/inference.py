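"""Maximum-likelihood deconvolution: multistart fits, bootstrap, selection.

The likelihoods are multimodal in the 6S-dimensional (birth-death) or
(5S+1)-dimensional (deterministic two-noise) parameter space, so fitting is
best-of-``n_restarts`` bounded L-BFGS-B runs from Latin-hypercube starting
points inside a feasible box.  Mixture labels are not identifiable during
optimization; fitted clones are always relabeled in ascending half-effect
dose (most drug-sensitive first) before anything is reported or compared,
which also keeps bootstrap percentile intervals free of label switching.

Fractions are optimized as p_1..p_{S-1} with p_S = 1 - sum (the remaining
clone absorbs the rest); each free fraction lives in [0, 1/2], which covers
every mixture because at most one clone can exceed one half.  Death rates
are optimized through the drug-free net growth rate delta = beta - nu,
matching the coupled feasible region nu in [beta - delta_max, beta].
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import qmc

from .dose_response import HillParams, SubpopulationParams, gr50, hill
from .likelihoods import (
    default_noise_thresholds,
    loglik_endpoints,
    loglik_livecell,
    loglik_phenopop,
)
from .moments import ModelParams, PhenoPopParams
from .simulate import ScreenDataset, simulate_dataset

__all__ = [
    "FitBounds",
    "FitResult",
    "BootstrapResult",
    "fit",
    "bootstrap_cis",
    "select_model",
    "error_metric",
    "n_free_parameters",
]

_B_EPS = 1e-6  # keep Hill asymptote strictly inside (0, 1)
_POS_EPS = 1e-6  # strictly positive lower bound for E, m
_PENALTY = 1e12


@dataclass(frozen=True)
class FitBounds:
    """Feasible box for optimization, one (lo, hi) pair per parameter kind.

    ``delta`` bounds the drug-free net growth rate beta - nu (and the
    growth rate alpha of the deterministic model); ``sigma`` bounds the
    two noise SDs of the deterministic model.
    """

    p: tuple = (0.0, 0.5)
    beta: tuple = (0.0, 1.0)
    delta: tuple = (0.0, 0.1)
    b: tuple = (0.27, 1.0)
    E: tuple = (0.0, 10.0)
    m: tuple = (0.0, 10.0)
    c: tuple = (0.0, 10.0)
    sigma: tuple = (0.0, 2500.0)

    def with_overrides(self, **kw) -> "FitBounds":
        return replace(self, **kw)


#: Feasible intervals used for the simulation studies.
TABLE4_BOUNDS = FitBounds()
#: Wider region intended for experimental-data fits.
TABLE5_BOUNDS = FitBounds(
    p=(0.0, 0.5),
    beta=(0.0, 1.0),
    delta=(0.0, 0.06),
    b=(0.878, 1.0),
    E=(0.0, 50.0),
    m=(0.001, 20.0),
    c=(0.0, 100.0),
    sigma=(0.0, 2500.0),
)
_PRESETS = {"table4": TABLE4_BOUNDS, "table5": TABLE5_BOUNDS}


def resolve_bounds(bounds) -> FitBounds:
    if isinstance(bounds, FitBounds):
        return bounds
    try:
        return _PRESETS[bounds]
    except KeyError:
        raise ValueError(
            f"unknown bounds preset {bounds!r}; use 'table4', 'table5' or a FitBounds"
        ) from None


def n_free_parameters(method: str, S: int) -> int:
    """Free-parameter count: 6S for the birth-death models, 5S+1 for phenopop."""
    return 5 * S + 1 if method == "phenopop" else 6 * S


def _e_indices(method: str, S: int) -> list:
    """Positions of the half-effect doses E_i in the packed vector."""
    stride, offset = (4, 2) if method == "phenopop" else (5, 3)
    return [S - 1 + stride * i + offset for i in range(S)]


def _box(method: str, S: int, fb: FitBounds) -> list:
    """Ordered (lo, hi) optimizer bounds for the packed parameter vector."""
    box = [fb.p] * (S - 1)
    if method == "phenopop":
        for _ in range(S):
            box += [
                fb.delta,
                (max(fb.b[0], _B_EPS), 1.0 - _B_EPS),
                (max(fb.E[0], _POS_EPS), fb.E[1]),
                (max(fb.m[0], _POS_EPS), fb.m[1]),
            ]
        box += [(max(fb.sigma[0], _POS_EPS), fb.sigma[1])] * 2
    else:
        for _ in range(S):
            box += [
                fb.beta,
                fb.delta,
                (max(fb.b[0], _B_EPS), 1.0 - _B_EPS),
                (max(fb.E[0], _POS_EPS), fb.E[1]),
                (max(fb.m[0], _POS_EPS), fb.m[1]),
            ]
        box += [fb.c]
    return box


def _fractions_from_free(free: np.ndarray) -> tuple | None:
    rest = 1.0 - float(np.sum(free))
    if rest < -1e-12:
        return None
    return tuple(free) + (max(rest, 0.0),)


def _unpack_bd(vec: np.ndarray, S: int) -> ModelParams | None:
    fractions = _fractions_from_free(vec[: S - 1])
    if fractions is None:
        return None
    subpops = []
    for i in range(S):
        beta, delta, b, E, m = vec[S - 1 + 5 * i : S - 1 + 5 * (i + 1)]
        subpops.append(
            SubpopulationParams(
                beta=float(beta),
                nu=max(float(beta - delta), 0.0),
                hill=HillParams(float(b), float(E), float(m)),
            )
        )
    return ModelParams(fractions=fractions, subpops=tuple(subpops), noise_c=float(vec[-1]))


def _unpack_pp(vec: np.ndarray, S: int, thresholds: tuple) -> PhenoPopParams | None:
    fractions = _fractions_from_free(vec[: S - 1])
    if fractions is None:
        return None
    alphas, hills = [], []
    for i in range(S):
        a, b, E, m = vec[S - 1 + 4 * i : S - 1 + 4 * (i + 1)]
        alphas.append(float(a))
        hills.append(HillParams(float(b), float(E), float(m)))
    return PhenoPopParams(
        fractions=fractions,
        alphas=tuple(alphas),
        hills=tuple(hills),
        sigma_H=float(vec[-2]),
        sigma_L=float(vec[-1]),
        T_L=thresholds[0],
        D_L=thresholds[1],
    )


def _pack_bd(theta: ModelParams) -> np.ndarray:
    vec = list(theta.fractions[:-1])
    for sp in theta.subpops:
        vec += [sp.beta, sp.beta - sp.nu, sp.hill.b, sp.hill.E, sp.hill.m]
    vec.append(theta.noise_c)
    return np.asarray(vec)


def _pack_pp(theta: PhenoPopParams) -> np.ndarray:
    vec = list(theta.fractions[:-1])
    for a, h in zip(theta.alphas, theta.hills):
        vec += [a, h.b, h.E, h.m]
    vec += [theta.sigma_H, theta.sigma_L]
    return np.asarray(vec)


def _sort_key_pp(theta: PhenoPopParams) -> PhenoPopParams:
    order = np.argsort([h.E for h in theta.hills], kind="stable")
    return PhenoPopParams(
        fractions=tuple(theta.fractions[i] for i in order),
        alphas=tuple(theta.alphas[i] for i in order),
        hills=tuple(theta.hills[i] for i in order),
        sigma_H=theta.sigma_H,
        sigma_L=theta.sigma_L,
        T_L=theta.T_L,
        D_L=theta.D_L,
    )


@dataclass
class FitResult:
    """Outcome of one maximum-likelihood fit.

    ``theta_hat`` is relabeled with clones in ascending half-effect dose.
    ``fractions`` and ``gr50`` are the derived per-clone quantities in that
    canonical order.  ``at_bounds`` names packed parameters whose estimate
    sits on the feasible boundary.
    """

    method: str
    S: int
    theta_hat: object
    loglik: float
    aic: float
    bic: float
    fractions: tuple
    gr50: tuple
    n_restarts_used: int
    converged: bool
    restart_logliks: np.ndarray
    at_bounds: tuple = ()

    def summary(self) -> pd.DataFrame:
        rows = []
        for i, (p, g) in enumerate(zip(self.fractions, self.gr50), start=1):
            rows.append({"clone": i, "initial_fraction": p, "gr50": g})
        return pd.DataFrame(rows)


def _loglik_fn(method: str):
    return {
        "phenopop": loglik_phenopop,
        "end_points": loglik_endpoints,
        "live_cell": loglik_livecell,
    }[method]


def _check_method_vs_data(method: str, data: ScreenDataset) -> None:
    if method not in ("phenopop", "end_points", "live_cell"):
        raise ValueError(f"unknown method {method!r}")
    if method == "live_cell" and data.design.assay != "live_cell":
        raise ValueError(
            "live_cell likelihood requires a live-cell dataset (complete "
            "trajectories per replicate); this dataset is "
            f"{data.design.assay!r}"
        )


def fit(
    data: ScreenDataset,
    method: str = "live_cell",
    S: int = 2,
    bounds="table4",
    n_restarts: int = 20,
    rng=None,
    x0=None,
) -> FitResult:
    """Best-of-restarts maximum-likelihood fit of one model.

    Parameters
    ----------
    data : ScreenDataset
    method : {"phenopop", "end_points", "live_cell"}
    S : number of subpopulations to fit.
    bounds : "table4", "table5" or a FitBounds instance.
    n_restarts : Latin-hypercube starting points.
    rng : seed or Generator controlling the starts (fit is deterministic
        given data and seed).
    x0 : optional ModelParams/PhenoPopParams (or packed vector) used as an
        additional warm start, e.g. for bootstrap refits.
    """
    _check_method_vs_data(method, data)
    if S < 1:
        raise ValueError("S must be >= 1")
    fb = resolve_bounds(bounds)
    box = _box(method, S, fb)
    lo = np.array([b[0] for b in box])
    hi = np.array([b[1] for b in box])
    thresholds = default_noise_thresholds(data.design)
    loglik = _loglik_fn(method)

    def unpack(vec):
        return (
            _unpack_pp(vec, S, thresholds)
            if method == "phenopop"
            else _unpack_bd(vec, S)
        )

    def objective(vec):
        theta = unpack(np.clip(vec, lo, hi))
        if theta is None:  # free fractions exceed the simplex
            excess = float(np.sum(vec[: S - 1])) - 1.0
            return _PENALTY * (1.0 + excess)
        try:
            value = loglik(theta, data)
        except (FloatingPointError, ValueError, np.linalg.LinAlgError):
            return _PENALTY
        if not np.isfinite(value):
            return _PENALTY
        return -value

    if n_restarts < 1 and x0 is None:
        raise ValueError("need n_restarts >= 1 or an explicit warm start x0")
    gen = np.random.default_rng(rng)
    starts = []
    if n_restarts > 0:
        sampler = qmc.LatinHypercube(d=len(box), seed=gen)
        unit = sampler.random(n_restarts)
        starts_arr = qmc.scale(unit, lo, hi)
        # Half-effect doses live on a log scale (like the dose grid): start
        # them log-uniformly across four decades below the upper bound so
        # low-E (drug-sensitive) basins are actually visited.
        e_cols = _e_indices(method, S)
        for j in e_cols:
            starts_arr[:, j] = np.exp(
                np.log(hi[j]) - 4.0 * np.log(10.0) * (1.0 - unit[:, j])
            )
        # Clone labels are exchangeable, so sorting each start's E values
        # ascending costs nothing and stratifies the starts across
        # (sensitive, ..., resistant) dose decades.
        starts_arr[:, e_cols] = np.sort(starts_arr[:, e_cols], axis=1)
        starts = list(np.clip(starts_arr, lo, hi))
    if x0 is not None:
        packed = (
            np.asarray(x0, dtype=float)
            if isinstance(x0, (np.ndarray, list, tuple))
            else (_pack_pp(x0) if method == "phenopop" else _pack_bd(x0))
        )
        starts.insert(0, np.clip(packed, lo, hi))

    best = None
    logliks = []
    any_success = False
    for s in starts:
        res = minimize(
            objective,
            s,
            method="L-BFGS-B",
            bounds=box,
            options={"maxiter": 400},
        )
        logliks.append(-res.fun)
        any_success = any_success or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or best.fun >= _PENALTY:
        diag = pd.DataFrame({"restart": range(len(logliks)), "loglik": logliks})
        raise RuntimeError(f"all optimization restarts failed:\n{diag}")

    # Iterated local search around the multistart winner: random perturbation
    # with a decaying scale, re-polish, keep improvements.  Cheap (warm runs)
    # and closes the fine-structure gap local searches leave in the higher-
    # dimensional fits.
    e_idx = set(_e_indices(method, S))
    n_refine = 0 if n_restarts <= 1 else max(6, len(box) // 2)
    for i in range(n_refine):
        scale = 0.25 * (0.3 ** (i / max(n_refine - 1, 1)))
        prop = best.x.copy()
        for j in range(len(box)):
            if j in e_idx:
                prop[j] *= np.exp(gen.normal(0.0, 2.0 * scale))
            else:
                prop[j] += gen.normal(0.0, scale * (hi[j] - lo[j]))
        prop = np.clip(prop, lo, hi)
        res = minimize(
            objective, prop, method="L-BFGS-B", bounds=box, options={"maxiter": 400}
        )
        logliks.append(-res.fun)
        if res.fun < best.fun:
            best = res

    x_hat = np.clip(best.x, lo, hi)
    theta_hat = unpack(x_hat)
    theta_hat = (
        _sort_key_pp(theta_hat) if method == "phenopop" else theta_hat.reordered_by_E()
    )
    ll = -float(best.fun)
    k = n_free_parameters(method, S)
    n_obs = int(np.prod(data.design.shape))
    hills = theta_hat.hills if method == "phenopop" else [sp.hill for sp in theta_hat.subpops]
    at = tuple(
        int(i)
        for i in np.where(
            (np.abs(x_hat - lo) < 1e-9 * (1 + np.abs(lo)))
            | (np.abs(x_hat - hi) < 1e-9 * (1 + np.abs(hi)))
        )[0]
    )
    return FitResult(
        method=method,
        S=S,
        theta_hat=theta_hat,
        loglik=ll,
        aic=-2.0 * ll + 2.0 * k,
        bic=-2.0 * ll + k * np.log(n_obs),
        fractions=tuple(theta_hat.fractions),
        gr50=tuple(gr50(h) for h in hills),
        n_restarts_used=len(starts),
        converged=any_success,
        restart_logliks=np.asarray(logliks),
        at_bounds=at,
    )


def _simulate_from_estimate(theta, method: str, design, gen: np.random.Generator):
    """Parametric bootstrap replicate: a fresh dataset from the fitted model."""
    if method == "phenopop":
        t = np.asarray(design.times, dtype=float)
        d = np.asarray(design.doses, dtype=float)
        mean = np.zeros((t.size, d.size))
        for p_i, a_i, h_i in zip(theta.fractions, theta.alphas, theta.hills):
            mean += p_i * np.exp(np.outer(t, a_i + np.log(hill(d, h_i))))
        mean *= design.n_initial
        sigma = np.where(
            (t[:, None] >= theta.T_L) & (d[None, :] <= theta.D_L),
            theta.sigma_H,
            theta.sigma_L,
        )
        counts = mean[:, :, None] + sigma[:, :, None] * gen.standard_normal(
            design.shape
        )
        return ScreenDataset(design=design, counts=counts)
    return simulate_dataset(theta, design, gen)


def _resample(data: ScreenDataset, gen: np.random.Generator) -> ScreenDataset:
    """Nonparametric bootstrap resample respecting the data's structure.

    Live-cell data: whole trajectories (replicate columns) are the
    exchangeable unit, resampled with replacement independently at each
    dose, preserving within-well time correlation for every fitting
    method.  End-point data: every (time, dose) cell's replicates are
    exchangeable and resampled independently.
    """
    n_t, n_d, n_r = data.design.shape
    counts = np.empty_like(data.counts)
    if data.design.assay == "live_cell":
        for k in range(n_d):
            idx = gen.integers(0, n_r, size=n_r)
            counts[:, k, :] = data.counts[:, k, idx]
    else:
        for j in range(n_t):
            for k in range(n_d):
                idx = gen.integers(0, n_r, size=n_r)
                counts[j, k, :] = data.counts[j, k, idx]
    return ScreenDataset(design=data.design, counts=counts, params=data.params)


def _estimate_row(result: FitResult) -> dict:
    row = {}
    for i, (p, g) in enumerate(zip(result.fractions, result.gr50), start=1):
        row[f"p_{i}"] = p
        row[f"gr50_{i}"] = g
    if result.method == "phenopop":
        th = result.theta_hat
        for i, (a, h) in enumerate(zip(th.alphas, th.hills), start=1):
            row.update({f"alpha_{i}": a, f"b_{i}": h.b, f"E_{i}": h.E, f"m_{i}": h.m})
        row.update({"sigma_H": th.sigma_H, "sigma_L": th.sigma_L})
    else:
        th = result.theta_hat
        for i, sp in enumerate(th.subpops, start=1):
            row.update(
                {
                    f"beta_{i}": sp.beta,
                    f"nu_{i}": sp.nu,
                    f"b_{i}": sp.hill.b,
                    f"E_{i}": sp.hill.E,
                    f"m_{i}": sp.hill.m,
                }
            )
        row["c"] = th.noise_c
    return row


@dataclass
class BootstrapResult:
    """Percentile bootstrap summary of one fit.

    ``table`` has one row per reported quantity (initial fractions, GR50s
    and raw parameters, clones in ascending-E order) with the point
    estimate and 2.5/97.5 percentile bounds; ``estimates`` keeps every
    bootstrap replicate's relabeled estimates.
    """

    method: str
    S: int
    n_boot: int
    point: FitResult
    estimates: pd.DataFrame
    table: pd.DataFrame
    n_failed: int = 0

    def ci_width(self, param: str) -> float:
        row = self.table.loc[self.table["parameter"] == param]
        if row.empty:
            raise KeyError(param)
        return float(row["upper"].iloc[0] - row["lower"].iloc[0])


def bootstrap_cis(
    data: ScreenDataset,
    method: str = "live_cell",
    S: int = 2,
    n_boot: int = 100,
    bounds="table4",
    n_restarts: int = 20,
    refit_restarts: int = 3,
    scheme: str = "nonparametric",
    rng=None,
) -> BootstrapResult:
    """Percentile bootstrap confidence intervals via full refits.

    The point estimate uses ``n_restarts`` cold starts.  With the default
    ``scheme="nonparametric"`` each bootstrap replicate resamples observed
    replicates with replacement, keyed to the data's correlation
    structure: whole trajectories per dose for live-cell data (every
    fitting method sees the within-well time correlation preserved),
    replicate indices per (time, dose) cell for end-point data.
    ``scheme="parametric"`` instead simulates each replicate dataset from
    the fitted model on the same design.  Each replicate is refit
    warm-started from the point estimate plus ``refit_restarts`` fresh
    Latin-hypercube starts (a budget-friendly stand-in for a full cold
    multistart).  Replicates whose refit fails are dropped and counted in
    ``n_failed``.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if scheme not in ("parametric", "nonparametric"):
        raise ValueError(f"unknown bootstrap scheme {scheme!r}")
    gen = np.random.default_rng(rng)
    point = fit(
        data, method=method, S=S, bounds=bounds, n_restarts=n_restarts,
        rng=gen.integers(2**31),
    )
    rows, n_failed = [], 0
    for _ in range(n_boot):
        if scheme == "parametric":
            sample = _simulate_from_estimate(
                point.theta_hat, method, data.design, gen
            )
        else:
            sample = _resample(data, gen)
        try:
            res = fit(
                sample,
                method=method,
                S=S,
                bounds=bounds,
                n_restarts=refit_restarts,
                rng=gen.integers(2**31),
                x0=point.theta_hat,
            )
        except RuntimeError:
            n_failed += 1
            continue
        rows.append(_estimate_row(res))
    if not rows:
        raise RuntimeError("every bootstrap refit failed")
    estimates = pd.DataFrame(rows)
    point_row = _estimate_row(point)
    table = pd.DataFrame(
        {
            "parameter": estimates.columns,
            "point": [point_row[c] for c in estimates.columns],
            "lower": estimates.quantile(0.025).to_numpy(),
            "upper": estimates.quantile(0.975).to_numpy(),
        }
    )
    return BootstrapResult(
        method=method,
        S=S,
        n_boot=len(rows),
        point=point,
        estimates=estimates,
        table=table,
        n_failed=n_failed,
    )


def select_model(
    data: ScreenDataset,
    method: str = "live_cell",
    S_candidates=(1, 2, 3),
    criterion: str = "aic",
    bounds="table4",
    n_restarts: int = 20,
    rng=None,
) -> pd.DataFrame:
    """Fit each candidate subpopulation count and rank by AIC or BIC.

    Returns one row per S with loglik, AIC and BIC, sorted by the chosen
    criterion (best first); the negative-loglik column supports elbow
    inspection.  The fitted results are attached in the ``fit`` column.
    """
    if not len(tuple(S_candidates)):
        raise ValueError("S_candidates must be nonempty")
    if criterion not in ("aic", "bic"):
        raise ValueError("criterion must be 'aic' or 'bic'")
    gen = np.random.default_rng(rng)
    rows = []
    for S in S_candidates:
        res = fit(
            data, method=method, S=S, bounds=bounds, n_restarts=n_restarts,
            rng=gen.integers(2**31),
        )
        rows.append(
            {
                "S": S,
                "loglik": res.loglik,
                "neg_loglik": -res.loglik,
                "n_params": n_free_parameters(method, S),
                "aic": res.aic,
                "bic": res.bic,
                "fit": res,
            }
        )
    return pd.DataFrame(rows).sort_values(criterion, kind="stable").reset_index(drop=True)


def error_metric(x_hat: float, x_true: float) -> float:
    """Absolute log-ratio error ``|log(x_true / x_hat)|``.

    Scale-free and symmetric in over/under-estimation on the log scale;
    both arguments must be positive.
    """
    if x_hat <= 0 or x_true <= 0:
        raise ValueError("error_metric requires positive arguments")
    return abs(float(np.log(x_true / x_hat)))
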