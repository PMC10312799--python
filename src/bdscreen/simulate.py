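"""Exact simulation of the birth-death drug-screen model and synthetic data.

The linear birth-death transition law over any interval is known in closed
form: each ancestor cell leaves 0 descendants with the extinction
probability, or a geometric number conditional on survival.  Summing over
ancestors gives a binomial number of surviving lineages and a negative
binomial total, so whole populations are advanced in O(1) draws per
interval regardless of size.  A Gillespie stochastic-simulation-algorithm
sampler is kept as an independent (slow) reference for testing.

``simulate_dataset`` produces complete synthetic drug screens: one
trajectory per (dose, replicate) for live-cell assays (counts correlated
across time), or an independent realization per (time, dose, replicate)
for end-point assays, plus i.i.d. Gaussian observation noise N(0, c^2).

``draw_parameters`` draws generating parameter vectors uniformly from the
simulation-study ranges (two- and three-subpopulation versions).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .dose_response import HillParams, SubpopulationParams, death_rate
from .moments import ModelParams, validate_time_grid

__all__ = [
    "ExperimentDesign",
    "ScreenDataset",
    "default_design",
    "simulate_bd_path",
    "simulate_bd_counts",
    "simulate_bd_path_gillespie",
    "simulate_dataset",
    "draw_parameters",
    "largest_remainder_allocation",
]

Assay = Literal["end_point", "live_cell"]


@dataclass(frozen=True)
class ExperimentDesign:
    """Layout of a drug screen: time grid, dose grid, replicates, seeding.

    ``times`` are the positive observation times; time 0 is implicit and
    carries the known initial count ``n_initial``.
    """

    times: tuple
    doses: tuple
    n_replicates: int
    n_initial: int
    assay: Assay = "live_cell"

    def __post_init__(self) -> None:
        t = validate_time_grid(self.times)
        object.__setattr__(self, "times", tuple(t))
        d = tuple(float(x) for x in self.doses)
        if any(x < 0 for x in d):
            raise ValueError("doses must be >= 0")
        object.__setattr__(self, "doses", d)
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        if not (isinstance(self.n_initial, (int, np.integer)) and self.n_initial > 0):
            raise ValueError("n_initial must be a positive integer")
        if self.assay not in ("end_point", "live_cell"):
            raise ValueError(f"unknown assay type {self.assay!r}")

    @property
    def shape(self) -> tuple:
        return (len(self.times), len(self.doses), self.n_replicates)


def default_design(assay: Assay = "live_cell", n_initial: int = 1000) -> ExperimentDesign:
    """Default in-silico screen mirroring a live-cell imaging setup.

    14 time points (t=0 plus 3, 6, ..., 39), 11 doses (vehicle control plus
    10 log-spaced concentrations spanning 0.01-10, bracketing typical
    half-effect doses of sensitive and resistant clones), 14 replicates,
    1000 seeded cells.  With the slow net growth rates of the study ranges
    (0-0.1 per unit time) the horizon gives up to ~e^4 drug-free expansion,
    matching the few doublings of a real live-cell screen and leaving
    minority clones enough time to become visible.
    """
    return ExperimentDesign(
        times=tuple(3.0 * k for k in range(1, 14)),
        doses=(0.0,) + tuple(np.logspace(-2, 1, 10)),
        n_replicates=14,
        n_initial=n_initial,
        assay=assay,
    )


@dataclass(frozen=True)
class ScreenDataset:
    """Observed (noisy) total cell counts of one screen.

    ``counts`` has shape (n_times, n_doses, n_replicates) aligned with the
    design grids.  When synthetic, ``params`` and ``seed`` record provenance.
    """

    design: ExperimentDesign
    counts: np.ndarray
    params: ModelParams | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        if c.shape != self.design.shape:
            raise ValueError(
                f"counts shape {c.shape} does not match design shape {self.design.shape}"
            )
        if not np.all(np.isfinite(c)):
            raise ValueError("counts must be finite")
        object.__setattr__(self, "counts", c)

    def to_frame(self, include_t0: bool = True) -> pd.DataFrame:
        """Long-format table with columns time,dose,replicate,cell_count."""
        t = np.asarray(self.design.times)
        d = np.asarray(self.design.doses)
        r = np.arange(1, self.design.n_replicates + 1)
        tt, dd, rr = np.meshgrid(t, d, r, indexing="ij")
        frame = pd.DataFrame(
            {
                "time": tt.ravel(),
                "dose": dd.ravel(),
                "replicate": rr.ravel(),
                "cell_count": self.counts.ravel(),
            }
        )
        if include_t0:
            dd0, rr0 = np.meshgrid(d, r, indexing="ij")
            head = pd.DataFrame(
                {
                    "time": 0.0,
                    "dose": dd0.ravel(),
                    "replicate": rr0.ravel(),
                    "cell_count": float(self.design.n_initial),
                }
            )
            frame = pd.concat([head, frame], ignore_index=True)
        return frame


def largest_remainder_allocation(n: int, fractions) -> np.ndarray:
    """Integer seeding counts n*p_i, rounded so they sum exactly to ``n``."""
    fr = np.asarray(fractions, dtype=float)
    raw = n * fr
    base = np.floor(raw).astype(int)
    short = n - int(base.sum())
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:short]] += 1
    return base


def _transition_probs(beta: float, nu_d: float, dt: float) -> tuple:
    """Extinction probability p0 and geometric parameter eta over ``dt``.

    Per ancestor: extinct w.p. p0, else the clone size is geometric on
    {1, 2, ...} with failure parameter eta.  Critical case beta == nu_d
    handled separately (p0 = eta = beta dt / (1 + beta dt)).
    """
    lam = beta - nu_d
    if beta == 0.0 and nu_d == 0.0:
        return 0.0, 0.0
    if lam == 0.0:
        q = beta * dt / (1.0 + beta * dt)
        return q, q
    g = np.expm1(lam * dt)
    denom = beta * g + lam
    return nu_d * g / denom, beta * g / denom


def _advance(counts: np.ndarray, p0: float, eta: float, rng: np.random.Generator) -> np.ndarray:
    """Advance an array of independent populations by one interval."""
    counts = np.asarray(counts)
    survivors = rng.binomial(counts, 1.0 - p0)
    if eta <= 0.0:
        return survivors
    total = survivors.astype(np.int64)
    mask = survivors > 0
    if np.any(mask):
        total[mask] += rng.negative_binomial(survivors[mask], 1.0 - eta)
    return total


def simulate_bd_counts(
    sp: SubpopulationParams,
    d: float,
    n0: int,
    times,
    rng: np.random.Generator,
    n_paths: int = 1,
) -> np.ndarray:
    """Sample ``n_paths`` exact birth-death trajectories over a time grid.

    Returns an integer array of shape (n_paths, n_times); the process is
    Markov so each interval is drawn from the exact transition law.
    State 0 is absorbing.
    """
    t = validate_time_grid(times)
    nu_d = float(death_rate(d, sp))
    state = np.full(n_paths, int(n0), dtype=np.int64)
    out = np.empty((n_paths, t.size), dtype=np.int64)
    prev = 0.0
    for j, tj in enumerate(t):
        p0, eta = _transition_probs(sp.beta, nu_d, tj - prev)
        state = _advance(state, p0, eta, rng)
        out[:, j] = state
        prev = tj
    return out


def simulate_bd_path(
    sp: SubpopulationParams, d: float, n0: int, times, rng: np.random.Generator
) -> np.ndarray:
    """Single exact birth-death trajectory (see ``simulate_bd_counts``)."""
    return simulate_bd_counts(sp, d, n0, times, rng, n_paths=1)[0]


def simulate_bd_path_gillespie(
    sp: SubpopulationParams, d: float, n0: int, times, rng: np.random.Generator
) -> np.ndarray:
    """Event-by-event Gillespie reference sampler (slow; test oracle only)."""
    t_grid = validate_time_grid(times)
    nu_d = float(death_rate(d, sp))
    total_rate_per_cell = sp.beta + nu_d
    out = np.empty(t_grid.size, dtype=np.int64)
    x, t, j = int(n0), 0.0, 0
    while j < t_grid.size:
        if x == 0 or total_rate_per_cell == 0.0:
            out[j:] = x
            break
        t += rng.exponential(1.0 / (x * total_rate_per_cell))
        while j < t_grid.size and t > t_grid[j]:
            out[j] = x
            j += 1
        if j >= t_grid.size:
            break
        x += 1 if rng.random() < sp.beta / total_rate_per_cell else -1
    return out


def _total_population_paths(
    params: ModelParams,
    d: float,
    times,
    rng: np.random.Generator,
    n_initial: int,
    n_paths: int,
) -> np.ndarray:
    """Exact total-count trajectories of the mixture, shape (n_paths, n_times)."""
    seeds = largest_remainder_allocation(n_initial, params.fractions)
    total = np.zeros((n_paths, len(tuple(np.atleast_1d(times)))), dtype=np.int64)
    for n_i, sp in zip(seeds, params.subpops):
        if n_i > 0:
            total += simulate_bd_counts(sp, d, int(n_i), times, rng, n_paths)
    return total


def simulate_dataset(
    params: ModelParams,
    design: ExperimentDesign,
    rng: np.random.Generator | int,
) -> ScreenDataset:
    """Generate one complete synthetic screen under the birth-death model.

    Live-cell assays observe one population trajectory per (dose, replicate)
    at every grid time (counts positively correlated in time); end-point
    assays use an independent population per (time, dose, replicate).
    Gaussian observation noise N(0, c^2) is added to every count and may
    produce non-integer or negative observations, which are kept as-is.
    """
    seed = int(rng) if isinstance(rng, (int, np.integer)) else None
    gen = np.random.default_rng(rng) if seed is not None else rng
    n_t, n_d, n_r = design.shape
    counts = np.empty((n_t, n_d, n_r), dtype=float)
    for k, dose in enumerate(design.doses):
        if design.assay == "live_cell":
            paths = _total_population_paths(
                params, dose, design.times, gen, design.n_initial, n_r
            )
            counts[:, k, :] = paths.T
        else:
            for j, tj in enumerate(design.times):
                counts[j, k, :] = _total_population_paths(
                    params, dose, (tj,), gen, design.n_initial, n_r
                )[:, 0]
    if params.noise_c > 0:
        counts += gen.normal(0.0, params.noise_c, size=counts.shape)
    return ScreenDataset(design=design, counts=counts, params=params, seed=seed)


# Uniform generation ranges for simulation studies: two-subpopulation table
# and the three-subpopulation overlay (fractions and half-effect doses).
RANGES_2POP = {
    "p_s": (0.3, 0.5),
    "beta": (0.0, 1.0),
    "b": (0.8, 0.9),
    "E_s": (0.05, 0.1),
    "E_r": (0.75, 2.5),
    "m": (1.5, 5.0),
    "c": (0.0, 10.0),
}
RANGES_3POP = {
    "p_s": (0.167, 0.333),
    "p_m": (0.167, 0.333),
    "E_s": (0.0313, 0.0625),
    "E_m": (0.25, 0.375),
    "E_r": (1.25, 2.5),
}


def draw_parameters(
    S: int, rng: np.random.Generator | int, ranges: dict | None = None
) -> ModelParams:
    """Draw a generating parameter vector uniformly from the study ranges.

    For two clones: sensitive fraction in [0.3, 0.5]; per clone, division
    rate beta in [0, 1], death rate nu uniform on [beta - 0.1, beta]
    truncated at 0, Hill asymptote b in [0.8, 0.9], steepness m in
    [1.5, 5], half-effect dose E in [0.05, 0.1] (sensitive) or [0.75, 2.5]
    (resistant); observation noise c in [0, 10].  For three clones the
    sensitive/moderate fractions are in [0.167, 0.333] and the half-effect
    doses in [0.0313, 0.0625] / [0.25, 0.375] / [1.25, 2.5].  Clones are
    returned sensitive-first (ascending E).
    """
    gen = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    r = dict(RANGES_2POP)
    if S == 3:
        r.update(RANGES_3POP)
    elif S != 2:
        raise ValueError("parameter ranges are defined for S = 2 or 3 subpopulations")
    if ranges:
        r.update(ranges)

    def u(key):
        lo, hi = r[key]
        return gen.uniform(lo, hi)

    if S == 2:
        p_s = u("p_s")
        fractions = (p_s, 1.0 - p_s)
        e_keys = ("E_s", "E_r")
    else:
        p_s, p_m = u("p_s"), u("p_m")
        fractions = (p_s, p_m, 1.0 - p_s - p_m)
        e_keys = ("E_s", "E_m", "E_r")

    subpops = []
    for key in e_keys:
        beta = u("beta")
        nu = max(0.0, gen.uniform(beta - 0.1, beta))
        subpops.append(
            SubpopulationParams(
                beta=beta,
                nu=nu,
                hill=HillParams(b=u("b"), E=u(key), m=u("m")),
            )
        )
    return ModelParams(fractions=fractions, subpops=tuple(subpops), noise_c=u("c"))
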