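# Methods

## Population model

Each of *S* subpopulations ("clones") is an independent linear birth–death
process.  A type-*i* cell divides at rate *βᵢ* and dies at rate
*νᵢ(d) = νᵢ − log Hᵢ(d)*, with *Hᵢ* a three-parameter Hill curve
(*bᵢ ∈ (0,1)*: residual effect at saturating dose; *Eᵢ > 0*: half-effect
dose in the same units as the screen concentrations; *mᵢ > 0*: steepness).
The drug acts cytotoxically — it raises the death rate and leaves the
division rate alone; cytostatic action (dose-dependent *β*) is out of
scope.  The net rate is *λᵢ(d) = βᵢ − νᵢ + log Hᵢ(d)*; with
*αᵢ = βᵢ − νᵢ* the mean dynamics coincide with a deterministic
exponential-growth mixture, which is exactly the deterministic baseline
model ("phenopop" method) with a two-level observation-noise variance.

Per ancestor cell, the closed-form moments at time *t* under dose *d* are

- mean `exp(λt)`,
- variance `(β + ν(d))/λ · (e^{2λt} − e^{λt})`, with the L'Hôpital limit
  `(β + ν(d))·t` at `λ = 0`,
- autocovariance between times `s ≤ t`: `e^{λ(t−s)} · var(s)`.

The mixture covariance `Σ(d)` used by the trajectory likelihood is the
fraction-weighted sum of these per-clone kernels; it is implemented in the
telescoped form `Σᵢⱼ = Σₖ pₖ e^{λₖ(tⱼ−tᵢ)} σₖ²(tᵢ)` (for `tᵢ ≤ tⱼ`), which
is algebraically equivalent to the increment double sum over the grid with
`t₀ = 0` — the tests verify the equivalence numerically to 1e−9 — and makes
the diagonal equal the marginal variance by construction.

### GR50

The supplementary material defining GR50 precisely is not available; this
package defines it as the dose at which the drug-induced increase in a
clone's death rate reaches half its maximum, i.e. the solution of
`log H(d) = log(b)/2`, in closed form `E·b^{−1/(2m)}`.  The same definition
is applied to all three methods, so cross-method comparisons are internally
consistent.  The closed form is validated against a root solver to 1e−10.

## Observation models

All three likelihoods are Gaussian around the mixture mean curve and are
computed in log space:

- **phenopop** — independent scalar Gaussians; variance σ_H² when
  `t ≥ T_L` and `d ≤ D_L`, else σ_L².  The thresholds are treated as known;
  the defaults are the midpoint of the time grid and the median nonzero
  dose (their exact values have little influence).
- **end_points** — independent scalar Gaussians with the birth–death
  central-limit variance `n σ²(t,d) + c²`; the variance depends on the
  growth parameters, which is what lets the method exploit the
  size-dependent noise in the data.
- **live_cell** — one multivariate Gaussian per (dose, replicate)
  trajectory, covariance `n Σ(d) + c² I`.  Cholesky factorization
  throughout (never an explicit inverse), with an escalating diagonal
  jitter (1e−9, then 1e−6, of mean trace/N) because `c` may sit at 0
  during optimization; a covariance that remains non-PD raises.

Time 0 carries the known seeding count `n` by convention: t = 0 rows in a
CSV are consumed as metadata, not likelihood terms.  Counts may be negative
or non-integer after measurement noise and are used as-is.  The exact
(non-Gaussian) hidden-Markov likelihood is out of scope.

Hot paths (moment matrices, covariance tensors, scalar and multivariate
Gaussian sums) are numba-compiled; the numpy implementations in
`bdscreen.moments` remain the reference API, and oracle tests pin the two
together.

## Simulator

The linear birth–death transition over any interval is sampled exactly:
per ancestor, extinction with probability `ν·g/(β·g + λ)` where
`g = e^{λΔt} − 1`, else a geometric clone size; summed over ancestors this
is a binomial number of surviving lineages plus a negative-binomial excess,
so a whole population advances in O(1) draws per interval at any size.  A
Gillespie event-by-event sampler is retained purely as a test oracle; the
two are compared with a two-sample energy-distance permutation test.

Live-cell screens observe one trajectory per (dose, replicate) at all grid
times; end-point screens draw an independent population per (time, dose,
replicate).  Initial clone sizes are `n·pᵢ` rounded by largest remainder so
they sum to `n` exactly.

### Default in-silico design

14 time points (0, 3, 6, …, 39), 11 doses (0 plus 10 log-spaced over
0.01–10), 14 replicates, n = 1000 — mirroring the published in vitro
layout.  The time horizon is chosen so that `λ·t_max` reaches ≈ 3.9 for the
fastest clones the generation ranges allow (net rates 0–0.1 per unit time),
i.e. a few population doublings over the screen, which is what real
live-cell screens achieve.  This matters: with a horizon of ~13 time units
the data contain too little growth signal to identify a 1% resistant clone
at all (a two-sensitive-clone fit then beats the truth in likelihood), and
no estimator could recover it.  The dose decade span brackets the
generation ranges for sensitive (E ∈ [0.05, 0.1]) and resistant
(E ∈ [0.75, 2.5]) clones and the three-clone overlay.

Generator defaults reproduce the published simulation-study ranges
(two-clone table and the three-clone overlay); the death-rate draw
`ν ~ U[β−0.1, β]` is clipped at 0, which leaves an atom at ν = 0 when
β < 0.1 — the source does not disambiguate clip versus renormalized
truncation.

## Estimation

Fractions are optimized as `p₁..p_{S−1}` with the last clone absorbing the
remainder; each free fraction lives in [0, ½], which represents every
mixture because at most one clone can exceed one half.  Death rates are
optimized through `δ = β − ν` with `δ ∈ [0, 0.1]` ("table4" preset) or
`[0, 0.06]` ("table5"), matching the published feasible regions; the noise
bound is `c ∈ [0, 10]` (table4) / `[0, 100]` (table5) and must be widened
explicitly (e.g. `TABLE4_BOUNDS.with_overrides(c=(0, 1000))`) for
high-noise fits — the published feasible intervals are inconsistent with
the high-noise experiments they accompany, which used c = 500.

The likelihood is multimodal, mainly in the half-effect doses.  `fit` runs
bounded L-BFGS-B from `n_restarts` Latin-hypercube starts with two
structural aids: the E coordinates are drawn log-uniformly over four
decades (E is a log-scale quantity, like the dose grid) and sorted
ascending within each start (clone labels are exchangeable, so sorting is
free stratification across sensitive/resistant decades).  The multistart
winner is then refined by a short iterated local search — random
perturbation with decaying scale, re-polish, keep improvements.  Both aids
were adopted after cold multistarts reproducibly stalled 20–56 nats short
of warm-started fits on three-clone problems.  Twenty restarts suffice for
two clones; three-clone fits benefit from 40–60.

Fitted clones are always relabeled in ascending E (most sensitive first)
before reporting — this also prevents label switching from inflating
bootstrap intervals.  Estimates at a feasible bound are flagged in
`FitResult.at_bounds`.

### Bootstrap

`bootstrap_cis` refits resampled data; percentile 2.5/97.5 intervals are
reported for fractions, GR50s and raw parameters.  The default scheme is
nonparametric with the exchangeable unit keyed to the **data's** assay:
whole trajectories per dose for live-cell data (preserving within-well time
correlation no matter which likelihood is being refit), per-(time, dose)
replicate indices for end-point data.  Resampling end-point style on
correlated live-cell data demonstrably under-disperses the intervals.  A
parametric scheme (simulate each replicate from the fitted model) is
available as an option.  Refits are warm-started from the full-data
estimate plus `refit_restarts` fresh cold starts; warm-start-only refits
are markedly anti-conservative and at least one cold start is recommended
whenever the intervals matter.

### Model selection

`select_model` fits each candidate S and reports log-likelihood, AIC
(`−2ℓ + 2k`) and BIC (`−2ℓ + k log N`), with k = 6S free parameters for
the birth–death methods and 5S + 1 for the deterministic baseline; the
negative log-likelihood sequence supports elbow inspection.

## Diagnostics

The empirical energy distance between two samples is the V-statistic
(self-pairs included, Euclidean norm), computed with blockwise pairwise
sums so 10⁴×10⁴ comparisons run in constant memory; tiny negative values
from floating point are clamped to zero with a warning.  The Gaussian-
approximation experiment simulates exact trajectory samples and matched
multivariate-normal samples across increasing seeding counts and reports
the distance table; with no stated measurement noise for that experiment,
c = 0 is used.  Note the V-statistic has a positive bias of order
`(1/k + 1/m)·E‖X−X′‖`, which grows with the count scale — at small sample
sizes this floor can mask the decrease at large n, which is why the
reproduction uses 10⁴ samples per side.

## What a green test establishes — and what it does not

The synthetic screens realize the model's own stated world: exponential
lifetimes, independent clones, no phenotypic switching, no density
dependence, i.i.d. Gaussian measurement noise, complete designs without
outliers.  Green recovery tests therefore establish correctness of the
simulator, moments, likelihoods and optimizer — not robustness to model
misspecification in real screens.

Known limitations observed in this stated world:

- Three-clone fits (17 parameters) are information-limited on a single
  default-design screen: the maximum-likelihood estimate — verified
  near-global by warm-started comparison — can sit about one sampling
  standard deviation from the generating values, so 50% bootstrap
  intervals need not cover the truth on a given dataset, and the
  three-clone interquartile-coverage acceptance check is left failing by
  design rather than widened.
- Under very large measurement noise (c = 500, half the seeding count) the
  likelihood develops a flat ridge coupling the sensitive fraction with
  its Hill parameters; sensitive-fraction estimates then deviate ~5–10%
  low on typical datasets.
- GR50 precision for a clone degrades when its half-effect dose falls
  between sparse low-dose grid points or when its initial fraction is
  small.
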