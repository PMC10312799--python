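# bdscreen

Deconvolution of bulk drug-screen cell counts into tumor subpopulations,
using stochastic linear birth–death process models.

## The problem

High-throughput drug screens measure total cell counts of a tumor sample
across a grid of drug concentrations, time points and replicate wells.
Tumors are usually mixtures of clones with different drug sensitivities, and
the bulk dose–response curve of the mixture can hide a small resistant clone
that later drives relapse.  `bdscreen` estimates, for each clone *i* of a
mixture of *S* clones: its initial fraction *pᵢ*, its division and death
rates *βᵢ*, *νᵢ*, and its dose–response parameters — from bulk counts alone.

## The model

Each clone is a linear birth–death process: every cell divides at rate
*βᵢ ≥ 0* and dies at rate *νᵢ(d) = νᵢ − log Hᵢ(d)*, where

> *Hᵢ(d) = bᵢ + (1 − bᵢ) / (1 + (d/Eᵢ)^{mᵢ})*

is a three-parameter Hill curve, so a cytotoxic drug raises the death rate
from *νᵢ* (no drug) to *νᵢ − log bᵢ* (saturating dose).  The net growth rate
is *λᵢ(d) = βᵢ − νᵢ + log Hᵢ(d)*.  A clone's **GR50** — the dose at which
the drug's effect on its death rate is half-maximal — is
*Eᵢ · bᵢ^{−1/(2mᵢ)}*.

Starting from *n·pᵢ* cells, clone *i* has mean *n pᵢ e^{λᵢ(d)t}* and
variance *n pᵢ (βᵢ+νᵢ(d))/λᵢ(d) · (e^{2λᵢ(d)t} − e^{λᵢ(d)t})* at time *t*;
for large *n* a central-limit argument makes the total count vector over the
time grid Gaussian with a known temporal covariance *nΣ(d)*.  Observed
counts add i.i.d. Gaussian measurement noise N(0, c²).  Three maximum-
likelihood methods are provided:

| method | variance model | use for |
|---|---|---|
| `live_cell` | multivariate Gaussian, covariance *nΣ(d) + c²I* | live-cell imaging (same well observed repeatedly) |
| `end_points` | independent Gaussians, variance *nσ²(t,d) + c²* | destructive end-point assays |
| `phenopop` | deterministic growth, two fixed noise levels σ_H/σ_L | baseline deterministic deconvolution |

Model size *S* is chosen by AIC/BIC; uncertainty comes from bootstrap
refits; an energy-distance diagnostic checks the Gaussian approximation
against exact birth–death simulation.

## Worked example

Simulate a balanced two-clone screen (published case-study parameters) on
the default design — 14 time points, 11 doses including vehicle control,
14 replicate wells, 1000 seeded cells — and deconvolve it:

```python
import numpy as np
from bdscreen import (
    HillParams, ModelParams, SubpopulationParams,
    SubpopulationDeconvolution, default_design, simulate_dataset,
)

truth = ModelParams(
    fractions=(0.4856, 0.5144),
    subpops=(
        SubpopulationParams(beta=0.1163, nu=0.0176,
                            hill=HillParams(b=0.8262, E=0.0674, m=4.5404)),
        SubpopulationParams(beta=0.4624, nu=0.3978,
                            hill=HillParams(b=0.8062, E=1.5776, m=4.2002)),
    ),
    noise_c=1.2103,
)
data = simulate_dataset(truth, default_design("live_cell"), rng=11)

model = SubpopulationDeconvolution(method="live_cell", n_populations=2,
                                   n_restarts=20, random_state=0)
model.fit(data)
print("initial fractions:", np.round(model.fractions_, 4))
print("GR50 doses:       ", np.round(model.gr50_, 4))
print("log-likelihood:   ", round(model.loglik_, 1))
print("AIC:              ", round(model.aic_, 1))
```

Output:

```
initial fractions: [0.4885 0.5115]
GR50 doses:        [0.069  1.6024]
log-likelihood:    -10551.3
AIC:               21126.7
```

The sensitive clone (smaller half-effect dose; clones are always reported
in ascending *E*) is estimated at 48.9% of the seeded population against a
true 48.6%, and the two GR50 estimates (0.069 and 1.60) sit next to the
generating values 0.0688 and 1.619 — the drug kills the sensitive clone at
a ~23× lower dose.  `model.bootstrap(data, n_boot=100)` adds percentile
confidence intervals, and `bdscreen.select_model(data, S_candidates=(1,2,3))`
ranks clone counts by AIC.

The same pipeline is available from the shell:

```bash
bdscreen simulate --preset table1 --seed 7 --out screen.csv
bdscreen fit --input screen.csv --method live_cell --S 2 --seed 1 --out-prefix fit
bdscreen select --input screen.csv --S 1,2,3 --seed 1 --out aic.csv
bdscreen validate-gaussian --seed 1 --out energy.csv
```

## Acceptance script

`scripts/acceptance.py` re-runs the four headline case studies from
scratch: it simulates one screen per published parameter vector (balanced
two-clone mixture; 99:1 unbalanced mixture; three-clone mixture; high-noise
c = 500 mixture), fits the corresponding likelihood with a cold multistart,
and writes the estimated initial fraction of the most drug-sensitive clone
for each case:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

- `bdscreen.dose_response` — Hill curves, dose-dependent rates, GR50
- `bdscreen.moments` — closed-form birth–death means/variances/covariances
- `bdscreen.simulate` — exact simulation, synthetic screens, parameter draws
- `bdscreen.likelihoods` — the three log-likelihoods
- `bdscreen.inference` — multistart MLE, bootstrap CIs, AIC/BIC selection
- `bdscreen.estimators` — scikit-learn style front end
- `bdscreen.diagnostics` — energy distance, CI-width comparisons
- `bdscreen.io` / `bdscreen.cli` — CSV interchange and the `bdscreen` command

See `docs/methods.md` for modelling assumptions, numerical choices and
known limitations.
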