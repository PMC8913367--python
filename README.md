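# ecolegacy

Extinction debts and colonization credits from the lagged response of bird
communities to land-cover change.

Communities rarely track habitat change instantaneously: after a landscape
is modified, local diversity drifts toward the equilibrium the new
landscape can sustain over years to decades. While that lag lasts, a
recently urbanized site still holds species it is committed to losing (an
**extinction debt**), and a site whose habitat improved has species still
to arrive (a **colonization credit**). `ecolegacy` implements, end to end,
a Bayesian model that quantifies these lags from roadside survey
abundances and two-timepoint land-cover compositions, and attributes the
resulting debts and credits to the type, magnitude and direction of
land-cover change. It is aimed at quantitative ecologists who want to fit
the model to survey-style data or study its behaviour on simulated
landscapes with known ground truth.

## The model

The response is the effective number of species (ENS) — the Hill number of
order q = 1, `exp` of the Shannon index — computed per survey segment from
3-year averaged counts. Observed ENS at segment *s* and timepoint *t* is

    R_{s,t} ~ Normal(mu_{s,t}, sigma)

and the mean at the current timepoint mixes two equilibria:

    mu_{s,t2} = f(x_{s,t2}; beta) * omega + f(x_{s,t1}; beta) * (1 - omega) + g(z_s; alpha)

* `f(x) = exp(beta_0 + sum_i beta_{1,i} x_i + sum_{i<=k} beta_{2,ik} x_i x_k
  + sum_{i!=k} beta_{3,ik} x_i x_k^2)` is a log-linear equilibrium surface
  over the five land-cover fractions (urban, forest, grassland, wetland,
  cropland), optionally reduced to a per-class second-order polynomial.
* `omega = exp(-sum_i sum_z gamma_{i,z} y_{i,z})` is the legacy weight:
  `y_{i,z}` holds the magnitude of the decrease (z = 1) or increase (z = 2)
  of class *i* in percentage points, and `gamma_{i,z} in [0,1]` are
  direction-specific decay rates. `omega = 1` means the community has fully
  equilibrated to the current landscape; `omega -> 0` means the past
  landscape still explains it entirely.
* `g(z)` holds static terms: linear+quadratic temperature, landscape
  heterogeneity (effective number of land-cover types), time of day, and
  observer random effects.

The debt/credit of a site is the equilibrium-minus-legacy prediction,
which reduces to `(1 - omega) (f(x_t2) - f(x_t1))` per posterior draw:
negative values are debts, positive values credits. A Gaussian GLM on the
ten directional change magnitudes, refit across posterior prediction sets
with coefficient resampling, attributes the spatial pattern to its
drivers.

Inference is Hamiltonian Monte Carlo (a NUTS implementation included in
the package, with analytic gradients of the joint posterior), with
truncated-normal priors on slopes, Uniform(0,1) on the decay rates,
rank-normalized split R-hat / ESS diagnostics and PSIS-LOO model
comparison via arviz.

## Worked example

```python
import numpy as np
from ecolegacy import (SimulationConfig, generate_dataset, diversity_table,
                       LegacyDiversityModel)

# a small synthetic study: 60 routes x segments {1,3,5}, known truth
cfg = SimulationConfig(n_routes=60, rng_seed=7)
ds = generate_dataset(cfg)
div = diversity_table(ds.abundance, {"t1": 2001, "t2": 2016})
inputs = ds.inputs(div)

model = LegacyDiversityModel(equilibrium_form="quadratic",
                             chains=2, iterations=400, warmup=400,
                             seed=1).fit(inputs)
print(f"max R-hat      {model.diagnostics_.max_rhat:.3f}")
print(f"fit r          {model.score(inputs):.2f}")
table, shares = model.debts_credits(n_rep=500)
print(f"debt share     {100 * shares['debt_share']:.0f}%")
print(f"credit share   {100 * shares['credit_share']:.0f}%")
```

Output from this exact snippet:

```
max R-hat      1.012
fit r          0.93
debt share     41%
credit share   40%
```

`max R-hat` near 1 says the four chains agree; the fit correlation is the
Pearson r between posterior-mean and observed ENS at the second timepoint;
the shares classify segments by the sign of the posterior-mean
equilibrium-minus-legacy difference (the remainder are unchanged segments,
whose difference is identically zero). A console script `ecolegacy`
exposes the same pipeline (`simulate`, `diversity`, `fit`, `predict`,
`validate`) for shell use.

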