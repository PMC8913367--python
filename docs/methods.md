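# Methods

## Model

`ecolegacy` fits a Gaussian mixed-effects model for the effective number
of species (ENS, Hill q = 1) in which the mean at the later timepoint is a
convex mixture of two equilibrium predictions:

    R_{s,t}  ~  Normal(mu_{s,t}, sigma)
    mu_{s,t2} = f(x_{s,t2}) omega_s + f(x_{s,t1}) (1 - omega_s) + g(z_s)
    mu_{s,t1} = f(x_{s,t1}) + g(z_s)

The t1 mean assumes the community had equilibrated to the first-timepoint
landscape — the identifying assumption that lets a two-timepoint design
separate the equilibrium surface from the lag. Both timepoints enter the
likelihood by default (`include_t1=False` restricts it to t2).

**Equilibrium surface.** `f` is log-linear in the five aggregated
land-cover compositions. Two forms are available: `"quadratic"` (per-class
linear + quadratic terms — 11 coefficients) and `"pairwise"`, which adds
all pairwise products and linear x quadratic interactions (41
coefficients). The pairwise surface nests the quadratic one: zeroing the
off-diagonal second-order and all third-order coefficients reproduces it
exactly (regression-tested).

**Legacy weight.** `omega = exp(-sum gamma_{i,z} y_{i,z})` with the change
magnitudes `y` split by direction (loss slot / gain slot, at most one
nonzero per class, `gain - loss` reconstructing the signed change
bit-exactly). With `gamma in [0,1]` and `y` in percentage points, a rate
of 0.23 yields a past-landscape contribution `1 - omega ~ 0.9` at a
10-point change, and 0.11 yields ~0.67 — the regime the model is designed
to resolve.

**Covariate scaling.** Compositions enter `f` as fractions (0–1) so
standard-normal priors on the coefficients are weakly informative; change
magnitudes enter `omega` in percentage points so the unit-interval bound
on `gamma` spans "no legacy" to "total legacy at a ~10-point change". Both
scalings are configurable (`landcover_scale`, `change_scale`); the
fraction/percent pair is the default because it keeps every prior on a
natural scale.

**Static terms.** Temperature (z-scored; linear >= 0, quadratic <= 0),
landscape heterogeneity (effective number of land-cover types at t2,
unstandardized, range 1–5), time of day (minutes, z-scored), and an
observer random effect with SD `sigma_obs_re`. Heterogeneity reuses the
same Hill-number computation as the species response.

**Priors and truncations.** Intercept and linear land-cover and
temperature effects bounded below at 0; quadratic counterparts bounded
above at 0; interaction terms unbounded; all with Normal(0,1) kernels.
`gamma ~ Uniform(0,1)`. The observer-effect SD carries Gamma(shape 0.001,
rate 0.001) on the SD itself; the (more conventional) same Gamma on the
precision is available by configuration. The residual SD prior is
Half-Normal(0, 5) — a package choice, weakly informative on the ENS scale
(ENS values here are ~2–30). Out-of-bounds parameters yield a log-density
of `-inf` rather than an exception so generic samplers and optimizers can
consume the density directly.

## Inference

The joint posterior and its **analytic gradient** are implemented on an
unconstrained scale (log transforms for sign-constrained and scale
parameters, logit for the decay rates, with log-Jacobians), and sampled by
an in-package No-U-Turn sampler: slice-sampled doubling trees, dual
averaging to a 0.8 acceptance target, and windowed metric adaptation. The
observer block is sampled non-centered (`effect = sigma_obs_re * z`,
`z ~ N(0,1)`), which removes the hierarchical funnel that otherwise stalls
mixing at moderate sample sizes.

Two numerical choices matter in practice:

* **Metric.** The default mass matrix is diagonal. A dense option exists
  and helps on well-identified posteriors (the polynomial features of `f`
  are strongly correlated), but a dense covariance estimated from a short
  warmup window can be worse than no estimate; dense window updates are
  therefore only accepted when the window holds at least `2 x dim` draws.
* **Initialization.** Chains start at mode-jittered points: an L-BFGS
  search on the posterior (using the analytic gradient) finds the mode, a
  finite-difference Hessian gives a Laplace covariance that seeds the
  metric, and chains are dispersed along it. Dispersed-prior starts remain
  the fallback, but with the near-flat Gamma(0.001, 0.001) SD prior they
  occasionally strand a chain on the weakly identified ridge where all
  observer effects shift by a constant against the intercept.

Diagnostics are rank-normalized split R-hat and bulk ESS (arviz);
parameters with R-hat > 1.01 or ESS < 400 are flagged, and sampling is
automatically rerun with doubled iterations while the minimum ESS is below
400 (up to a configured cap; rerun rather than append keeps the draws
valid under any warmup scheme). Model variants are compared by PSIS-LOO
(WAIC reported alongside, Pareto-k warnings counted).

## Debts, credits, drivers, validation

The per-site debt/credit is the equilibrium prediction (legacy weight
forced to 1) minus the legacy prediction. The static term cancels by
construction, leaving `(1 - omega)(f(x_t2) - f(x_t1))` per posterior draw
— implementers should not re-add `g`. Uncertainty is propagated by
repeating the prediction over (by default) 1,000 posterior draws;
summaries are the mean, equal-tailed 95% interval, and a geometric
coefficient of variation computed as `sqrt(exp(ln(sd + 1)^2) - 1)`. That
formula (with the "+1" inside the logarithm) is kept as primary
deliberately; it differs from the conventional geometric CV
(`sqrt(exp(sd_log^2) - 1)` with `sd_log` the SD of logs), which is
available via `cv_form="log_sd"`.

The driver analysis regresses delta values on the ten directional change
magnitudes (11-term Gaussian GLM). Uncertainty propagation is two-stage:
the GLM is refit to `n_glm` posterior prediction sets, each coefficient
vector is resampled `n_param` times from a multivariate normal with the
OLS estimate and covariance (the resampling mechanism is a package choice),
and means and equal-tailed 95% percentile intervals are pooled over the
`n_glm x n_param` values. Either segment-level or grid-aggregated deltas
can serve as the response; never-observed directions are dropped with a
warning.

Validation uses Pearson correlations (fitted vs observed ENS; predicted
delta vs observed ENS change toward a later timepoint, computed without
any land-cover information from that period) and Moran's I with binary
distance-band, row-standardized weights at a list of radii
(normal-approximation p-values; a 999-permutation test is available).
Correlations with numerically zero spread raise rather than return a
meaningless value.

## Synthetic data

The generator emulates the study system so every stage can be tested
against known truth:

* **Survey structure.** 960 routes by default (segments 1, 3, 5 of five
  10-stop segments retained: 2,880 segments), 3 survey years per
  timepoint, observers shared across ~8 routes, route coordinates uniform
  over a ~4,000 km square.
* **Landscapes.** Six-class Dirichlet compositions (five modelled classes
  plus an unmodelled remainder) scaled to percent, which enforces the
  simplex constraint by construction. A configurable fraction of segments
  (default 20%) has exactly zero change — needed to exercise the
  `omega = 1` collapse. Changing segments perturb one or two classes with
  exponential magnitudes (mean 6–8 points, capped at 35), compensated in
  the remainder class; infeasible proposals are rejected and resampled.
* **Communities.** The model mean is computed from the truth via the same
  code paths the fitter uses; a target ENS is drawn from
  Normal(mu, sigma) truncated at 1; an abundance vector whose exp(Shannon)
  matches the target to ~1e-9 is built from a geometric-series profile
  (richness = ceil(target) + 8, log-ratio solved by Brent's method —
  the evenness-to-ENS map is monotone from 1 up to the richness, so a
  root always exists); each survey year gets a Poisson replicate around
  the expected abundances. The generative direction (ENS -> abundances)
  is a package construction: the field observes abundances, it does not
  specify how to synthesize them.
* **Truth defaults.** The equilibrium surface declines with urban,
  cropland and grassland cover over the realistic range, rises with
  wetland and (saturating) forest; decay rates put >= 0.9 of the mixture
  on the past landscape at a 10-point change for urban/cropland gain and
  grassland/cropland loss, and ~0.67–0.7 for forest loss and grassland
  gain; residual SD 1 ENS unit, observer SD 0.5. These settings make
  urban/cropland gain and wetland loss seed debts and grassland loss seed
  credits, the qualitative pattern the driver analysis is meant to
  recover.
* **Third timepoint.** An optional later timepoint moves each mean a
  fraction `relaxation` of the way from the legacy mean to the current
  equilibrium, giving the two validation limits (full relaxation:
  correlation near 1; zero relaxation: no signal).

What the generator does **not** emulate: spatial autocorrelation in
landscapes or communities, species identities and traits, detectability
variation beyond the observer effect, and route-level survey gaps. Passing
tests therefore demonstrate correctness of the machinery and
recoverability under the model's own assumptions — not robustness to the
violations real surveys exhibit.

## Problem sizes and test design

The parameter-recovery experiment uses 1,002 segments (334 routes), the
quadratic surface and 4 chains x 1,000 post-warmup iterations; at this
size all R-hat <= 1.01 and the 95% intervals cover the generating decay
rates in >= 8/10 components and the linear effects in >= 4/5. Several
decay components remain prior-limited (their class rarely changes), so
gamma posteriors contract slower than root-n; the contraction property is
tested as monotone tightening at 4x data. Model-selection and
future-change experiments run at 90–180 segments with shortened chains and
(for model selection) homogeneous observers, where the legacy-vs-
equilibrium PSIS-LOO gap is large (~30–130 elpd) and insensitive to the
scaling. Driver-sign recovery exercises the propagation machinery with
bound-respecting synthetic draw sets around the truth rather than repeated
MCMC fits.

## Known limitations

* The equilibrated-t1 assumption is structural; with only two timepoints
  the data cannot test it.
* `gamma` components for rarely changing classes are prior-dominated;
  their posteriors mostly reflect the Uniform(0,1) prior.
* The Gaussian observation model admits (with small probability) negative
  ENS predictions at extreme covariates; the log-linear `f` is positive,
  but `g` is unbounded.
* Moran's I uses a normal approximation by default; for small n or very
  sparse neighbour graphs prefer the permutation option.
* The in-package NUTS is single-threaded; chains run sequentially.
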