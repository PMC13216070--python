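# Methods

## Model

The package estimates household wild-meat consumption from recall surveys
by decomposing the consumption rate (kg undressed meat per adult-male
equivalent per day) into three linked processes, fitted jointly so that
studies contributing only part of the information (consumption flags but
no quantities, say) still inform the shared structure.

**Consumption probability.** Every recall event contributes a Bernoulli
observation with logit-linear predictor.  A recall-duration term captures
the mechanical effect that a longer look-back window is more likely to
contain at least one consumption event; predictions are therefore
evaluated at a one-day window (daily rates).  Study and household random
intercepts absorb methodology and repeated-measurement structure.

**Frequency of consumption.** A household's observed proportion of
consumption days follows a Beta distribution parameterized by its mean
`phi` and sample size `kappa`.  The latent `logit(phi)` is normal around
the regression mean with sd `Sigma_h = sigma * (365 - mdays_h)`: a
household interviewed once about a whole year is maximally noisy, one
monitored daily for a year is observed exactly.  The hierarchy is
non-centred (`phi_h = phibar_h + Sigma_h * tau_h`, `tau_h ~ N(0,1)`),
which removes the funnel geometry that frustrates gradient samplers.
Observed frequencies exactly at 0 or 1 are clamped to `[1e-4, 1 - 1e-4]`
before the Beta likelihood; the clamp count is reported.

**Quantity.** On consumption days, the per-AME daily quantity follows a
Gamma distribution in shape-rate form with mean `mu` log-linear in
covariates and in the number of AMEs sharing the meal.  Missing household
AMEs are imputed inside the model: `AME_m ~ Normal(nu, psi)` constrained
positive (sampled on the log scale with its Jacobian), with `nu` centred
at the observed mean AME.  Because the Gamma response is `q / AME` and the
imputed AME is a parameter, the exact conditional density of the datum `q`
carries a `-log(AME)` change-of-variables term; omitting it lets the
density grow without bound as the imputed AME inflates, and in recovery
experiments the imputation mean drifted to 2-3 times its true value until
the term was included.

**Spatial autocorrelation.** Locations close together share unmeasured
cultural and environmental drivers.  A latent Gaussian process over the
great-circle distance matrix (haversine, km; a planar option exists for
projected coordinates) uses the exponentiated-quadratic kernel
`zeta^2 exp(-rho^2 D^2)` with fixed jitter `1e-9`, non-centred through the
Cholesky factor.  The spatial term enters the consumption and frequency
predictors (two independent processes sharing `D`); the
simulation-study configuration places it on consumption only, matching
its generator.

## Priors

Weakly informative defaults, all overridable: Normal(0, 2.5) on logit- and
log-scale coefficients; half-Normal(0, 2) on sd-like parameters (GP
marginal sd, monitoring noise `sigma`, imputation `psi`, random-intercept
sds); Gamma(2, 0.1) on the Beta sample size `kappa` and Gamma rate
`theta`; Normal(observed mean AME, 2) on `nu`.  The GP inverse length
scale gets half-Normal(0, 5 / median inter-site distance), letting
correlation decay anywhere from negligible to complete across the study
area.

## Sampler

A multinomial No-U-Turn Sampler over hand-differentiated gradients
(including the exact Cholesky differential for the kernel
hyperparameters, contracted in trace form so both hyperparameters share
two triangular solves).  Warmup follows the usual scheme: dual-averaging
step-size adaptation towards a target acceptance statistic, and a
diagonal mass matrix re-estimated over expanding windows, initialized
from a rough Fisher-information guess so that far-from-unit-scale
coefficients (the raw recall-duration slope) do not stall early warmup.
Desk-scale default: 2 chains x 1,500 iterations (1,000 warmup); the
full-scale 4 x 5,000 configuration is available through `SamplerConfig`.
Positions where the kernel is numerically singular evaluate to log-density
`-inf` and are rejected; trajectories losing more than 1,000 units of
joint density count as divergent and are reported, never hidden.
Convergence is summarized by split-Rhat per scalar parameter (each chain
halved, so a single chain still yields the diagnostic) with the usual
1.01 threshold; failures appear in the convergence report.

Divergent transitions bias exploration in hierarchical models; when a fit
reports more than a handful, re-running with a higher target acceptance
(0.9-0.95, at the cost of smaller steps and deeper trees) is the standard
remedy and is a one-line `SamplerConfig` change.

## Synthetic landscape

The generator reproduces the model's simulation study and is the package's
only data source (the real survey database is access-restricted).  A
30 x 30 grid (900 cells, one location each, ~70 km spacing near the
equator) splits into three contiguous regions of 360/180/360 cells:
region 1 high V1 / low V2, region 2 the reverse, region 3 intermediate
(cell covariates normal around region means +/-1, sd 0.4).  Household
counts are Poisson with region means 40/100/65; household AMEs are
Poisson(5) truncated at 1; a two-level household covariate V3 has 30/70
frequencies.  Consumption is logit-linear in V1, V3 and a GP draw over
the 900-cell distance matrix plus the duration term; frequency is
logit-linear in V2, V3; quantity is log-linear in V2 and AME with Gamma
noise.

The generative coefficients are package defaults — intercepts near -2.4
(consumption), -1.9 (frequency), -1.1 (quantity, log kg), slopes 0.2-0.8,
duration increment 0.05/day, `zeta = 0.5`, `rho = 0.006` per km,
`sigma = 0.004`, `theta = 2` — chosen so that roughly 16% of recall
events register consumption, matching the strong predominance of
non-consumption records in real recall data.  True regional totals are
computed two independent ways (cell sums and household sums) and agree to
rounding.

Observation emulates a campaign: a coverage fraction of cells is surveyed
(5/10/15% scenarios); exactly 80% of surveyed locations report
frequencies and 50% quantities (locations grouped into studies of ~10
sharing a reporting profile; quantity studies are short-recall type,
others long-recall); 20% of households lack AME.  Monitored days are
log-uniform on [1, 365], split across ~3 recall events per household;
observed frequencies are the true values perturbed by logit-normal noise
with sd `sigma * (365 - mdays)` — no additional Beta draw, so a fully
monitored household reports its true frequency exactly.  One seed governs
generation through independent sub-streams per stage.

What the generator does *not* emulate: real covariate rasters and their
measurement error, unit-conversion noise in local measures, cooking-pot
inflation, non-ignorable missingness (AME and reporting gaps are missing
completely at random), and temporal change (a single period).  Passing
recovery tests therefore demonstrate that the estimator is correct under
the model's own assumptions at realistic sizes — not that those
assumptions hold in any real survey.

## Desk-scale problem sizes

The recovery study runs ten replicates of the 10%-coverage scenario
(90 surveyed locations), sampling ~10% of each location's households
(~550-600 households, ~1,600 recalls, ~600 free parameters) with one
chain of 1,500 iterations — the package's desk-scale choice, mirroring a
full-scale study design of 100 replicates at several thousand iterations.
Across replicates, 95% credible intervals for the 22 generative
regression coefficients are checked for nominal coverage, and the
posterior median of the predicted regional tonnes is compared with the
generator's truth.

## Prediction

Grid cells carry scenario covariates; settlement classes are
population-thresholded (village < 10,000; town 10,000-100,000; city
> 100,000, boundaries assigned to the larger class), cell AME counts
follow from population and child share under a 0.5 adult sex ratio, and
categorical parameters are weighted by class proportions.  Per posterior
draw and cell, realized consumption, frequency and quantity are drawn
from the fitted distributions and multiplied; biomass is rate x AME x 365,
summed into regional tonnes.  Random effects enter at their prior mean;
the spatial effect is zero-mean off the surveyed sites and is not kriged
onto the grid — with the default kernel scale this costs a few percent of
regional totals, well inside the recovery tolerance.  The study-type
parameter is fixed at the short-recall class, the least biased per the
cooking-pot hypothesis.

The protein chain multiplies a rate by the 70% edible (dressed) fraction
and 29.4 g protein per 100 g, against the recommended 56 g/day.  The
dissimilarity index normalizes each covariate's absolute deviation from
the recall-weighted data mean by its maximum across cells (the
normalization method was an open choice; maximum-scaling keeps each
covariate's contribution in [0, 1] and the sum in [0, 4]).

## Numerical and design notes

* Cell geometry: the printed cell area (5,027 km², the 40-km covariate
  circle) and nominal side (70.09 km) are mutually inconsistent by ~1.1%
  (sqrt(5027) = 70.90); both printed values are kept as defaults — the
  area for AME conversion, the side for the forest-buffer radius
  (2 x 70.09 = 140.18 km) — rather than deriving one from the other.
* Weekly and yearly categorical frequencies use 52/365 and 1/365 by
  analogy with the monthly 12/365 convention.
* The "gigot" carcass fraction defaults to one fifth of whole-body mass;
  all conversion factors are table-driven and overridable.
* Missing values are NaN internally; the legacy "-1" code is translated at
  ingestion and never survives into model-ready data.
* Duplicate recall identifiers are rejected and logged (their provenance
  cannot be resolved automatically); recalls with quantity > 0 but
  consumed = 0 are excluded and logged.
* AME imputation uses one parameter per household lacking AME, shared by
  that household's recalls.
* Education enters as a three-level main effect (reference:
  primary-or-none); period as an intercept offset (reference: first
  period); the population-density slope varies by settlement type.
* Frequencies require at least two monitored days; single-day frequencies
  are dropped with a flag.

## Known limitations

* The spatial effect is not projected onto unsurveyed grid cells, so
  cell-level maps understate spatial heterogeneity away from data (the
  dissimilarity index is the intended guard-rail).
* The Beta sample size `kappa` has no generative counterpart in the
  simulation (whose observation noise is purely logit-normal) and is
  weakly identified there; it is excluded from coverage checks.
* Single-chain recovery runs rely on split-Rhat, which cannot detect a
  chain stuck in one mode; multi-chain configurations are available and
  recommended for real analyses.
* `rho` and `zeta` are weakly identified from ~90 surveyed sites; their
  priors matter more than for the regression coefficients.
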