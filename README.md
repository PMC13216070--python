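# wildmeat

Joint Bayesian analysis of household wild-meat consumption surveys in
Central Africa — and anywhere household recall data on wildlife food use
are collected.  The package is aimed at quantitative ecologists and
epidemiological modellers who need regional consumption-rate and consumed-
biomass estimates from heterogeneous recall surveys: studies differ in
recall window (24 h to a year), in what they record (consumption yes/no,
frequency, quantity), in units (kg or local measures), and in coverage.

## The model

Per-household consumption is decomposed into three linked submodels whose
product is the consumption rate in kg of undressed meat per adult-male
equivalent (AME) per day:

    rate = consumption x frequency x quantity

* **Consumption** (recall level): `consumed_r ~ Bernoulli(pi_r)` with
  `logit(pi_r)` linear in site covariates, plus a recall-duration term
  (longer windows are more likely to record an event), study and household
  random intercepts, and a latent spatial Gaussian process
  `eps = LX @ eta` over the inter-location great-circle distance matrix
  `D`, where `LX` is the Cholesky factor of the exponentiated-quadratic
  kernel `X = zeta^2 exp(-rho^2 D^2) + delta I`.
* **Frequency** (household level): observed proportions of consumption
  days follow `Beta(phi_h kappa, (1 - phi_h) kappa)` where
  `logit(phi_h) = phibar_h + Sigma_h tau_h` (non-centred), and the
  monitoring-noise sd `Sigma_h = sigma (365 - mdays_h)` vanishes for a
  household monitored every day of a year.
* **Quantity** (recall level, consumption days only):
  `q_r / AME_r ~ Gamma(mu_r theta, theta)` with `log(mu_r)` linear in
  covariates and in the number of AMEs sharing the meal; missing household
  AMEs are imputed inside the model via `AME_m ~ Normal(nu, psi)`
  constrained positive.

The joint posterior is sampled by a No-U-Turn Sampler over a
hand-differentiated log-density (analytic gradients, including the exact
differential of the kernel Cholesky factor), with split-Rhat convergence
diagnostics.  Fitted draws are pushed through a prediction grid —
category parameters weighted by the proportions of people per settlement
type and education class in each cell — to map rates, annual consumed
biomass (`rate x AME x 365`, summed into regional tonnes), protein
contribution, and two uncertainty surfaces (posterior sds and a
covariate-dissimilarity index in [0, 4]).

Because the underlying survey databases are access-restricted, the package
ships a synthetic-landscape generator that reproduces the model's
simulation study — a 900-cell, three-region world with contrasting
covariates, spatially autocorrelated consumption, and partial observation
(5/10/15% coverage; 80% of surveyed locations report frequency, 50%
quantities, 20% of households lack AME) — providing ground truth for
parameter-recovery testing.

## Worked example

```python
from wildmeat.model import JointPosterior, SamplerConfig, sample_posterior, sim_design
from wildmeat.predict import predict_cells, protein_contribution, sim_cell_design
from wildmeat.survey import ingest_tables
from wildmeat.synthetic import generate_landscape, observe, prediction_cells, simulate_truth

landscape = generate_landscape(seed=0)          # 900 cells, 3 regions
truth = simulate_truth(landscape, seed=1)       # latent spatial effect + true surfaces
tables = observe(truth, seed=2)                 # 10% coverage survey campaign
ingested = ingest_tables(tables["studies"], tables["locations"],
                         tables["households"], tables["recalls"])
model = JointPosterior(sim_design(ingested))
draws = sample_posterior(model, SamplerConfig(chains=1, iterations=1500,
                                              warmup=1000, seed=42))
preds = predict_cells(draws, prediction_cells(landscape), sim_cell_design(), seed=7)
print(round(truth.total_tonnes, 1), round(preds.regional_summary()["tonnes_median"], 1))
```

prints `478.6 522.1`: the generator's true annual total is 478.6 tonnes
and the posterior median of the predicted regional total is 522.1 tonnes —
a 9% error from a survey that observed 10% of the landscape.  The
protein chain converts any rate to dietary terms:

```python
protein, pct = protein_contribution(50.0)   # g undressed meat / AME / day
```

gives `protein = 10.29` g/day and `pct = 18.4`% of the 56 g/day
recommended intake (the 70% edible fraction times 29.4 g protein per
100 g).

The numbered scripts under `analysis/` run the same sequence as a
narrative: simulate the three coverage scenarios, ingest, fit, predict,
and convert to protein contributions.  A `wildmeat` CLI exposes the
pipeline verbs (`simulate`, `ingest`, `fit`, `predict`, `report`,
`make-fixtures`).

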