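# camuse

Paired **N-mixture** and **occupancy** analysis of camera-trap habitat use,
as a tested, reusable Python pipeline.

Camera-trap surveys of wide-ranging carnivores produce repeated
observations at fixed sites under imperfect detection. Two hierarchical
models answer two different questions about the same data:

* an **occupancy model** estimates the probability ψ that a species *uses*
  a site at all, from detection/non-detection histories;
* an **N-mixture model** estimates the *intensity* of use — a latent
  per-site expected count λ — from repeated count histories.

Run together on one dataset, the pair gives a more complete picture of how
terrain and human activity shape where a species occurs and how heavily it
uses the places it does occur. `camuse` implements both models for a small
multi-species community, the data-processing chain that turns raw
time-stamped camera events into model-ready histories, the fit and
convergence diagnostics, and the cross-model agreement report — plus a
seeded synthetic-data generator so the whole chain is testable without any
field data.

## The models

For sites *i*, occasions *j*, species *k*, and replicate deployments
*m(i,j)* ∈ {1..4}:

**N-mixture (counts):**

```
n_ik  ~ Poisson(λ_ik),          log(λ_ik)  = α_k · x_i
y_ijk ~ Binomial(n_ik, ρ_ijk),  logit(ρ_ijk) = β_{m(i,j),k} + ε_ijk
ε_ijk ~ Normal(0, σ)
```

**Occupancy (detection/non-detection):**

```
z_ik  ~ Bernoulli(ψ_ik),        logit(ψ_ik) = φ_k · γ_i
y_ijk ~ Bernoulli(ρ_ijk z_ik),  logit(ρ_ijk) = β_{m(i,j),k}
```

In both models the species-specific covariate effects (α_k, φ_k) are
normal random effects around **community hyper-parameters** (a mean and sd
per covariate), so scarce species borrow strength from the community.
`x_i`/`γ_i` are standardized site covariates with a leading 1 for the
intercept.

Fitting marginalizes the discrete latent states (abundance by truncated
enumeration with Gauss–Hermite quadrature over ε; occupancy exactly over
z ∈ {0,1}) and samples the remaining continuous parameters with an
adaptive blocked Metropolis/Gibbs MCMC. Fit quality is assessed with a χ²
discrepancy posterior-predictive check (Bayesian p-value in [0.25, 0.75]
and ĉ < 1.1 indicate adequate fit), convergence with the split-chain
Gelman–Rubin statistic (R̂ < 1.1), and effects are classified at two
one-tailed credible levels (strong at 95%, moderate at 85%).

## Worked example

```bash
python examples/04_fit_models.py
```

simulates 150 sites × 16 seven-day occasions for three species at
contrasting abundances, fits both models, and prints (abbreviated):

```
expected count per site (N-mixture):
         mean  ci_lo  ci_hi     method
species
bear     3.39   2.82   4.08  intercept
wolf     2.86   2.36   3.45  intercept
lynx     1.80   1.46   2.22  intercept

site-use probability (occupancy):
         mean  ci_lo  ci_hi     method
species
bear     0.93   0.87   0.96  intercept
wolf     0.91   0.86   0.95  intercept
lynx     0.80   0.74   0.86  intercept

N-mixture fit: max R-hat 1.082, Bayesian p 0.40, c-hat 1.01
```

The expected count is the back-transformed state intercept, exp(α₀ₖ): the
latent number of individuals using a typical site (all covariates at their
mean). Site-use probability is ilogit(φ₀ₖ). The Bayesian p-value near 0.5
and ĉ near 1 say the fitted model reproduces the dispersion of its own
data. `examples/05_compare_models.py` then shows the agreement report:
which species × covariate effects each model flags, which are shared, and
whether any shared effects conflict in sign.

Other entry points: `examples/01_simulate_study.py` (the generator),
`examples/02_process_events.py` (raw events → histories: 15 m site
merging, deployment capping, species-specific independence gaps, 7-day
occasions, trap-rate covariates), `examples/03_screen_covariates.py`
(Pearson |r| > 0.7 screen and group resolution), and a thin CLI
(`camuse run-all --seed 1 --outdir run/`) with per-stage subcommands.

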