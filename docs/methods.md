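# Methods

This note documents the models, the data-processing conventions, the
sampler, the synthetic-data generator, and the design choices made where
more than one reasonable convention exists. Everything quantitative
claimed here is computed by the test suite or by `scripts/acceptance.py`.

## Data processing

Raw inputs are a time-stamped event table (site, deployment, timestamp,
species — including `human`/`vehicle` background records) and a deployment
table (id, site, projected easting/northing in metres, start/end dates).
The chain to model-ready histories:

1. **Site merging.** Camera locations within 15 m are the same site. The
   within-radius relation is closed transitively (connected components of
   the proximity graph), so a chain of nearby placements collapses even
   when its endpoints exceed the radius. The canonical site id is the
   earliest deployment's site id, which makes the operation invariant to
   input order.
2. **Deployment selection.** Per site, at most one deployment per calendar
   year is kept (the longest; ties broken by earlier start — the one-per-
   year rule has no stated tie-break, so we fixed one), then at most four
   deployments (again longest, ties by earlier start). Survivors are
   numbered 1..4 chronologically; this replicate index *m* carries its own
   detection intercept in both models, absorbing between-deployment
   differences in camera placement and era.
3. **Independence filtering.** Each (site, species) stream is scanned in
   time order; a record is kept iff it is ≥ the species' gap (bear 10 min,
   lynx 1 min, wolf 30 min) after the **last kept** record. Measuring from
   the last *kept* rather than the last raw record avoids a burst
   swallowing genuinely separated later events. The filter is idempotent
   and monotone in the gap; gap 0 is the identity. Human/vehicle streams
   pass through unfiltered (they feed effort-style covariates, not
   histories).
4. **Occasions.** Deployments are cut into half-open 7-day windows
   `[start + kL, start + (k+1)L)`. Half-open windows make event assignment
   unambiguous. A trailing partial window is kept and its effort (active
   days) recorded; the detection models contain no effort term, so effort
   is stored for extensions but not used in fitting.
5. **Histories.** Occasions from all retained deployments at a site are
   concatenated along the occasion axis, each tagged with its deployment's
   replicate number; counts are kept events per window (clipped to {0,1}
   for the occupancy model). Concatenating across years under a single
   latent state knowingly relaxes closure — both models treat the latent
   state as constant over the pooled record, which is why ψ is read as
   "site use" rather than instantaneous occupancy.
6. **Trap rates.** Per deployment, background-category events ÷ active
   days; per site, the duration-weighted mean over retained deployments.
   These join the site-covariate table as human/vehicle activity.

An event whose timestamp falls outside every occasion window of its
(retained) deployment raises an error — it signals inconsistent inputs.
Events from deployments dropped by selection are silently excluded: those
windows were not surveyed in the final design.

## Covariate preparation

Covariates are standardized column-wise to mean 0, sd 1 using the sample
sd (denominator n−1; fixed so tests can assert exact values), with the
scaler retained for back-transforming predictions. Collinearity screening
computes pairwise Pearson r and links covariates with |r| strictly > 0.7;
connected components with ≥ 2 members are conflict groups. Each group is
resolved by fitting the single-covariate version of the hierarchical model
to each candidate and keeping the one with the largest absolute
posterior-mean community (hyper-level) effect — the community level rather
than any single species, because the decision applies community-wide.
Exact ties fall back to name order and are flagged; a non-convergent
candidate fit (R̂ ≥ 1.1) downgrades the comparison's status to a warning
without blocking selection. The pipeline resolves groups with the
occupancy model by default (the two models' univariate rankings agree in
our synthetic checks and the occupancy fit is an order of magnitude
cheaper); this is configurable.

## The two models

See the README for the model statements. Points worth recording:

* Species are conditionally independent given parameters: additive
  covariate effects, no interaction terms.
* Species-specific state effects (α_k, φ_k), **including the intercept**,
  are normal random effects around per-covariate community hyper-means
  with per-covariate hyper-sds.
* Detection intercepts β_{m,k} are replicate- and species-specific with a
  common normal prior; they are not tied to community hyper-parameters.
* The occasion-level overdispersion deviate ε appears only in the
  N-mixture detection equation (count data can be extra-binomially noisy
  in ways detection/non-detection data cannot express); the asymmetry is
  deliberate.
* Default priors are diffuse: hyper-means Normal(0, 10), hyper-sds
  Uniform(0, 10), β Normal(0, 10), σ Uniform(0, 10). All are configurable
  per fit (`PriorConfig`).

## Likelihood computation

Both discrete latent layers are marginalized.

**Occupancy** is exact: per site and species the likelihood is
ψ·∏_j ρ^y (1−ρ)^{1−y} + (1−ψ)·1{all y=0}, evaluated from sufficient
statistics (detections and trials per replicate class), in log space.

**N-mixture** sums the latent abundance n from 0 to a truncation bound N
and integrates ε per occasion by Gauss–Hermite quadrature (33 nodes for
the reference site-likelihood; 11–15 for MCMC, where quadrature error is
far below Monte Carlo error). Because ρ depends only on (replicate,
species), the per-occasion marginal P(y | n) collapses to a lookup table
over the distinct (replicate, count) pairs in the data, and the quadrature
sum factorizes into rank-one terms Σ_q w_q e^{yA_q} e^{nB_q} with
A = log(p/(1−p)), B = log(1−p) — one small matrix product per
(replicate, species) instead of a five-dimensional log-sum-exp. The two
hot loops are numba-compiled; a full-data likelihood evaluation at the
default scale costs well under a millisecond, which is what makes plain
random-walk MCMC viable.

The truncation bound adapts **per site** — max count + max(40, 10·λ̂,
8·max count) with a crude detection-corrected λ̂, capped at 600 — because
one site with a 40-count occasion needs latent n enumerated into the
hundreds while the typical sparse site needs ~80. Sites are grouped into
banded buckets by their bound so the heavy-count minority does not slow
the contraction for everyone else, and the likelihood returns −∞ for
parameter values whose site rates put non-negligible Poisson mass beyond
their bucket's bound (λ_max + 8√λ_max above the headroom) — an implicit
cap on expected counts far outside the data's support. A property test
asserts that widening the bound changes the log-likelihood by < 1e-12.

Numerical conventions: log-probabilities of impossible cells (n < y) use
the finite constant −1e30 rather than −inf so that zero-weighted sums stay
NaN-free; all mixtures are combined by log-sum-exp.

## Sampler

A blocked adaptive random-walk Metropolis sampler with conjugate Gibbs
steps, exploiting the species-factorized likelihood:

* one proposal per species for the state-effect row α_k (all species
  proposed and accepted in a single vectorized pass);
* one proposal per species for the detection column β_{·,k};
* a **ridge move** that shifts a species' state intercept up while
  shifting all its detection intercepts down by the same amount. The
  abundance and detection scales are only weakly identified through the
  repeat-visit structure, so the posterior has a long λ↔ρ (or ψ↔ρ) ridge
  that axis-aligned proposals traverse slowly; the joint move cuts worst-
  case R̂ from ~1.2–1.3 to ~1.1 at the study scale;
* reflected random-walk Metropolis for σ on its uniform support;
* conjugate normal Gibbs draws for the community hyper-means and log-scale
  Metropolis for the hyper-sds (cheap: K normal terms each).

Proposal scales adapt by Robbins–Monro on the log scale during warmup only
(targets 0.3 for vector blocks, 0.44 for scalars), so the post-warmup
kernel is fixed and valid. Chains are seeded via `SeedSequence(seed)`
children: identical (data, config, seed) reproduce draws bit-for-bit.
Desk-scale defaults are 3 chains × 6,000 iterations (2,000 burn-in); the
published workflow's 3 × 200,000–400,000 data-augmented iterations can be
mirrored through `FitConfig`, but the marginalized sampler needs far fewer
iterations because it never waits on latent n/z updates.

Initialization is data-driven but crude (naive detection-corrected
intercepts, small per-chain jitter); burn-in handles the rest.

## Diagnostics

* **R̂**: split-chain Gelman–Rubin, `sqrt(((n−1)/n·W + B/n)/W)` after
  halving each chain (the conservative variant; the classic unsplit form
  is available by flag). Chains with zero within-chain variance return NaN
  with a degenerate flag rather than a number. Cross-checked against
  arviz in the tests.
* **Posterior predictive check**: per posterior draw (evenly subsampled
  across chains), a replicate dataset is simulated on the observed survey
  structure (same mask and replicate indices) and the χ² discrepancy
  T = Σ (y−e)²/(e+c) is computed for observed and replicated data against
  that draw's expected values e (λ·E[ρ] for counts, ψ·ρ for detections).
  The stabilizer c = 0.5 keeps sparse cells from dominating (the
  discrepancy's exact form is a convention; c is configurable). The
  Bayesian p-value is P(T_rep ≥ T_obs); ĉ is the mean of per-draw ratios
  T_obs/T_rep (a pooled-ratio variant is available by flag — neither
  estimator is canonical and both sit near 1 for well-specified fits).
* **Significance**: an effect is classified from its posterior sign
  probability — strong at the one-tailed 95% level (P(>0) ≥ 0.95 or
  ≤ 0.05), moderate at 85%; symmetric central 95%/85% intervals are
  reported alongside for plotting. The 85% tier exists because community
  shrinkage pulls species effects toward the community mean, muting
  otherwise-real associations.
* **Comparison**: per species × covariate cell, both models' categories
  are merged into shared-same-sign / shared-conflict / one-model-only /
  neither; "significant" includes both tiers. The shared fraction is
  2·n_shared/(n_sig_A + n_sig_B), defined as 1.0 when neither model flags
  anything.

## Synthetic data

The generator produces studies with exactly the statistical structure the
models assume, plus the raw-event layer above it.

* **Scale defaults** mirror the emulated survey at desk scale: 150 sites,
  3 species, 16 seven-day occasions per site split across 1–4 deployments
  drawn in the observed proportions (≈ 71/19/7/4% of sites with 1/2/3/4
  deployments).
* **Covariates** are multivariate normal with a factor-built correlation
  matrix (positive definite by construction) in which slope, roughness and
  the wide forest buffers form one |r| > 0.7 block and the 500 m forest
  buffer stays outside it — the structure the screen is meant to find.
* **Community truth** defaults put expected counts between 1 and 3 per
  site, per-individual per-occasion detection of a few percent (N-mixture)
  or 0.09–0.18 per site (occupancy), covariate effect sizes of |0.15–0.5|
  on the link scale, and σ = 0.5 — the magnitudes reported for this kind
  of carnivore survey.
* **Event streams** place independent Poisson arrivals within deployment
  windows at per-site intensities, then spawn sub-gap "echo" bursts
  (probability 0.3, ~1.5 echoes within 5 min) that exercise the
  independence filter, plus unfiltered human/vehicle background. The
  pipeline's synthetic mode drives focal intensities with a latent
  Poisson abundance times a per-individual daily encounter rate (0.02/day,
  about one carnivore record per 50 camera-days), so occasion counts are
  Poisson rather than binomial-given-n — an approximation used only by the
  end-to-end event-stream demo; model-validation studies generate
  histories directly from the exact model.
* The generator does **not** emulate home ranges, movement, spatial
  autocorrelation beyond covariates, or seasonal dynamics. Passing tests
  therefore certify the statistical machinery under the models' own
  assumptions, not robustness to the spatial/temporal structure of real
  camera-trap data.
* Open convention: whether an occasion count records independent events or
  individuals is left to the event layer; the filter's gap rule (one event
  per gap window) makes the default "independent events per occasion".

## Calibration experiments

`camuse.calibration` implements simulation-based calibration: each
replicate draws the complete truth — hyper-means, hyper-sds, species
effects, detection intercepts, σ — from the same proper priors the fit
uses, simulates a study at the survey footprint, fits, and scores the
central 95% credible intervals of the hyper-means against the truth.
With truth drawn from the prior, coverage is exactly nominal for a correct
sampler; fixed-truth coverage under diffuse priors would systematically
over-cover with only three species and say little. The calibration priors
are scientifically moderate (intercept hyper-mean N(0.5, 0.75), slopes
N(0, 0.25), hyper-sds U(0, 0.5), β N(−2, 0.75), σ U(0, 0.5)) — camera-trap
scales, not the diffuse defaults.

Calibration fits use 3 chains × 2,800 iterations (1,300 burn-in) with an
11-node quadrature — sized so a 20-replicate study of both models runs in
minutes while keeping worst-case R̂ near 1.1. The posterior-predictive
p-value of a correctly specified fit is *not* uniform (posterior
predictive checks are conservative; p concentrates near 0.5), so
calibration is asserted as the fraction of replicates inside the
[0.25, 0.75] good-fit band rather than by a uniformity test. The
misspecification probe (five seeded replicates) generates counts with
σ = 1.0 and fits with σ forced to 0; the unmodelled extra-binomial noise
inflates T_obs relative to replicated data and pushes ĉ past 1.1.

## Known limitations

* Single-season, closed-population models only; the occasion axis pools
  years by design (matching the analysis this package reproduces), so λ
  and ψ absorb any closure violations.
* The N-mixture truncation guard effectively bounds site-level expected
  counts; data genuinely supporting λ in the hundreds would need a larger
  explicit `abundance_truncation`.
* The univariate group-resolution step compares hyper-level effects only;
  per-species rankings can differ.
* The sampler is tuned for the handful-of-parameters-per-species regime
  (≤ ~10 covariates, ≤ ~6 species); much wider models would want gradient
  MCMC.
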