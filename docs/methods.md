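# Methods

## The problem

`lepitrend` analyses multi-decade light-trap records of nocturnal
macro-moths sampled along a mountain elevational gradient.  The scientific
question is how per-night community characteristics — total abundance,
species richness, and total dry biomass — changed over the study years, and
how those changes depend on elevation and on species traits (body size,
temperature niche, larval food specialisation, overwintering stage).  The
central estimand is the interaction between (standardized) calendar year
and site elevation on the log scale of the expected response: a positive
interaction means trends become more positive with elevation, the signature
of an upward range shift.

## Community responses

For each trap night the package computes

* **abundance**: the sum of individuals across species;
* **biomass** (mg): the abundance-weighted sum of species-level dry-mass
  estimates;
* **coverage-corrected richness**: species richness standardized to a
  common sample coverage.

Sample coverage is estimated with the Chao–Jost estimator
`C_hat = 1 - (f1/n) * (n-1)f1 / ((n-1)f1 + 2 f2)` from the singleton and
doubleton counts.  Richness is interpolated to the effective sample size
`m` whose expected coverage equals the target (combinatorial rarefaction,
evaluated in log space so `n` in the thousands cannot overflow) or
extrapolated via the Chao1 estimate of undetected species, capped at
`m = 2n`.  The original analysis does not state the coverage level it
standardized to; the package default is `C* = 0.90`, configurable.  Nights
that cannot reach the target even at `m = 2n` use the capped value and emit
a warning; empty nights are zeros (handled by the hurdle likelihood rather
than dropped).

## Species traits

Dry mass comes from a two-step allometry: an OLS line mapping wingspan
(widely catalogued) to forewing length, then a log-log power law
`mass = a * FL^b`.  The power-law coefficients are configuration values
(defaults `ln a = -3.2`, `b = 2.63`, a generic lepidopteran allometry);
tests pin the functional form, not the constants.  Species without
wingspan data receive the mean estimated mass of congeners; singleton
genera are flagged unresolved and excluded from mass-based groupings only.

The Species Temperature Index (STI) is the plain (unweighted) mean
temperature over the distinct 50 × 50 km grid cells holding at least one
occurrence record; duplicate records within a cell count once.  Whether
the original index weighted cells by area or record count is not stated;
the plain cell mean is used.

Food specialisation follows the host-plant taxonomy: one plant genus →
monophagous, several genera of one family → oligophagous, several families
→ polyphagous.  Continuous traits (mass, STI) are cut into tertiles at the
33% and 66% sample quantiles (linear-interpolation / type-7 convention,
the most common default; ties go to the lower group so labels are
independent of input order).

## The hierarchical models

Per-night responses are modelled with generalized linear mixed models on a
log link:

* abundance: **zero-inflated negative binomial** — with probability `pi` an
  excess zero, otherwise `NB(mu, phi)` with `Var = mu + mu^2/phi`;
* richness and biomass: **hurdle gamma** — an exact zero with probability
  `pi`, otherwise gamma with shape `alpha` and mean `mu`.

The linear predictor contains standardized year, elevation, their
interaction, two-day mean temperature and two-day precipitation sum;
sum-to-zero contrasts for trap type (3 levels), lamp type (4), number of
traps (4, ordinal levels treated as a nominal factor since no monotonicity
is imposed), and previous-night sampling (2); a cyclic cubic B-spline in
day of year (8 basis functions, column-centred) for the seasonal activity
curve; a B-spline in sampling duration (4 basis functions) applied only to
manual-trap nights with known duration, plus an indicator for manual
nights whose duration is unknown (a constant effect); and four Gaussian
random intercepts — site, site × year, night group (simultaneously
operated sites share a night), and the spatio-temporal cluster.

Clusters chain sites within 20 km of each other within a year into
connected components (single linkage); a clique mode (every pair within
the radius) is available by flag.  Synthetic data uses planar km
coordinates; a geodesic (great-circle) mode covers lon/lat inputs.

The zero/hurdle probability is intercept-only: covariates are specified
for the conditional mean only.

### Priors

Population-level slopes get improper flat priors.  The intercept gets
`student_t(3, centre, scale)` with centre the median link-scale response
and scale `max(2.5, 2.5 * mad)`.  All random-effect and smoothing SDs get
`half-student-t(3, 0, 2.5)`; the NB/gamma shape gets `gamma(0.01, 0.01)`;
the mixing probability `pi` gets a flat prior on the probability itself
(equivalently a logistic density on the logit scale).  These follow the
documented defaults of widely used Bayesian regression packages and are
overridable.

### Sampling

The posterior is explored with an adaptive Hamiltonian Monte Carlo sampler
written for this package: leapfrog integration with a jittered number of
steps (uniform on `[L/2, L]`, default `L = 16`), dual-averaging step-size
adaptation to a target acceptance rate (default 0.8), and a diagonal mass
matrix re-estimated at two warmup checkpoints.  Random effects and spline
coefficients use the non-centred parametrization; SDs, shapes and the
mixing probability are sampled on unconstrained scales with the
appropriate Jacobians.  All gradients are analytic (with the
`gammaln`/`digamma` terms grouped by unique count value for speed) and
verified against central differences in the test suite.  By default chains
start from a jittered posterior mode with SDs floored away from the funnel
neck, which makes short warmups effective; with short chains the trajectory
length is the main mixing lever, and the recovery studies use long
trajectories (up to 96–128 leapfrog steps) so that 2 × 600 iterations
reproduce the posterior spread of long (4 × 1500) reference runs.  Runs are deterministic given the seed:
chain `c` draws from a generator seeded `[seed, c]`.

Convergence is monitored with split-R-hat (optionally rank-normalized);
a fit is flagged non-converged if any scalar parameter reaches 1.1.  The
reference fitting profile is 4 chains × 2000 iterations (1000 warmup);
the reduced test profile is 2 × 600.  Divergent trajectories are counted
and reported, never hidden.

### Trend quantities

All derived quantities are computed draw-wise and summarized by the
posterior mean and the symmetric 95% quantile interval:

* **conditional trends**: expected response over the study years at the
  0/25/50/75/100% quantiles of the observed elevational range, other
  continuous covariates at their standardized mean, factors at the
  sum-to-zero level average, smooths and random effects at zero, and the
  `(1 - pi)` factor included in the natural-scale mean;
* **change factor / percent change**: the ratio of predictions between the
  last and first study year present in the data (not hard-coded calendar
  years); `percent = 100 * (factor - 1)` holds exactly per draw;
* **threshold elevation**: the elevation where the year main effect and
  the interaction cancel, `z* = -beta_year / beta_yx`, back-transformed
  with the stored standardization constants; draws with a vanishing
  interaction map to signed infinity, and summaries outside the observed
  range are reported as `<min` / `>max`;
* **single-species models**: the community abundance-model structure
  applied to per-species counts (zeros filled), for species recorded in at
  least a configurable number of unique site-year combinations;
* **interaction rescaling**: `exp(beta_yx * (10/sd_year) * (1000/sd_elev))`,
  the change in the 10-year change factor when moving 1000 m up;
* **proportion positive**: the fraction of species with a positive
  interaction coefficient, evaluated per posterior draw with draws
  permuted within species (the fits are independent, so no draw alignment
  is meaningful; a species-level binomial CI is available by flag of the
  caller's choosing);
* **sign-change point**: with species sorted by posterior-mean
  coefficient, the count of negative means, bootstrapped over species
  (default 10,000 resamples) for a 95% CI;
* **abundance-weighted mean interaction** per trait class, weighting each
  species' rescaled coefficient draws by its total abundance.

## The synthetic-data generator

Real records are not bundled; the generator emulates the survey's
statistical structure with known truth so estimator behaviour can be
verified end-to-end:

* sites spread uniformly over 193–2454 m asl with planar km coordinates,
  each active in a contiguous random block of years (mimicking the sparse,
  unbalanced site × year panel of long-running schemes);
* trap nights across the whole year with stratified trap-type
  (50/39/11% fixed1/fixed2/manual), lamp-type and trap-count assignment
  (every level guaranteed present), previous-night indicators derived from
  the actual date sequence, and manual-trap durations of 1–13 h with a
  random 30% missing;
* weather from an elevational lapse (−0.0055 °C/m) plus a seasonal cycle
  and AR(1) night-to-night noise, inducing the elevation–temperature
  confounding real data has; precipitation from a gamma law;
* counts per night × species from the ZINB with
  `log mu = beta0 + beta_year z_y + beta_elev z_e + beta_yx z_y z_e +
  season(doy) + u_site + u_siteyear + u_night + u_cluster + species
  effect`, a mid-summer Gaussian activity bump (peak day 190, SD 45 d,
  centred), and per-trait-group modifiers of the year and interaction
  slopes;
* occurrence grids whose cells span a temperature gradient, occupied
  preferentially near each species' latent thermal niche (so STI recovers
  the niche ranking), plus host-plant records covering all three
  specialisation classes.

Default truth: `beta0 = -1`, `beta_year = 0`, `beta_elev = 0.3`,
`beta_yx = 0.3`, `pi0 = 0.4`, `phi = 0.6`, random-effect SDs
0.5/0.3/0.3/0.2 (site/site-year/night/cluster) and a species-level spread
of 0.75 — chosen once to give sparse, overdispersed, zero-heavy counts
with realistic rank-abundance variation.  What the generator does *not*
emulate: real geography (no country borders or true grid geometry),
lunar-phase or trap-attraction physics, species phenology differences, or
temporal autocorrelation in counts beyond the shared random effects.
Passing recovery tests therefore show the estimation machinery is
self-consistent under the assumed model, not that the model is correct
for any particular real dataset.

## Problem sizes and numerical choices

The test suite and the acceptance script run reduced studies: recovery
uses surveys of 20 sites × 10 years (≈ 5,000–6,000 nights, ~40 species)
with 2 chains × 600 iterations (trajectories up to 96 leapfrog steps), and
the sign-pattern study 10 sites × 8 years with 2 × 400; the suite runs 10
replicates of each, the script 5.  These sizes were chosen as the smallest at which the
interaction posterior is informative while keeping a full run in minutes.
Exhaustive coverage oracles enumerate all abundance vectors with `n ≤ 12`.
Binomial coefficients are evaluated via `gammaln`; likelihood evaluations
that would overflow (`eta > 40`) return `-inf` and are rejected by the
sampler; ties at quantile cut points go to the lower group; a single
individual has coverage 0 and an empty night has richness and biomass 0.

## Known limitations

* The HMC sampler uses fixed-length jittered trajectories, not dynamic
  (NUTS-style) ones; strongly funnel-shaped posteriors mix more slowly and
  short test-profile chains can leave R-hat above 1.1 for the shape
  parameter and some random-effect SDs.  The reference profile (4 × 2000)
  should be used for substantive runs.
* The observation-level night random effect and the NB shape are jointly
  weakly identified; this is inherent to the model, not the sampler.
* The zero-inflation probability is barely informed when community totals
  contain no zero nights; its posterior then follows the prior's pull
  towards small values.
* Extrapolated richness beyond `m = 2n` is deliberately not attempted;
  very sparse nights are reported at the cap with a warning.
* Threshold-elevation posterior means are heavy-tailed when the
  interaction is near zero (draw-wise ratios), which is why out-of-range
  summaries are clipped to labels rather than reported numerically.
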