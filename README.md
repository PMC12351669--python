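# lepitrend

Long-term trend analysis of light-trap moth communities along elevational
gradients.

Multi-decade light-trap schemes record, for each trap night, which moth
species were caught and in what numbers.  `lepitrend` turns such records
into per-night community characteristics — total abundance,
sample-coverage-corrected species richness, and estimated dry biomass —
and fits hierarchical Bayesian regression models asking how those
characteristics changed over the study years, how the change depends on
site elevation, and how it differs between species groups defined by
traits (body size, temperature niche, larval food specialisation,
overwintering stage).  It is written for ecologists analysing standardized
long-term insect monitoring data, and ships a seeded synthetic-survey
generator with known ground truth so every estimator can be validated
end-to-end.

## The models

Per-night abundance `y_i` follows a zero-inflated negative binomial,

    y_i ~ pi * delta_0 + (1 - pi) * NB(mu_i, phi),        Var = mu + mu^2/phi

and richness/biomass follow a hurdle gamma (`P(y=0) = pi`, gamma with
shape `alpha` and mean `mu_i` otherwise), both with a log link:

    log mu_i = beta_0 + beta_year * z_year + beta_elev * z_elev
             + beta_yx * z_year * z_elev + beta_temp * z_temp + beta_prec * z_prec
             + f_doy(day of year) + f_dur(duration | manual)
             + factor effects (sum-to-zero contrasts)
             + u_site + u_site_year + u_night + u_cluster

Continuous predictors are standardized; `f_doy` is a cyclic spline;
sites within 20 km of each other in a year share a spatio-temporal
cluster.  The headline quantity is `beta_yx`, the year × elevation
interaction: positive values mean trends improve with elevation — the
signature of upward range shifts.  From a fitted model the package derives
change factors and percent changes between the first and last study year
at any elevation, the threshold elevation where the year terms cancel
(`z* = -beta_year / beta_yx`), and, from per-species models, the
proportion of species shifting upwards and abundance-weighted interaction
summaries per trait group.  Posteriors are sampled with a seeded adaptive
HMC sampler and checked with split-R-hat (threshold 1.1).

Full model and generator details are in [docs/methods.md](docs/methods.md).

## Worked example

```python
import lepitrend as lt

# a synthetic 10-year survey, 20 sites between 193 and 2454 m asl,
# ground-truth year x elevation interaction 0.3
cfg = lt.SurveyConfig(n_sites=20, year_range=(2000, 2009), n_species=40,
                      nights_per_site_year=30, seed=7,
                      true_params=lt.GenerativeParams(beta_yx=0.3))
sites, nights, records, species = lt.generate_survey(cfg)

table = lt.build_community_table(records, nights,
                                 species.assign(dry_mass_mg=1.0))
model = lt.CommunityTrendModel.from_tables(table, nights,
                                           response="abundance")
fit = model.fit(chains=2, iterations=1200, warmup=600, seed=3,
                max_leapfrog=64)

print(fit.summary().head(4).to_string(index=False))
low = lt.change_factor(fit, fit.model.design.observed_elev_range[0])
high = lt.change_factor(fit, fit.model.design.observed_elev_range[1])
print(f"change at lowest site:  x{low['factor_mean']:.2f} "
      f"({low['percent_mean']:+.0f}%)")
print(f"change at highest site: x{high['factor_mean']:.2f} "
      f"({high['percent_mean']:+.0f}%)")
```

prints (reduced-chain profile; exact numbers depend on the seed)

```
    parameter      mean       sd     ci2.5   ci97.5     rhat
    intercept  2.482324 0.123160  2.247686 2.727904 1.024042
       year_z -0.028121 0.059876 -0.152115 0.086297 0.999234
       elev_z  0.287822 0.121854  0.057511 0.516537 1.004147
year_z:elev_z  0.229584 0.065444  0.099105 0.358902 1.008838
change at lowest site:  x0.22 (-78%)
change at highest site: x3.52 (+252%)
```

The interaction CI covers the generating value 0.3 and every R-hat is
below 1.1; abundance declines at the valley floor and rises at the highest
sites, and the draw-wise identity `percent = 100 * (factor - 1)` holds
exactly.  `lepitrend.plotting.plot_conditional_trends(fit)` draws the
trend curves per elevation quantile with their 95% bands.

The same analysis is scriptable from the shell:

```sh
lepitrend simulate --seed 7 --out run
lepitrend traits  --run run
lepitrend metrics --run run
lepitrend trends  --run run --response abundance
```

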