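# pollenlag

Among-population asynchrony in conifer pollen phenology.

Wind-pollinated trees such as Scots pine (*Pinus sylvestris*) exchange genes
between fragmented populations only while their flowering overlaps in time.
Field surveys of pollen phenology record, for a sample of trees per site on
repeated visits, an **ordinal developmental score** (1–7, with stage 5 = peak
pollen shedding) for the five most developed male strobili per tree. Because
visits are ~10 days apart, the exact date of peak shedding is never observed
directly; it has to be inferred from the ordinal records. `pollenlag` is a
library (plus a small CLI) for biologists doing exactly that: it fits
cumulative link models to such surveys, converts the coefficients into
between-site and between-year time lags in days, relates development to
thermal time, and asks whether individual trees develop in the same order
every year.

## The model

For score *Y* with stages *x* = 1..7, a proportional-odds cumulative logit
model

  P(Y ≤ x) = logistic(θ_x − η),  η = β_t·t + β_site[s] + β_year[y] (+ interaction)

with ordered thresholds θ_1 < … < θ_6 and a slope shared across stages. The
time covariate *t* is either calendar day (counting May 1 as day 1) or
cumulative growing degree days (GDD, base 5.5 °C from January 1). Fitting is
in-house maximum likelihood (log-increment threshold parametrisation,
analytic gradient, BFGS), with the observed-information covariance.

Derived statistics:

* **time lag** between factor levels *i*, *j*:
  `lag(i, j) = (β_j − β_i) / β_t` — the difference in days at which half the
  strobili at one site reach the same stage as at the other. CIs come from a
  cluster bootstrap (trees resampled with replacement within site); for
  significance the CI is widened by ±3 days (the span over which one tree
  sheds most of its pollen) and must still exclude zero.
* **rank consistency**: per visit, each tree's five scores are summed and
  ranked; ranks are summed over the year and ranked again; between-year
  agreement is Spearman's ρ per site.

A seeded synthetic-survey generator with latent site/year/tree effects on
the day scale makes the whole pipeline testable end-to-end without any field
data.

## Worked example

```python
import pollenlag as pl

# a 3-year, 5-site survey; two sites join from the second year
survey = pl.simulate_survey(pl.SimulationParams(
    site_years={"BL": [2015, 2016], "LD": [2015, 2016]}, seed=1))

spec = pl.ClmSpec(time_term="day", factors=("site",), subset={"year": [2014]})
res = pl.fit_clm(survey, spec)
print(res.summary())
est = pl.bootstrap_lag_ci(survey, spec, "AC", "BE", n_boot=200, seed=1)
print(f"lag AC vs BE: {est.lag_days:.2f} d, CI ({est.ci[0]:.2f}, {est.ci[1]:.2f}),"
      f" significant={est.significant}")
```

prints (abridged)

```
Cumulative link model (logit)
  response levels: [1, 2, 3, 4, 5, 6, 7]   n_obs: 2100
  log-likelihood: -1722.2298   converged: True   iterations: 29
parameter                 estimate     std err
...
day                         0.2845      0.0073
site[BE]                    3.2105      0.1454
site[RM]                    1.2016      0.1221
  reference site: AC
lag AC vs BE: 11.28 d, CI (9.81, 12.61), significant=True
```

`day` is the slope of the latent development process (logit units per day);
`site[BE] / day ≈ 11.3` says trees at the westernmost site reach every stage
about 11 days before the reference site — i.e. site AC needs ~11 more
calendar days to reach peak shedding, so their pollen seasons barely overlap
(the survey was generated with a 12-day offset). The penalized CI
(here (6.81, 15.61)) excludes zero, so the difference counts as significant
even allowing for the ~3-day shedding window of a single tree.

The same objects drive the other analyses: `between_year_fit` (day + site×year
on the sites present in all years, year-vs-year lags), `thermal_fit` (GDD in
place of calendar day, unrepresentative stations excluded) and
`consistency_table` (per-site Spearman ρ between annual tree rankings).

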