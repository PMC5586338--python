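# Methods

## The model

Strobilus development is recorded as an ordinal stage 1–7 (stage 5 = peak
pollen shedding). We model the stage of strobilus *r* on tree *t* at time
*t* with a proportional-odds cumulative logit model,

    P(Y ≤ x) = F(θ_x − η),  F(z) = 1 / (1 + e^(−z)),
    η = β_t · time + β_site[s] + β_year[y] (+ β_site×year[s,y]),

where θ_1 < … < θ_6 are latent thresholds shared by all observations and the
linear predictor has a single slope common to all stages. The shared slope
is the proportional-odds assumption: differences between sites are the same
number of days at every stage, which is what allows a single "time lag" per
pair of sites. The time covariate is either calendar day (May 1 = day 1,
inclusive, so June 30 = day 61) or cumulative growing degree days.

Each strobilus score enters as one independent observation (five per
tree-visit). This is a plain fixed-effects CLM, not a mixed model: the
dependence of scores within a tree is ignored at the likelihood stage and
handled instead where it matters for inference — the bootstrap resamples
whole trees. Two consequences worth knowing:

* model-based standard errors on single coefficients are optimistic; use the
  cluster bootstrap for interval statements;
* latent tree-to-tree heterogeneity attenuates the slope and the factor
  coefficients by the same logistic-mixing factor, so the lag ratio
  `(β_j − β_i)/β_t` is essentially unbiased even though each coefficient on
  its own is shrunk. The test suite exploits this: raw-slope recovery is
  checked on data generated without tree effects, lag recovery with them.

## Time lags and the penalized significance rule

`lag(i, j) = (β_j − β_i)/β_t` is the difference in days (or degree-days) at
which half the strobili at one level reach a stage relative to the other.
Within one fit lags are exactly antisymmetric and additive, and invariant to
the choice of reference level and to any shift of the time origin (tested).

Confidence intervals: nonparametric cluster bootstrap. Trees are resampled
with replacement within each site (keeping all of a tree's visits and years
together), the model refitted per replicate from a warm start at the
full-data optimum, and the 2.5/97.5 percentiles taken. Defaults: 1000
replicates, percentile method; replicates that lose a response category or
fail to converge are dropped and counted, with an error beyond 20% failures.
The resampling unit, replicate count and CI method are this package's
choices; the percentile method is the simplest defensible option and the
tree is the natural exchangeable unit.

Significance uses a penalized interval: the CI is widened by ±3 days before
asking whether it excludes zero. The 3-day penalty reflects the span over
which a single tree sheds most of its pollen — a pair of sites closer than
that is biologically synchronous regardless of statistical resolution. The
penalty is applied symmetrically to both endpoints. No multiple-testing
correction is applied across pairs; the penalization is the only guard.

## Model variants

* **per-year**: `day + site`, fitted separately per year on the sites
  visited that year. This is the workaround for the rank deficiency that a
  pooled `site × year` interaction produces when some sites are missing in
  some years (the design detects this and raises rather than silently
  dropping columns).
* **between-year**: `day + site × year` on the sites present in every year
  (full-rank by construction); year-vs-year lags compare the year main
  effects.
* **thermal**: `gdd + site × year` after attaching the GDD covariate; sites
  whose nearest weather station is judged unrepresentative are excluded via
  the station map rather than interpolated.

## Thermal time

Daily average temperature is the midpoint of tmax and tmin. GDD accumulates
from January 1 with base 5.5 °C: a day contributes max(tavg − 5.5, 0), with
strict exceedance (a day at exactly 5.5 °C contributes nothing). The source
phrasing of the index is ambiguous between excess-above-base and
full-degrees conventions; excess is the standard degree-day definition and
the default, the full convention is available as `convention="full"`.
Accumulation requires gap-free coverage from January 1; gaps are an error,
not interpolated.

## Rank consistency

Per visit, each tree's replicate scores are summed and trees ranked within
the site (average ranks on ties); per year, each tree's visit ranks are
summed and the sums ranked again (average ties). Ranks ascend with score
sum, so a higher final rank means an earlier developer; Spearman's ρ between
two years' final rankings is orientation-invariant, so this convention does
not affect the reported coefficients. Trees absent from a year are dropped
pairwise from that year-pair, never scored as latest. ρ and the p-value use
the tie-corrected Pearson-on-ranks definition with a t approximation on n−2
degrees of freedom (adequate at 20 trees; verified by null calibration), with
a seeded Monte-Carlo permutation alternative behind `method="permutation"`.

## The synthetic-data generator

The generator is the package's study design. Scores are drawn from the same
ordinal logistic process the model assumes, with all effects on the day
scale: η = β_day·(day + site_effect + year_effect + tree_offset). Positive
effects mean earlier development. Defaults, fixed once:

| parameter | default | rationale |
|---|---|---|
| sites / effects (d) | AC 0, LD 3, RM 5, BL 8, BE 12 | spans the observed ~12-day west–east gradient, westernmost earliest |
| year effects (d) | 2014 0, 2015 −11.4, 2016 −3.2 | coolest year latest by ~11 days |
| β_day | 0.30 logit/d | development traverses the 7 stages in ~8 weeks |
| thresholds | 2.4 … 14.4 | stage-5 crossing near day 32 for a zero-effect site |
| tree_sd | 3 d | visible within-site spread without swamping site signal |
| design | 20 trees × 5 scores, 10-day visits May 1–Jun 30 | the field protocol |

Tree offsets are drawn once per tree and reused across years — this is the
mechanism that makes annual rankings correlate; `tree_sd = 0` gives the null.
Temperature series are a sinusoidal seasonal cycle (coldest mid-January)
plus i.i.d. daily noise, split into tmax/tmin by a fixed diurnal range, with
optional per-station-year anomalies.

What the generator does **not** emulate: scoring "the five most developed
strobili" is a max-order-statistic sample, while replicates here are i.i.d.
given the tree's latent state; there are no within-crown aspect effects, no
interval censoring beyond the visit schedule, and no biophysical
(chilling/forcing) development mechanism. Passing tests therefore establish
that the estimators recover the truth under the assumed ordinal process at
the field design scale — not that the process is a complete account of real
surveys.

## Numerical choices

* Threshold ordering is enforced by parametrising (θ_1, log Δ_2, …, log Δ_6);
  optimisation is BFGS with an analytic gradient, gradient tolerance 1e-8,
  max 500 iterations, plus a single restart when BFGS reports precision loss.
  Convergence is judged by the optimizer's own flag or a gradient small
  relative to the objective's magnitude (1e-6 · |NLL|).
* Initialisation: thresholds at the logits of pooled empirical cumulative
  proportions, slopes at 0. For the balanced intercept-only model this start
  is already the MLE.
* vcov is the inverse observed information, obtained by central finite
  differences of the analytic score in the direct (θ, β) parametrisation.
* Category probabilities are clipped at 1e-300 before logging; thresholds
  must be strictly increasing or the likelihood raises.
* Complete separation (a factor level observed only at an extreme category)
  triggers a warning naming the level; a time slope below 1e-8 in absolute
  value makes the lag undefined and raises.
* Treatment coding with the alphabetically (or numerically) first observed
  level as reference; lags are invariant to this and the invariance is
  tested.

## Problem sizes

The acceptance script and the heavier tests run at the field design scale:
5 sites × 20 trees × 5 scores × ~7 visits (≈ 3 500 observations per year),
50 (tests) or 20 (script) simulation seeds for lag recovery and coverage at
200 bootstrap replicates, and 1 000 replicate two-year surveys for the null
calibration of the rank-consistency p-value.

## Known limitations

* No mixed-effects CLM, non-logit links, or partial proportional odds.
* Whether the original field analysis entered five rows per tree-visit or a
  single modal score is unknowable from the record; five rows is the default
  and the reader can be fed either layout.
* Bootstrap CIs at 20 trees/site are mildly anti-conservative for extreme
  percentiles; empirical coverage of nominal 95% intervals at the design
  scale is ≈ 0.94 in the recovery harness.
* GDD is computed from station records mapped site→station; no spatial
  interpolation, chilling requirement or photoperiod term.
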