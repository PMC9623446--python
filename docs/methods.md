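# Methods

## Estimand and design

The pipeline estimates the short-term association between warm-season
(May–September) daily maximum temperature and pediatric ED visits with a
time-stratified case-crossover design. Exposure is the *county-specific
percentile* of daily maximum temperature, which makes counties with very
different climates commensurable; the headline contrast is a day at the
95th percentile (the extreme-heat threshold) versus the 50th (a typical
day), cumulated over lags 0–5 days. Each case day is compared only to the
other days of the same year, calendar month and day of week in the same
county, so the conditional-logistic likelihood differences out every
covariate that is constant within such a stratum: seasonality, long-term
trend, weekday structure, and all time-invariant county and population
characteristics.

## Exposure construction

Point-level (sub-county) daily values are aggregated to county-days with
population weights: `t̄ = Σ wᵢtᵢ / Σ wᵢ` over points with data. A
county-day is excluded when more than 20% of the county population lacks
data (strict inequality; exactly 20% missing is retained). Percentile
tables are built per county from warm-season, coverage-passing days only,
using linear interpolation between order statistics at plotting positions
`(k−1)/(n−1)` — the common default of mainstream numeric stacks; the rule
is encapsulated in one class and straightforward to swap. Percentiles of
values outside the observed range clamp to 0/100; with tied values the
inverse maps to the highest tied position (immaterial for continuous
temperatures). Warm seasons 2016–2019 are pooled into a single distribution
per county. The series is evaluated (through the warm-season table) on the
five days before each May 1 so early-May case days keep complete lag
histories instead of being discarded; relative humidity is aggregated with
the same weighting and coverage rule as temperature, symmetric by choice.

## Cause groups

The 21 ICD-10 cause groups plus all-cause are packaged as code ranges.
Membership is prefix-inclusive on the normalized (dot-free) code, so
`T67.0XXA ∈ T67` and `J45.909 ∈ J45`. Heat-related illness (T67, E86, E87)
is matched on any diagnosis position; all other groups on the principal
code only. Asthma, bacterial enteritis and suicidality/depression
deliberately overlap their parent chapters. Because published summaries
have quoted the heat-related share of visits under both tabulation rules,
`heat_related_shares` reports the any-mention and principal-only shares
side by side rather than reconciling them. Visits aged 18+ are rejected at
ingest; unparseable codes classify to all-cause only and are countable by
the caller.

## Cross-basis

The exposure dimension uses a quadratic B-spline with one interior knot at
the 50th percentile and boundary knots at 0 and 100, as the *full*
(partition-of-unity) basis centered at the reference percentile, so a
reference-level day maps to the zero row. Centering introduces one exact
linear dependency per lag-basis column; the fitter's pivoted-QR rank screen
removes it, and because every reported contrast is a difference of
realizable design rows, contrasts are invariant to which aliased column is
dropped. The lag dimension uses a natural cubic spline on lags 0–5 with
two interior knots at equal log-spacing, `exp(log 5 · k/3)` ≈ 1.71 and
2.92 days (with the anchor convention left configurable, since "equal
intervals on the log scale" does not pin down the anchors; synthetic checks
showed cumulative ORs insensitive to the alternative). Natural splines are
constructed from the cubic B-spline basis by a null-space projection of the
boundary second-derivative constraints; tests verify the span against an
independent truncated-power construction. Sensitivity variants — 2 or 3
exposure knots (placed at tertiles/quartiles of the percentile scale) and
3 lag knots — are expressed through the same `CrossBasisSpec`.

## Fitting

The conditional likelihood `Σ_s w_s [x_case'β − log Σ_d exp(x_d'β)]` uses
case-count weights `w_s` for multiple same-day visits in a cell, which is
exactly likelihood-equivalent to replicating the stratum (tested).
Covariates are the cross-basis columns, a 3-df natural spline in daily mean
relative humidity (interior knots at the tertiles of observed values,
boundary at the observed range) and a single 0/1 federal-holiday indicator;
a no-humidity variant simply omits the spline columns. Maximization is
Newton–Raphson with step-halving on the observed information, after
standardizing retained columns by their within-stratum spread; convergence
requires relative log-likelihood change < 1e−9 and score max-norm < 1e−6.
Ill-conditioned information triggers a BFGS fallback; a standardized
coefficient exceeding 15 in absolute value flags probable separation and
marks the fit non-converged. The covariance is the inverse observed
information, embedded with zero rows/columns for screened-out coefficients.

Strata in which any day (case or referent) lacks any of the six lagged
percentiles or the humidity value are dropped whole, so referent-set size
carries no information about missingness; drops are the only data-loss
mechanism and are accounted against the input visit count.

## Inference

Odds ratios use the delta method: `log OR = c'β`, `se = √(c'Σc)`, 95% CIs
with the exact normal quantile 1.96. The cumulative contrast sums the lag
basis over integer lags; per-lag contrasts multiply to the cumulative OR by
construction. Besides 95:50, the pipeline reports 95:1 and 95:mean, the
mean reference being each county's warm-season mean temperature mapped
through its own percentile table and averaged over counties. Subgroup
estimates come from stratified refits (separate models per subgroup level),
and homogeneity across levels is tested with the fixed-effects Wald
statistic `Q = Σ wᵢ(bᵢ − b̄)²`, `wᵢ = 1/seᵢ²`, against chi-square with
k−1 df. No multiplicity adjustment is applied across cause groups.

## Synthetic data generator

The generator emulates the study's inputs, not their full realism. Daily
maximum temperature at a point is a smooth seasonal curve (peak ≈ July 20,
default peak ≈ 88 °F) + a county offset (sd 6 °F) + a county-level AR(1)
anomaly (coefficient 0.7, innovation sd 4 °F, restarted each year) +
point-level noise (sd 1 °F); humidity is negatively correlated with the
temperature anomaly (r = −0.4) and clipped to [0, 100]. Point-days are
masked missing at 0.2% — rare, as in the emulated study, where the
coverage exclusion affected well under 1% of county-days; tests exercise
the exclusion and stratum-drop paths at elevated rates. Dates span April 26
to September 30 to supply pre-season lags.

Visit counts per county-day and cause are Poisson with log-rate
`log(base) + month + day-of-week + holiday + Σ_ℓ w_ℓ f(p_{d−ℓ})`, where
`f` is piecewise linear in the percentile with a single node at the median:
`f(50) = 0` and `f(95) = log(true OR)`, flat below the median. Because the
lag weights `w_ℓ = (0.50, 0.25, 0.12, 0.07, 0.04, 0.02)` sum to one
(effects concentrated at lag 0, as in the emulated study), the generator's
cumulative 95-vs-50 rate ratio equals the configured truth exactly. The
fitted quadratic-spline surface only approximates this kink, so recovery is
judged with tolerance bands, not exactness; measured bias of the cumulative
OR at truth 1.30 is under 2%. Heat-related events carry T67/E86/E87 in the
principal position with probability 0.7, otherwise in a secondary position
behind a nonspecific principal code. The generator does **not** emulate
spatial climate structure, realistic ICD code frequencies beyond group
membership, between-county heterogeneity of the heat effect, or
overdispersion; passing tests therefore demonstrate correctness of the
estimator under the stated model, not robustness to those features of real
claims data.

## Problem sizes

The default study is 20 counties × 4 grid points × 4 warm seasons with a
heat-related baseline of 0.7 visits per county-day (~8,000 heat-related
events), which a laptop CPU fits in seconds. The replicate experiments
(null calibration at truth OR 1, recovery at truth OR 1.30, and the
paired doubled-calendar confounding check) use a scaled-down single-cause
study — 8 counties × 2 points × 2 seasons, baseline 1.2 (~3,000 events per
realization) — chosen so that hundreds of replicates complete in minutes
while a single estimate still carries a usable standard error (~0.12 on
the log-OR scale). Replicate counts: 400 (null), 100 (recovery), 40
(paired confounding).

## Known limitations

* Exposure percentile ties and non-daily gaps are handled conservatively
  (highest tied position; gaps become missing lags that drop strata).
* The conditional likelihood treats multiple cases in a cell by weighting,
  not by the exact multi-case conditional likelihood; the two coincide for
  the case-crossover use here because all same-day cases in a cell share
  one exposure history.
* Separation is detected heuristically (coefficient divergence on
  standardized columns), not by a linear-programming certificate.
* County-level pooling assumes a common exposure-lag-response surface on
  the percentile scale across counties; subgroup refits relax this only
  along the configured axes.
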