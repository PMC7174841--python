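# Methods

## Scope and data model

The package analyses two kinds of data. *Microclimate*: hourly temperature
(and, on a subset of loggers, relative humidity) records from paired
understorey/subcanopy loggers at forest sites grouped into four areas —
elevation band (high ≈ 1200–1350 m a.s.l., low ≈ 450–550 m) × Andean slope
(east/west). *Thermal tolerance*: heat-knockdown trials in which a butterfly
stands in a 39–41 °C chamber until it loses locomotor performance, observed
for at most 60 min.

Timestamps are naive local time throughout. Ecuador observes no daylight
saving, so calendar arithmetic (day/night splits, daily and monthly
grouping) needs no timezone handling.

## Microclimate summaries

Daily maximum/mean/minimum and diurnal range are computed per logger per
calendar date. A day is *complete* when it has at least `min_hours` hourly
records (default 20 of 24); incomplete days are flagged and excluded from
every annual statistic, which guards monthly aggregates against battery
changes and gaps. Annual statistics average over complete days directly; a
month-weighted variant is not the default because the areas were logged
continuously and the months are nearly balanced.

Exceedance counts use a strict inequality on daily maxima ("days above
39 °C" means strictly above). Seasonality is the sample standard deviation
(n−1) of monthly means of the daily mean temperature.

Buffering is quantified two complementary ways:

* **Stratum offsets** — for every site with complete days in both strata on
  the same date, the subcanopy−understorey difference of each daily
  statistic, averaged over paired site-days within an area. Positive
  daily-max offsets mean the understorey stays cooler during the day;
  daily-min offsets are typically small and negative (the canopy keeps the
  understorey marginally warmer at night).
* **Buffering slope** — OLS of hourly understorey temperature on hourly
  subcanopy temperature, pooled across a whole area's aligned hours. Only
  hours present in both series are used; there is no interpolation.

The lapse rate is the OLS slope of per-logger annual mean temperature on
logger elevation (°C/m, also reported per 10 m).

Group comparisons use the pooled-variance (Student) two-sample t-test —
the degrees-of-freedom convention matching classical reporting of such
assays — and Tukey's HSD (studentized range) for all-pairs comparisons.

## Vapour pressure deficit

VPD = e_s(T)·(1 − RH/100), computed only for coupled observations (same
logger, same hour). Saturation vapour pressure uses Bolton's (1980)
empirical constants, e_s(T) = 6.112·exp(17.67 T/(T+243.5)) hPa, accurate to
about 0.1% over the tropical range; the classic Magnus coefficients are
available behind the `formula` switch for sensitivity checks. Annual
summaries report the mean over all hourly records, the mean of per-day
maxima over complete days, and the count of hours strictly above each
threshold (default 12 hPa, the level above which transpiration of tropical
montane trees is thought to be impeded).

## Bioclimatic variables

Monthly T_max/T_min are means of daily extrema over complete days within
calendar months; T_avg is their midpoint. Bio1 is the unweighted mean of
monthly T_avg, Bio2 the unweighted mean of monthly ranges. On equal-length
months Bio2 equals the plain annual mean of daily diurnal ranges exactly
(a linearity identity, property-tested); on a real calendar year the two
differ by at most a few hundredths of a degree.

Comparison against interpolated macroclimate consumes a per-area monthly
T_max/T_min table as data (raster extraction is deliberately out of scope,
keeping the package free of geospatial dependencies). Logger monthly stats
are averaged within area × stratum and differenced month by month; the sign
convention is microclimate − interpolated, so a negative offset means the
interpolation runs warmer than the forest interior.

## Heat-knockdown analysis

QC applies three rules in order: assays whose chamber exceeded 41.9 °C are
removed; assays where the chamber fell below the 39 °C floor are removed;
and (group × altitude) cells with five or fewer individuals are removed
("more than five" retained — the rule is strict). Sixty-minute survivors
are retained as right-censored records carrying the sentinel value 60.

Censoring is handled asymmetrically on purpose: the product-limit
(Kaplan–Meier) resistance curves and the log-rank test treat 60-min
survivors as right-censored, which is statistically correct for survival
machinery; the mixed models and ANOVA enter them as observed values of 60,
matching the convention of the assay protocol in which the horizon itself
is the recorded trait value. Both conventions are documented on the
functions that use them.

Proportions knocked down before the chamber reached 39 °C are reported with
Wilson 95% intervals, which behave sensibly at boundary counts (0 or n).

### Mixed models

All models are Gaussian random-intercept models with a single grouping
factor (species for wild surveys, brood mother for common-garden assays).
Because the analyses need tens of thousands of refits (parametric
bootstrap, calibration simulations), the fitter works on the profiled
likelihood in the variance ratio λ = σ²_g/σ²_e: per-group covariance blocks
I + λJ have closed-form inverses and determinants, GLS and σ²_e are
profiled out, and the resulting one-dimensional REML or ML criterion is
minimised by bounded scalar search followed by root-finding on the analytic
gradient (the criterion is numerically flat near its minimum, so
function-value search alone is only accurate to ~1e-7 in λ). A boundary
check allows σ̂²_g = 0 exactly. The implementation is cross-checked in the
test suite against statsmodels MixedLM (general designs) and against the
closed-form balanced one-way ANOVA estimator (MSB − MSW)/n, which interior
REML reproduces exactly.

Continuous fixed effects are standardised to mean 0 / unit variance before
fitting (the scaling constants are kept on the model); the response stays
in raw minutes. Categorical covariates use treatment coding; `a:b` terms
are column products.

Backward selection tests the random intercept first (REML likelihood-ratio
test against the no-random model, plain χ²₁ reference — conservative at the
boundary; the 0.5χ²₀+0.5χ²₁ mixture is available behind a switch), then
drops fixed terms one at a time by the largest ML-LRT p-value above α,
never removing a main effect while one of its interactions survives.
Fixed-effect p-values come from ML likelihood-ratio tests rather than
Satterthwaite-approximate F-tests: the LRT is exactly specified,
library-independent, and its α-level is verified by simulation in the
acceptance suite.

Repeatability R = σ²_g/(σ²_g+σ²_e) comes from the intercept-only model.
Uncertainty uses a parametric bootstrap: simulate from the fitted model,
refit, take the 2.5/97.5 percentile interval (default 1000 draws; refit
failures are dropped and counted). Simulation shows the plain percentile
interval covers the true ICC at ≈92–93% rather than the nominal 95%
(measured over 800 replicates at 30 groups of 10, and persisting at 100
groups), a property of percentile intervals for variance-ratio estimators
whose sampling distribution is skewed and slightly downward-biased; this is
reported as-is rather than corrected, because the percentile interval is
the field-standard convention for this estimator. Marginal/conditional R² follow the Nakagawa–Schielzeth
decomposition with σ²_f the variance of the fixed-effect predictor over
the data.

## Synthetic data generator

The generator is first-class, tested code; every downstream estimator has a
configurable truth to recover.

*Microclimate.* Subcanopy temperature is baseline + annual harmonic +
diurnal harmonic (peaking 13:00 local, smooth sinusoid) + AR(1) noise
(default coefficient 0.7, marginal sd 0.8 °C — hourly temperature errors
are autocorrelated, so day-level statistics get realistic variance).
The understorey is intercept + b × subcanopy + white noise, hour-aligned.
Relative humidity on humidity-equipped loggers is
clip(base − c·(T − site baseline) + noise, 5, 100).

Default presets encode the study conditions: lowland baseline 24.5 °C vs
highland 20.4 °C (a 4.1 °C gap), coupling slopes 0.68 (lowland) / 0.73
(highland), mean stratum offsets 0.44/0.25 °C, seasonal amplitude 0.9 °C
(seasonality sd ≈ 0.6 °C — low, as expected near the Equator), lowland
diurnal amplitude 5.0 °C vs highland 3.5 °C, a −0.005 °C/m lapse across
site elevations, and between-site baseline offsets of sd 0.3 °C. Site
offsets are centred within each area so the configured baseline is the
exact area mean rather than only its expectation — generative-recovery
tests compare estimates against configured truth, and leaving the area
mean itself random would conflate estimator error with design noise.
The interpolated-climate generator returns the simulated subcanopy monthly
extremes plus a configurable per-area bias (e.g. +2.01 °C on highland
maxima) to emulate an interpolation product that runs warm.

*Assays.* Knockdown time follows a random-intercept linear model whose
variance components and effects are stated in minutes on the analysis
scale. To keep times positive the noise is drawn on the log scale:
T = η·exp((u+ε)/η̄ − σ²_z/2), where η is the deterministic predictor, η̄ its
mean and σ²_z the total noise variance on the log scale. The correction
term makes E[T] equal η exactly; by the delta method the minute-scale
variance components are preserved to first order (relative distortion of
order (σ/η̄)², e.g. < 1% for the presets used in the recovery suites, but
~5–10% for the deliberately skewed wild-survey preset whose coefficient of
variation is large). Times at or above 60 min are censored at the horizon.
Pre-39 °C knockdowns occur with a per-band probability and carry a chamber
temperature drawn uniformly from 35–39 °C.

The wild-survey preset uses 10 species × 2 bands × 14 individuals
(≈280 trials), highland mean knockdown 5.4 min, a +10.5 min lowland effect,
and pre-39 probabilities 0.33/0.07. A single scalar ICC cannot
simultaneously reproduce a strong altitude effect, the intercept-only
repeatability, and both R² values of a confounded field design in a
balanced generator, so the recovery suites target each quantity in the
configuration that defines it (ICC 0.44 in a no-effect design; the altitude
effect and R² decomposition in covariate designs).

What the generator does **not** emulate: radiative spikes and storms
(temperature noise is Gaussian AR(1), so extreme-tail counts such as
days-over-39 °C are not calibrated), sensor drift and missing data (gaps
are supported by the readers but not simulated by default), species/altitude
confounding, and any physical canopy energy balance. Passing recovery tests
therefore demonstrates estimator correctness under the assumed statistical
structure, not robustness to real-world artefacts.

## Numerical and design choices

* RH readings in (100, 103] are clamped to 100 (capacitive sensors
  overshoot slightly at saturation); above 103 the record is dropped.
* Temperatures outside [−10, 55] °C are treated as sensor faults and
  dropped with a warning.
* Duplicate timestamps collapse to the first occurrence; sub-hourly
  duplicates and clock drift have no canonical treatment, so the rule is
  deliberately simple and logged.
* The variance-ratio search runs on log λ ∈ [−12, 12] with an explicit
  λ = 0 boundary comparison; ties within 1e-10 of the boundary resolve
  to 0.
* Pipeline stages communicate only through CSV files; with a fixed seed,
  reruns are byte-identical (the run manifest's timestamp is the single
  run-specific field, and per-stage manifests omit filesystem paths).
* Problem sizes in the test and acceptance suites (e.g. a one-year,
  7-sites-per-area network; 200-replicate calibration runs) are chosen so
  the whole suite completes in a few minutes on one core while keeping
  Monte-Carlo error well inside the asserted tolerances.

## Known limitations

* One random intercept, one grouping factor: nested or crossed random
  effects (e.g. logger within site within area) are out of scope; the
  microclimate analyses use fixed-effect summaries instead.
* Mixed models enter censored times as 60 min, understating upper-tail
  variance when censoring is common (it is rare in the intended designs).
* The LRT for σ²_g uses the plain χ²₁ reference by default, which is
  conservative at the boundary.
* Percentile bootstrap intervals for repeatability run ~2–3 points below
  nominal coverage regardless of group count (measured; see above).
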