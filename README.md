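# thermobuffer

Analysis toolkit for two linked questions in tropical thermal ecology:

1. **How strongly does forest structure buffer microclimate?**  From hourly
   temperature/relative-humidity logger records collected in paired forest
   strata (understorey ~1 m, subcanopy ~10 m) across elevation bands on both
   Andean slopes, the package computes daily and annual temperature
   summaries, stratum buffering offsets and slopes, vapour pressure deficit
   (VPD), lapse rates, and the bioclimatic variables Bio1/Bio2/seasonality —
   and compares them against interpolated macroclimate tables (e.g. a
   WorldClim2 extraction).
2. **How heat-tolerant are the butterflies living there?**  From
   heat-knockdown assays (minutes to loss of locomotor function in a
   39–41 °C chamber, right-censored at 60 min) it runs assay QC, knockdown
   proportions and product-limit resistance curves with log-rank tests,
   random-intercept mixed models of knockdown time, repeatability
   (intra-class correlation) with a parametric bootstrap, and
   likelihood-ratio backward model selection with Nakagawa–Schielzeth R².

A synthetic-data module generates logger networks and assay datasets with
the statistical structure the analyses assume, so the whole pipeline runs
and is testable offline.

## The statistics at the core

* **Buffering slope** — OLS of hourly understorey on subcanopy temperature,
  `T_u = a + b·T_s + ε`; `b < 1` means damped thermal excursions below the
  canopy.
* **VPD** — `VPD = e_s(T)·(1 − RH/100)` with Bolton's saturation vapour
  pressure `e_s(T) = 6.112·exp(17.67·T/(T + 243.5))` hPa.
* **Bioclim** — Bio1 = yearly mean of monthly `(T_max + T_min)/2`; Bio2 =
  yearly mean of monthly `(T_max − T_min)`; seasonality = sd of monthly
  mean temperatures.
* **Mixed model** — `y = Xβ + Zu + ε`, `u ~ N(0, σ²_g)`, `ε ~ N(0, σ²_e)`,
  one random intercept per species/brood, fitted by profiled REML/ML
  (`RandomInterceptLMM.fit()` → `LMMResults.summary()`).
  Repeatability `R = σ²_g/(σ²_g + σ²_e)`;
  `R²_m = σ²_f/(σ²_f + σ²_g + σ²_e)`, `R²_c = (σ²_f + σ²_g)/(…)`.

## Worked example

```python
import thermobuffer as tb
from thermobuffer import microclimate as mc

params = tb.MicroclimateSimParams(seed=1)          # study-condition presets
metas, series = tb.gen_microclimate(params)        # 4 areas x 7 paired sites
slopes = mc.buffering_slopes_by_area(series, metas)
print(slopes[["area", "slope", "r2"]])
```

```
        area     slope        r2
0   west-low  0.679544  0.975383
1   east-low  0.679932  0.975212
2  west-high  0.729552  0.960053
3  east-high  0.729516  0.960224
```

The understorey warms by ~0.68 °C per 1 °C of subcanopy warming in the
lowland areas and ~0.73 °C in the highlands — the configured coupling,
recovered from a year of hourly data.  On the assay side:

```python
recs = tb.gen_assays(tb.AssaySimParams(seed=1))    # wild-survey preset
kept, qc = tb.qc_filter(recs)
out = tb.repeatability(kept, n_boot=500, seed=1)
print(round(out.repeatability, 3), (round(out.ci_low, 3), round(out.ci_high, 3)))
```

```
0.076 (0.0, 0.184)
```

i.e. ~8% of knockdown-time variance in this preset is attributable to
species identity once the altitude contrast is left in the residual
(the intercept-only repeatability model conditions on nothing).

Command line: `thermobuffer run --config config.yml` chains
simulate → summarize → vpd → bioclim → compare → tolerance and writes CSV
tables plus a hash manifest; each stage is also available as its own
subcommand (see `thermobuffer --help`).

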