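# creelweather

Weather, tropical cyclones and a pandemic all change how much people fish.
`creelweather` is a tested Python implementation of three linked analyses of
weekly recreational-fishing (creel survey) effort in a subtropical coastal
system with two regions (east/west):

1. **Weather–effort model.** Weekly log effort is regressed on four
   effort-weighted weather covariates — precipitation, maximum temperature,
   maximum wind and small-craft-advisory counts — with month-varying
   intercepts and slopes, and a second-level linear trend of the temperature
   slope across the calendar:

   ```
   y_i  ~  Normal(α_j(i) + Σ_k β_j(i),k · z_ik ,  σ²)
   (β_j1 … β_j4)  ~  MVN(μ_j, Σ),    μ_j = (μ_β1, γ0 + γ1·z_month(j), μ_β3, μ_β4)
   α_j  ~  Normal(μ_α, σ_α²)
   ```

   with z-scored predictors, `z_month(j) = j − 6.5`, Σ modeled by the scaled
   inverse-Wishart construction, and diffuse priors throughout.  Effects are
   summarized as 95% credible intervals per (variable, month); an effect is
   "credible" when its interval excludes zero.

2. **Tropical-cyclone recovery model.** For each storm, the five survey weeks
   from landfall form a recovery series.  Log effort is fit with
   varying-intercepts/varying-slopes regression on relative week (1–5), and
   the storm slopes are regressed on Saffir–Simpson severity at landfall
   (`b_k ~ Normal(δ0 + δ1·category_k, τ²)`), testing whether more severe
   storms dent effort harder and recover faster.

3. **Pandemic comparison.** Monthly 2020 effort per region against the
   2015–2019 baseline, expressed as percent difference from the baseline mean
   with the min–max envelope.

Because the underlying creel data are proprietary, the package ships a fully
specified **synthetic-data generator**: a Monday-start 52-week survey
calendar, daily regional weather (seasonal sinusoid + AR(1) temperature,
zero-inflated-gamma rain, Weibull wind), advisory counts derived from wind
exceedances, a 12-storm catalog with a fixed severity mix, a ~70% weekend
effort share, and a multiplicative 2020 anomaly.  The generating parameters
are retained (`TruthBundle`) so every estimator is tested against known
ground truth.  All models are fit by purpose-built conjugate Gibbs samplers
(numpy/scipy only) with split-chain rank-normalized Gelman–Rubin R̂
diagnostics (converged when R̂ < 1.1).

It is aimed at fisheries scientists and quantitative ecologists who want a
reproducible template for effort–weather hierarchical models, or a ground-truth
harness for interrupted-time-series recovery analyses.

## Worked example

```python
import creelweather as cw
from creelweather import prep

ds = cw.simulate_dataset(seed=42)                      # full 2015-2021 study
records = prep.assemble_weekly_records(
    prep.aggregate_regions(ds.effort_by_area),
    ds.weekly_weather,
    prep.realign_warning_weeks(ds.advisories, ds.storms))
retained, audit = prep.exclusion_filter(records)       # drops warning/holiday/2020 weeks
design = prep.standardize(retained[retained.region == "east"], region="east")

spec = cw.WeatherModelSpec(chains=3, iterations=4000, burnin=2000)
post = cw.fit_weather_model(cw.build_weather_model(design, spec), spec, seed=7)
print(post.n_retained, round(post.max_rhat, 3))
trend = cw.temperature_month_trend(post)["gamma1"]
print({k: round(v, 4) for k, v in trend.items() if k != "negative"})
```

prints

```
6000 1.037
{'mean': -0.0202, 'lower': -0.0489, 'upper': 0.0124, 'credible': False}
```

6,000 retained draws (3 chains × 2,000 post-burn-in), every monitored
parameter converged (max R̂ 1.04 < 1.1), and the month trend of the
temperature slope is recovered near its generating value of −0.02 per month —
negative but not credibly so, i.e. the positive effect of warm weeks on
effort fades over the calendar year.  The same dataset drives the other two
analyses:

```sh
creelweather run --out-dir out/        # full pipeline: 96 monthly effects,
                                       # 12 storm slopes, 24 pandemic rows
```

The storm-severity regression on this synthetic study gives
`delta1 = +0.094 [+0.048, +0.132]` — recovery slopes credibly increase with
storm category — and the pandemic table shows spring 2020 effort 30–130%
above baseline while January/February sit near normal.

## Layout

- `src/creelweather/synth.py` — calendar, weather process, storm catalog, effort generator
- `src/creelweather/prep.py` — effort weighting, regional rollup, warning realignment, exclusion filter, standardization
- `src/creelweather/weather_model.py` — hierarchical weather–effort Gibbs sampler and effect summaries
- `src/creelweather/tc_model.py` — 5-week storm subsets, recovery model, per-storm classification
- `src/creelweather/pandemic.py` — monthly percent-of-normal comparison
- `src/creelweather/diagnostics.py` — R̂, credible intervals, end-to-end pipeline
- `docs/methods.md` — modeling choices, generator calibration, limitations
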