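# Methods

## The weather–effort model

Weekly effort (single-day single-angler trips) is natural-log transformed.
The four predictors enter in the fixed order precipitation (1), temperature
(2), wind (3), small-craft advisories (4); each is mean-centered and divided
by its sample standard deviation (ddof = 1) within region, over the retained
weeks.  The month index j(i) of a week is the month containing at least four
of its seven days (no tie is possible in a 7-day week).

The likelihood and hierarchy are

- y_i ~ Normal(α_j(i) + Σ_k β_j(i),k z_ik, σ²),
- β_j ~ MVN(μ_j, Σ) with μ_j = (μ_β1, γ0 + γ1 z_month(j), μ_β3, μ_β4),
- α_j ~ Normal(μ_α, σ_α²), exchangeable and outside the MVN (the coefficient
  covariance couples only the four slopes).

`z_month(j) = j − 6.5` centers the month covariate so γ0 is the temperature
slope at the calendar midpoint and γ1 is change per month.  Results are
reported on this per-month scale.

**Priors.** Normal(0, 100²) on every location hyperparameter (μ_α, μ_β1,
μ_β3, μ_β4, γ0, γ1) and Uniform(0, 10) on every standard deviation (σ, σ_α).
Σ uses the scaled inverse-Wishart construction: Σ = Λ Q Λ with Q ~
Inverse-Wishart(K+1, I), Λ = diag(ξ), ξ_k ~ Normal(0, 100²).  This keeps the
marginal scales of Σ diffuse while the K+1 degrees of freedom give uniform
marginal correlations.

**Computation.** In the non-centered parameterization β_j = μ_j + Λ η_j with
η_j ~ MVN(0, Q), every full conditional is a normal, an inverse-Wishart
(drawn by Bartlett decomposition), or a truncated inverse-gamma (the
conditional of a variance whose SD prior is Uniform(0, 10), drawn by inverse
CDF through the regularized incomplete gamma function).  The model is
therefore fit with a blocked Gibbs sampler; chains start from overdispersed
perturbations of pooled least-squares estimates, with chain-specific
sub-streams spawned from the user seed.  Monitored quantities — α_j, β_jk,
the location hyperparameters, σ, and the unique entries of Σ — are all
invariant to the sign non-identifiability of (ξ, η).

The desk-scale default schedule is 3 chains × 4,000 iterations with the first
half discarded (6,000 retained draws); the full published-scale schedule
(3 × 100,000, burn-in 30,000, thinned by 2, i.e. 105,000 retained draws) is
available via `WeatherModelSpec.full_schedule()`.  Burn-in is removed first,
then thinning applied, which is the only reading consistent with the
105,000-draw arithmetic.  At these problem sizes (n ≈ 300–364 per region) the
desk schedule converges with maximum R̂ ≈ 1.01–1.04.

**Monthly effects and the temperature trend.**  Each (variable, month) effect
is summarized by its posterior mean and the central 95% interval from
empirical quantiles with linear interpolation; the effect is flagged credible
iff the interval excludes zero.  The level-2 line γ0 + γ1 z_month(j) is
reported at j = 1..12 for plotting.

## The tropical-cyclone recovery model

For each storm, five consecutive region-weeks of log effort starting at the
landfall week (relative week 1 contains the landfall day) are taken from the
*unfiltered* effort series — warning weeks must be present here even though
the weather model excludes them.  Edge rule: when landfall falls on a Monday
or Tuesday and the tropical-storm/hurricane warning was issued in the
previous survey week (the ~36-hour lead), the window starts at the warning
week, since the impending landfall already suppressed that week's effort.

The model is log E_{k,w} ~ Normal(a_k + b_k w, σ²) with relative week w
entered uncentered as 1–5, a_k exchangeable normal, and b_k ~ Normal(δ0 +
δ1 category_k, τ²), category 0 denoting a tropical storm.  Priors mirror the
weather model.  A catalog in which all storms share one category leaves δ1
unidentified; the fit refuses and instructs fixing δ1 = 0.

Both classification routes are exposed: `classify_recovery` flags a storm
significant-positive when its *partial-pooling* slope interval lies above
zero, and `per_storm_ols` gives independent 5-point least-squares fits with
classical t intervals.  Partial pooling is the default because it shares the
residual variance across storms and essentially never false-alarms on null
storms.

## The pandemic comparison

Weekly effort is rolled up to months by the majority-day label, so the twelve
monthly totals sum exactly to the annual total.  Each 2020 month is compared
with the arithmetic mean (configurable to median) of the same month over
2015–2019; 2021 is excluded from both sides.  Two scales are emitted:
percent difference (100·(E2020 − baseline)/baseline, "75 % higher") and
percent of normal (100·E2020/baseline).

## The synthetic-data generator

The generator is the package's study system; its defaults are fixed and are
what every test and the acceptance script consume.

**Calendar.** Week 1 of a year starts on the first Monday on or after
January 1; a 53rd week is dropped so each of the seven study years
contributes exactly 52 weeks (364 per region).  Daily weather is simulated a
few days past year-end so the 52nd week is always complete.

**Weather.** Daily maximum temperature is an annual sinusoid (mean 24 °C,
amplitude 8 °C, peak around day 200) plus AR(1) anomalies (coefficient 0.7)
whose innovation SD (2.2 °C) is modulated ±50% seasonally, larger in winter.
This calibrates the weekly effort-weighted January temperature SD to ≈3.3 °C
with June near 1.2 °C — the winter-variable, summer-stable pattern of the
study region that explains why standardized temperature effects matter most
in the cool season.  Precipitation is zero-inflated gamma (wet-day
probability 0.28–0.45 by season, shape 0.9, scale 12 mm); wind is Weibull
(shape 2) with a seasonally shifted scale (7 ± 1.5 m/s, windier winters) and
a windier east region.

**Advisories.** Weekly small-craft-advisory counts are (days with daily
maximum wind ≥ 10.8 m/s, the 21-kt criterion) × (marine zones per forecast
office: 8 east, 5 west), putting east totals in the low thousands over seven
years.  Counts are deliberately *not* effort-weighted.  Tropical-storm and
hurricane warnings are implied by the storm catalog; a Monday/Tuesday
landfall places them in the previous survey week, generating the edge case
the realignment rule and the TC-window rule both handle.

**Storms.** Twelve storms with the fixed severity multiset {0×6, 1×2, 2, 3,
4×2}, June–November landfalls spaced at least 42 days apart so recovery
windows never overlap.  The default catalog places no landfall in 2020: a
2020 storm's recovery slope would be confounded with the multiplicative
pandemic anomaly, corrupting the known ground truth the recovery tests rely
on.  (The real study period did contain 2020 storms; this is a deliberate
synthetic-design choice.)

**Effort.** log effort = α_month + Σ_k β_month,k z_k + Normal(0, 0.3), with
z_k the within-region z-scores of the generated covariates.  Monthly
intercepts follow a seasonal cycle peaking in July (≈ e^10.35 ≈ 31,000
trips/week) with winter troughs near 10,000.  The coefficient truth has
temperature slopes declining from ≈ +0.29 (January) to ≈ +0.07 (December)
(γ0 = 0.18, γ1 = −0.02 per month) and small negative means for the other
three variables, drawn once around MVN(μ_j, Σ) with SDs 0.04–0.07.  A storm
of category c imposes an additive log-scale effect min(0, −0.35(1+c) +
0.10(1+c)(w−1)) over its five-week window; 2020 weeks are multiplied by
monthly factors (March/April 1.75, May 1.40, August 1.50, otherwise 1),
anchored to the ~75% spring anomaly reported for the east region — a single
statewide multiplier set is used rather than region-specific ones.  Day-of-
week effort weights default to Mon–Thu 0.075 each, Fri 0.15, Sat 0.30, Sun
0.25 (weekend share exactly 0.70); within-week daily effort is the
deterministic product of the weekly total and these shares.

All randomness flows from one user seed through a spawned generator
hierarchy; a fixed seed reproduces every table bit-identically.

## Experiment designs used by the tests

- **Coverage.**  50 replicates at n = 364: each draws monthly coefficients
  from MVN(μ_j, Σ) (so the data-generating values are themselves draws from
  the hierarchical population), simulates an undisturbed study, fits with a
  reduced 2-chain × 900-iteration schedule (coverage needs no multi-chain
  diagnostics), and checks that the 2,400 95% intervals cover truth at a rate
  in [0.88, 0.99].
- **Severity recovery.**  On the default catalog the generated recovery
  slope is 0.10(1+c) per week, so the level-2 severity coefficient δ1 must be
  estimated positive with its 95% interval above zero.
- **One-of-twelve detection.**  Eleven storms have their effect switched off;
  the highest-category storm receives a major-hurricane-scale disturbance
  (effect scale 2: ≈97% effort loss in week 1, full recovery by week 5, true
  slope ≈0.9 per week).  A storm with the default category-0 dip (slope
  ≈0.09/week) is statistically invisible in five weekly points with residual
  SD 0.3 — the detectable-storm scenario mirrors the one devastating
  hurricane the study singled out.  Exactly the effect storm must be flagged
  in ≥90% of 50 replicates.
- **Degenerate-hierarchy oracle.**  With a single month, no month trend and
  diffuse priors, posterior coefficient means must match ordinary least
  squares within twice the Monte-Carlo standard error (effective sample size
  from arviz).

## Numerical choices

- Natural log for effort throughout (recorded on the design table).
- Sample SD (ddof = 1) for standardization; a zero-variance predictor is an
  error naming the column.
- Credible intervals use linear-interpolation empirical quantiles.
- R̂ is the split-chain rank-normalized statistic (maximum of the bulk and
  folded versions), matching the modern Gelman–Rubin variant; constant chains
  return NaN with a warning.  It is invariant under affine transformations up
  to floating-point tie resolution in the folded ranks.
- Truncated inverse-gamma draws use the regularized upper incomplete gamma
  inverse; a zero shape (one group) falls back to the uniform SD prior, and a
  zero sum of squares (perfect fit) returns a tiny variance.
- The exclusion filter logs region, year, week and reason for every dropped
  row, since warning-week edge cases are resolved by deterministic rule
  rather than manually.

## Limitations

The generator emulates the *statistical structure* the models assume, not the
full texture of real creel data: effort estimates carry no survey estimation
error, spatial heterogeneity within regions (which confounded real post-storm
recovery) is absent, advisory/warning counts are only order-of-magnitude
realistic, the pandemic multiplier is statewide rather than regional, and
covariate collinearity arises only through the shared wind process (wind vs
advisories ≈ 0.7 here, stronger than the −0.57 maximum reported for the real
predictors).  Passing tests therefore demonstrate correctness of the
estimators under the assumed model, not robustness to real-data
misspecification.  The level-2 month trend is linear only; alternative
functional forms are out of scope, as is any causal interpretation of the
pandemic comparison.
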