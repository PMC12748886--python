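# Methods

This note records the models, the defaults and why they were chosen, the
numerical decisions, and what the synthetic-world validation does and does
not establish.

## Counterfactual temperature construction

The premise is observational: the component of local warm-season warming
that scales with the global mean surface temperature (GMST) rise is treated
as the anthropogenic signal, and a no-climate-change world is obtained by
subtracting it day by day. This preserves observed weather variability —
individual heat waves remain in the counterfactual, only cooler — which is
what makes year-specific attribution possible. It deliberately does not
separate natural from anthropogenic forcing, nor capture circulation or
aerosol-driven regional effects.

**SSA smoothing.** The monthly GMST series is embedded in a Hankel
trajectory matrix (window L = 120 months), decomposed by SVD, and
reconstructed by diagonal averaging from the trend group. The grouping rule
is ours and configurable: a component belongs to the trend group when the
fraction of its left singular vector's periodogram power at frequencies
≤ 1/L is at least `low_freq_fraction` (default 0.5). This keeps constant
and quasi-monotone components, and rejects seasonal (period ≤ L) and noise
components, whose spectra are concentrated at higher frequencies. A pure
linear ramp is reconstructed exactly; the annual cycle is removed. The
central, lower and upper GMST series are smoothed independently; for a
near-monotone smoother this preserves their ordering and is the simplest
defensible treatment of the published uncertainty bounds.

**Re-baselining** subtracts the 1850–1900 mean (configurable) from both raw
and smoothed series, so the anomaly is relative to a pre-industrial level.

**Scaling regression.** OLS of the annual Jun–Sep city mean on the
calendar-year mean of the smoothed central anomaly, 1950–2022, with a
t-based 95% CI (n − 2 df). The central smoothed series is the predictor for
all three slope bounds; slope uncertainty enters only through the
regression CI, since the 9-member ensemble already crosses GMST bounds with
slope bounds. At least 10 overlapping years are required; a zero-variance
predictor is an error.

**Application window.** The subtraction is applied to warm-season months
plus the 10-day pre-season buffer (May 22–31); buffer days use their own
month's anomaly. Outside that window the series passes through unchanged,
since nothing downstream consumes it.

**Moving-average sensitivity.** The 5-year centred moving average of annual
anomalies (assigned to all months of the year) replaces SSA under
`gmst_smoothing="annual-ma-5"`; edges shrink the window symmetrically so the
series keeps its length.

## First-stage distributed-lag models

Each city × subperiod (six 5-year blocks 1993–2022 by default; five 6-year
blocks as sensitivity) is fitted separately so the association may vary
over time while knots stay fixed:

- **Exposure basis**: natural cubic spline, 2 inner knots at the 50th and
  90th percentiles of the city's pooled 1993–2022 warm-season daily means
  (linear-interpolation quantiles), boundary knots at the pooled min/max —
  3 columns. Percentile knots rather than fixed temperatures make the basis
  comparable across cities with different climates; fixing them across
  subperiods (and across counterfactual variants) keeps coefficients
  comparable over time, which the whole design depends on.
- **Lag basis**: lags 0–10 days; intercept plus a natural cubic spline with
  2 inner knots equally spaced on the log(lag+1) scale — 4 columns. This is
  the standard choice for mortality displacement horizons of about a week
  and a half; it is configurable.
- **Confounding control**: 6 day-of-week contrasts, year indicators, and a
  per-year day-of-season natural spline (2 inner knots) interacted with the
  year indicators. Year-stratified seasonal splines control both the
  within-season shape and the between-year level for warm-season-only
  series.
- **Estimation**: log-link Poisson IRLS (statsmodels GLM); dispersion =
  Pearson χ²/df multiplies the covariance (quasi-Poisson). Point estimates
  are independent of the dispersion. Aliased columns are dropped by pivoted
  QR with a logged warning. Non-convergent fits are flagged and excluded
  downstream with a warning.
- **Reduction**: with cross-basis coefficients η and covariance V, the
  lag-cumulative coefficients are θ = Mη, S = MVM′, where M sums the lag
  basis over lags 0..10 per exposure column. This is exact linear algebra;
  with a 0-lag intercept-only basis it is the identity.

The natural cubic spline basis follows the usual statistical convention
(cubic B-splines projected onto the null space of the boundary
second-derivative constraints, intercept removed, K inner knots → K+1
columns) and extends linearly beyond the boundary knots, which is exact for
a natural spline.

## Second-stage meta-regression

Units are city × subperiod triples (θ, S). The model is

    θ_ik ~ N(B′x_ik + b_i, S_ik),   b_i ~ N(0, Ψ),

with one shared 3-dimensional random effect per city (longitudinal
structure). Estimation is ML, not REML: fixed-effect LR tests are then
valid and AIC/BIC comparable across fixed-effect specifications. Ψ is
parameterised by its Cholesky factor (log-diagonal), and the fixed effects
are profiled out by GLS at every likelihood evaluation. The optimizer
(L-BFGS-B) is started from a method-of-moments estimate (covariance of
per-city mean residuals from the Ψ=0 GLS fit, minus the within-unit
attenuation, eigen-clipped) and from a scaled identity; the better optimum
wins. When the design is balanced the per-city Cholesky factorisations run
as one batched call. Random slopes for time and nested grouping structures
are available via the random-design argument but are not defaults.

**Meta-predictors** are standardised internally (results are invariant;
the optimizer is better conditioned); predictions and the counterfactual
construction work in original units. When a subperiod scheme differs from
the one the predictor table was tabulated under (the 6-year sensitivity),
values are interpolated linearly at subperiod midpoints — the predictors
are subperiod means of smooth annual indicators, for which midpoint
interpolation is the natural reconstruction.

**Selection** is forward-then-backward by AIC over the candidate
predictors on top of a base model containing a natural-spline trend in the
subperiod midpoint (1 inner knot at the study midpoint). LR p-values are
reported in the trace but never gate the search. After the predictor
search the base trend spline itself competes on AIC: with six time points
and a near-linear LE trajectory, trend spline and LE are close to
collinear, and ML can split the temporal decline into an over-negative LE
coefficient compensated by a positive trend — which corrupts the fixed-LE
counterfactual prediction. Letting the more parsimonious model win resolves
the split in favour of the predictor that also explains the cross-city
variation.

**Heterogeneity**: Cochran's Q from GLS residuals weighted by the S_ik
alone, df = 3n − p, I² = max(0, (Q−df)/Q)·100.

**BLUPs**: u_i = ΨZ_i′V_i⁻¹(y_i − X_iβ̂); the per-unit covariance is the
fixed-prediction covariance plus the conditional random-effect variance
Ψ − ΨZ_i′V_i⁻¹Z_iΨ. Counterfactual (no-LE-improvement) BLUPs replace each
unit's LE with the city's first-subperiod value in the fixed-effect part
and keep the factual residual; their covariance is carried over unchanged
(the residual adds no new uncertainty under the model).

## Attribution

MMT search: 0.1-percentile grid from the 25th to 99th percentile of the
relevant temperature series (each counterfactual variant defines its own
grid; the coefficients do not change), ties broken to the lowest
temperature. The forward-perspective daily attributable count multiplies
the attributable risk fraction 1 − exp(−Δ) by the forward moving average of
observed deaths over lags 0–10; the window truncates at September 30 so
October deaths, absent from the data, are never imputed. Four scenarios
cross factual/counterfactual temperatures with factual/fixed-LE
associations. P_CC for a period aggregates as 100·ΣAN_CC/ΣAN_factual;
annual P_CC values feed the trend fits.

Monte Carlo eCIs resample association coefficients only (normal, 1000
draws; eigvalue square-root factorisation so PSD-degenerate covariances are
accepted); the MMT stays at its point-estimate value per draw (recomputing
it per draw is a config option, off by default, chosen for stability).
Factual and fixed-LE coefficients share the same residual draw per unit,
mirroring how the counterfactual BLUPs are constructed. Cities are drawn
independently; all-cities intervals are computed on per-draw sums.

## Trends and tests

OLS on year, reported per decade with a t-interval; natural-spline
alternatives with 2–4 df are compared by Gaussian AIC (counting the
residual variance as a parameter). The Wilcoxon rank-sum comparison pools
the 9 counterfactual ensemble members into one group (15 vs 135 in the full
design), following the combined-sample convention; this treats ensemble
members as independent observations and is therefore optimistic — flagged
here, configurable to a paired design.

## Synthetic world

The generator emulates the statistical structure the pipeline assumes:

- GMST: sigmoid-plus-linear trend reaching ≈ +1.1 °C by 2022 relative to
  1850–1900, monthly AR(1) noise (innovation SD 0.09, ρ 0.5), CI bounds at
  ±0.05 °C.
- 15 cities, daily temperatures from 1950: annual-cycle amplitude 8.5 °C
  around a 10 °C mean (giving warm-season means near 18.5 °C), daily AR(1)
  noise (innovation SD 1.7, ρ 0.75), city scaling slopes β ~ N(1.4, 0.15²).
- LE rises ~2.5 years per decade with between-city variation in both level
  (SD 0.8 at 1993) and slope (SD 0.05/yr). The slope variation matters: it
  is what identifies the LE effect against a shared time trend in the
  second stage.
- Mortality: negative-binomial counts (variance/mean 1.2 by default;
  Poisson at 1.0) around a baseline of 15–90 deaths/day with a mild annual
  shape and weekend deficit. The true cumulative risk curve is a quadratic
  rise above the 75th percentile projected onto the fitting spline basis
  — so the well-specified case is exactly representable — scaled per
  subperiod so RR at the 99th percentile equals
  1.45·exp(−0.03·(LE − 76)), i.e. roughly 1.45 falling to ~1.18 over the
  study period. Lag weights are a decaying profile constructed inside the
  lag-basis span, summing to one. A NB rather than quasi-Poisson generator
  is deliberate: quasi-Poisson is an estimation device, not a generative
  model.
- Ground truth (TruthBundle) records β, the risk curves, MMTs, and the
  closed-form expected attributable deaths Σ λ₀(t)(exp(Δ(t))−1) over days
  above the true MMT — the estimand the forward accounting targets.
- Seeding is hierarchical (numpy SeedSequence spawning), so worlds are
  bit-reproducible and per-city streams independent.

What passing the synthetic validation shows: the pipeline's algebra and
calibration are correct under the assumed structure, and the four-scenario
sign pattern (declining factual AF, rising AF without LE improvements,
no distinct trend without either driver, rising P_CC) is recovered when the
world truly has warming plus LE-driven vulnerability decline. What it does
not show: robustness to spatially correlated mortality shocks, harvesting
dynamics beyond 10 days, age-structure effects, or misspecified exposure
bases (a threshold-linear truth option exists for robustness checks but is
not part of the default validation).

## Problem sizes and defaults in the test-suite

Statistical checks use the sizes their properties need: 500 replicates for
CI-calibration of the scaling slope and the LR-test size, 200 for
first-stage coverage and the attribution oracle, 50 world seeds for the
end-to-end sign pattern. Integration fixtures use 2–6 cities; recovery
checks use the full 15-city default. The factual-AF trend condition is the
statistically weakest link of the sign pattern: its true value (about −0.04
to −0.25 AF percentage points per decade across seeds) is small relative to
estimation noise, so single seeds can flip its sign; the acceptance bound
(≥80% of seeds) absorbs this.

## Known limitations

- The counterfactual removes only the GMST-scaled signal; circulation and
  aerosol-driven components of regional warming are not represented.
- Ensemble members enter trend tests as independent samples (optimistic).
- The meta-regression assumes normal within-unit errors with known S_ik;
  very small daily counts would strain this.
- No cold-related risk: the accounting is heat-only, above the MMT.
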