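# Methods

This note documents the models, the synthetic world, the numerical
choices, and the limits of what the test suite demonstrates.

## 1. The estimand and the estimator

For city *i*, pollutant *p*, alert day *t*, the policy effect is

    Δ_{ipt} = obs_{ipt} − f̂_ip(x_t) · c_ip ,

where f̂ is the business-as-usual (BAU) predictor selected on non-alert
days and c is the city × pollutant correction factor. Percentage effects
use the corrected BAU as denominator. Two selection problems make the
naive estimator (no exclusion, no correction) biased:

* days influenced by interventions must not enter training, so every
  alert interval is removed together with a buffer (1 day before, 3 days
  after, inclusive) covering ramp-up and decay of the measures;
* removing them leaves the model trained on a "too-clean" sample: it has
  never seen the meteorology/emission regime of the worst winter days and
  under-predicts exactly where alerts fire.

The correction factor compensates the second problem. Its derivation is
tied to alert intensity: the fraction of heating-season (Nov 1–Mar 31,
inclusive, year-spanning) days removed by the mask in the evaluation
period determines how many of the worst heating-season days are excluded
from an alert-free historical reference period. The same model family is
refit on the remaining reference days, the excluded extreme days are
predicted, and the factor is the aggregated daily observed/predicted
ratio. On alert days the prediction is multiplied by the factor; all
other days pass through unchanged.

### Baseline models

One model per city × pollutant. Features: days-since-origin trend, year,
month, ISO day-of-week, wind components u = −speed·sin(dir),
v = −speed·cos(dir), temperature, surface pressure, boundary-layer
height, precipitation. The candidate roster is deliberately small and
reproducible — LightGBM (400 trees, learning rate 0.05, single-threaded,
fully seeded), random forest (200 trees), and a ridge pipeline with
one-hot month/day-of-week — rather than an opaque AutoML sweep; the
selection harness accepts any mapping of scikit-learn-style estimators.
Selection minimizes RMSE on a random held-out 20% of unmasked days
(a chronological split is available through the same seed-controlled
interface but random is the default; the day-to-day residual in both the
synthetic and the real problem is short-memory compared to the features).
Predictions are clipped at zero. Skill is reported as Willmott's index of
agreement IOA = 1 − Σ(P−O)²/Σ(|P−Ō|+|O−Ō|)², Pearson r, and RMSE; for a
constant prediction IOA is well-defined (0 for the mean predictor) while
r is undefined and reported as missing.

### Correction-factor choices

* **Aggregator.** Median of daily obs/pred ratios by default; mean,
  geometric mean, and ratio-of-means are selectable. In piloting, the
  median was the best-calibrated estimator of the mean alert-day bias
  under forecast-triggered alerts; the alternatives over-corrected by
  3–8% of the corrected level.
* **Reference-day selection.** Top-share-by-concentration heating-season
  days, ties to the earlier date. Two pooling conventions are exposed:
  pooled over all reference winters (pipeline default — alert days
  concentrate in severe winters and pooled selection weights reference
  days the same way) and per-heating-season (used by the transferability
  check, where each winter window must have comparable selection depth).
* **Degenerate samples.** Below 10 reference days (configurable) the
  low-level operation raises; the pipeline falls back to a neutral factor
  of 1.0 with a logged warning.
* **Tier-agnostic factors.** One factor per city × pollutant, applied to
  every alert tier. A constant factor can calibrate the *average*
  alert-day bias but not a level-dependent one; per-tier effect estimates
  therefore inherit a mechanical tilt (over-correction of mild days,
  under-correction of the deepest days) and the package's validated claim
  is the overall alert-day effect, not its tier decomposition.

### Transferability check

The reference period is split in two (first sub-period strictly before
the split date). Factors derived from the first half's excluded extremes
are applied to the second half's extreme-day predictions from an
independently fitted model. Residuals are evaluated per high-pollution
window — the excluded extreme days of one heating season — as
|mean(obs) − mean(corrected)| / mean(obs), averaged over windows, because
the factor targets aggregate bias, not day-level scatter; at the default
lognormal residual sd of 0.25 and ~35 extreme days per window the
window-mean sampling noise alone puts a floor of roughly 5–8% under this
statistic.

### Policy-effect aggregation

Daily effects carry the highest tier covering the day; non-alert days are
emitted with tier "none" as a control. Outliers are removed per
city × pollutant (controls fenced separately) with a Tukey fence
[Q1 − 1.5·IQR, Q3 + 1.5·IQR]; groups smaller than 4 are left untouched.
Aggregation order is fixed: day → city → group. Group means are means of
city means; standard errors are the standard deviation of city-level
means over √n_cities, never pooled over days; single-city groups report a
missing SE. When a summary is not grouped by tier, control rows are
excluded so alert-day means are never diluted.

### Health model

RR = exp(β·E) with β = ln(RR₁₀)/10, RR₁₀ = 1.0065 (CI 1.0044–1.0086) per
10 μg m⁻³, and exposure E = max(0, PM2.5 − 2.4 μg m⁻³). Each scenario's
RR is computed from that scenario's own exposure, which is what makes the
observed and counterfactual burdens separately computable. The baseline
mortality rate γ₀ is a required input in deaths·person⁻¹·yr⁻¹, converted
to a daily rate by /365 (leap days use the same rate); the worked
configuration uses 0.00708, a crude national all-cause rate, with a
(0.0060, 0.0085) range. Burdens are summed over alert-period city-days
and aggregated to annual totals. Uncertainty is an envelope: ΔMort is
re-evaluated at the γ₀ range endpoints and (optionally, default on) at
the RR confidence-interval endpoints; the reported bounds are the min and
max of that grid.

## 2. The synthetic world

The generator emulates daily city-level series from a polluted northern
winter-heating region:

* **Levels and trend.** Baseline annual levels 55/100/40/18 μg m⁻³ for
  PM2.5/PM10/NO2/SO2 with a −5.5%/yr multiplicative trend (≈24% decline
  over five years).
* **Seasonality.** A smooth winter weight peaking mid-January scales
  concentrations up to `season_amplitude` (default 2×) and drives the
  meteorological climatology (shallow boundary layers, cold).
* **Meteorology.** AR(1) anomalies (boundary-layer height, wind,
  temperature, pressure), seasonal precipitation occurrence, and a
  wind-direction random walk. Concentrations respond log-linearly to
  standardized anomalies (defaults −0.30 blh, −0.20 wind, −0.08
  temperature, −0.06 precipitation), all recoverable from the model
  features.
* **Noise.** Lognormal day-to-day residual (sd 0.25 in log space),
  correlated across pollutants (ρ = 0.85) the way haze episodes lift all
  species together.
* **Extreme surge.** Heating-season days whose latent PM2.5 exceeds a
  threshold (default: the yellow alert trigger) carry an extra +25%
  multiplicative surge the features cannot explain — the winter
  heating/emission burst that motivates the correction stage. This is the
  dominant, stable component of the clean-day model's extreme-day bias.
* **Alerts.** Authorities act on a lognormal-noise *forecast* of latent
  PM2.5 (sd 0.20; 0 gives a perfect forecast): tiers at 115/150/250
  μg m⁻³, highest threshold exceeded wins, consecutive qualifying days
  merge into events (constant-tier segments), minimum length 1 day.
  Forecast error matters structurally: it leaves some genuinely severe
  days unalerted (and hence in the training data), which keeps the
  baseline's bias a level-stable multiplicative one — the regime the
  correction method assumes — instead of a hard truncation at the alert
  threshold.
* **Intervention.** During an alert run, each pollutant is multiplied by
  (1 − effect[tier] · ramp), the ramp reaching 1 after `effect_lag` days
  (default 2, consistent with emergency measures taking ~48–72 h to reach
  full effect). Defaults: PM2.5 20/30/35%, PM10 18/25/30%, NO2 10/15/20%,
  SO2 3/5/8% for yellow/orange/red. The latent no-intervention series is
  returned alongside, so observed ≡ latent off alert days by
  construction.

What the generator does **not** emulate: spatial transport between
cities, chemistry (pollutant ratios are fixed up to noise), measurement
error distinct from process noise, discretionary or politically-timed
alert issuance, and structural emission change between reference and
evaluation periods beyond the smooth trend. Passing tests therefore show
that the chain recovers known effects *when its assumptions hold*; they
do not certify behavior under regime shifts the correction cannot see.

## 3. Test design and problem sizes

The suite runs scenarios sized for single-CPU execution: 2–5 cities and
4–8 years per scenario, LightGBM-only rosters where the candidate
comparison is not itself under test. The central property checks:

* **Parameter recovery.** With imposed tier-uniform effects of 30%
  (PM2.5) and 15% (NO2), immediate onset, and an alert-free 4-year
  reference, the across-20-replicate mean recovered overall alert-day
  percentage reduction must fall within ±5 points of truth (piloted at
  −27.7 ± 3.7 and −17.0 ± 3.6 per replicate). Recovery is claimed for the
  overall alert-day mean, not per tier (see the tier-agnostic-factor
  note).
* **Null control.** Zero-intervention scenarios (3 seeds × 5 cities):
  control-day deltas and city-level relative avoided mortality must be
  indistinguishable from zero, tested as |mean| ≤ 2·SE with
  practical-equivalence floors fixed at design time — 0.5% of the ambient
  level for concentration deltas and 10 points of relative avoided
  mortality (about a third of the imposed-effect signal) — because the
  constant factor leaves a few-percent calibration residual by
  construction.
* **Bias mechanism.** On endogenous-alert scenarios the uncorrected
  baseline must underestimate latent BAU on alert days (piloted ratio
  ≈ 0.54) and correction must shrink the absolute bias (≈ 0.98).
* **Oracles.** Closed-form micro-examples of the risk/burden formulas at
  10⁻¹⁰ relative tolerance, brute-force enumeration of exclusion masks,
  and the algebraic special cases of the Willmott score.

The acceptance script reports three desk-scale quantities: the RR for a
10 μg m⁻³ increment (exact), the held-out IOA for one default synthetic
city over five years (≥ 0.7 floor; measured ≈ 0.81–0.84 across seeds),
and the transferability residual on a 3-city alert-free reference with
the surge onset set below the extreme-day selection cut so that every
excluded extreme day carries the built-in 20% under-prediction (measured
mean ≈ 7.8%, 12-seed max 9.7%).

## 4. Known limitations

* A single multiplicative factor cannot correct a level-dependent bias;
  tier-resolved effects are reported but carry a mechanical tilt.
* The correction assumes the reference-period bias structure transfers to
  the evaluation period; a structural emission change concentrated on
  extreme days would violate this silently.
* The health model is log-linear with a uniform national γ₀; no age
  structure, no supralinear response at very high PM2.5, no
  population-weighted intra-urban exposure.
* The 80/20 split is random over unmasked days; with strongly
  autocorrelated residuals a temporal split would give more conservative
  skill estimates.
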