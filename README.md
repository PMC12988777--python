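# alerteval

Counterfactual evaluation of air-pollution alerts: weather-normalized
business-as-usual baselines, historical bias correction, alert-day policy
effects, and the short-term PM2.5 mortality burden they avoid.

## The problem

Cities in cold, industrialized regions issue tiered pollution alerts
(yellow < orange < red) when forecasts predict severe haze. Each alert
activates short-term interventions — industrial curtailments, traffic
restrictions, construction bans — meant to cut emissions for a few days.
Did they work? The question is hard because alerts fire precisely on the
days that would have been worst anyway: comparing alert days with ordinary
days confounds the intervention with meteorology, seasonality, and the
long-term emission trend.

`alerteval` implements a two-step machine-learning counterfactual chain
for this setting, exercised end-to-end on synthetic multi-city data with
known ground truth:

1. **Baseline (BAU) model.** For each city and pollutant, candidate
   learners (gradient-boosted trees, random forest, regularized linear)
   are trained on non-alert days only — every alert plus a buffer of 1 day
   before and 3 days after is excluded — using calendar features (trend,
   year, month, day-of-week) and meteorology (wind u/v, temperature,
   pressure, boundary-layer height, precipitation). The candidate with the
   lowest held-out RMSE on a random 80/20 split is selected and evaluated
   with Willmott's index of agreement (IOA), Pearson r, and RMSE.
2. **Bias correction.** Training only on "clean" days biases the baseline
   low under exactly the conditions when alerts fire. From an alert-free
   historical reference period, the same share of worst heating-season
   (Nov–Mar) days that the alert mask removed from training is excluded,
   the model is refit, the excluded extreme days are predicted, and the
   aggregated observed/predicted ratio becomes a city × pollutant
   correction factor applied to alert-day predictions.
3. **Policy effects.** The daily effect is observed − corrected BAU
   (negative = the alert reduced pollution), with a Tukey 1.5×IQR outlier
   fence per city × pollutant, aggregated day → city → group with standard
   errors taken across city-level estimates. Non-alert days ride along as
   a control that should scatter around zero.
4. **Health impact.** A log-linear concentration-response function
   RR = exp(β·ΔPM2.5), β = ln(1.0065)/10 per μg m⁻³ (95% CI
   1.0044–1.0086 per 10 μg m⁻³), with a 2.4 μg m⁻³ no-effect threshold,
   converts observed vs counterfactual PM2.5 into attributable deaths:
   Mort = γ₀_daily Σᵢⱼ popᵢ (1 − RRᵢⱼ⁻¹) and
   ΔMort = γ₀_daily Σᵢⱼ popᵢ (RR_obs⁻¹ − RR_cf⁻¹),
   where γ₀ is a user-supplied crude mortality rate.

A synthetic-data module generates the whole study world — declining
trends, winter surges, autocorrelated stagnation meteorology, lognormal
scatter, forecast-triggered tiered alerts, and a configurable
multiplicative intervention effect — while retaining the latent
no-intervention truth, so every stage of the chain is testable against
ground truth.

## Worked example

```python
from alerteval import (HealthConfig, ModelSettings, PipelineConfig,
                       ScenarioConfig, run_pipeline)

config = PipelineConfig(
    scenario=ScenarioConfig(n_cities=4, start_date="2015-01-01",
                            end_date="2022-12-31",
                            alert_start_date="2019-01-01", seed=42),
    reference_split_date="2019-01-01",   # 2015-18 = alert-free reference
    settings=ModelSettings(pollutants=("pm25", "no2"),
                           candidates=("lightgbm",), seed=0),
    health=HealthConfig(gamma0_annual=0.00708,
                        gamma0_range=(0.0060, 0.0085)),
)
results = run_pipeline(config, "runs/demo")
print(results.summary())
mort = results.health_impact(config.health)
```

prints (abridged):

```
Baseline skill (held-out):
   pm25: IOA 0.831  r 0.709  RMSE 14.2 ug/m3  families ['lightgbm']
    no2: IOA 0.820  r 0.694  RMSE 11.4 ug/m3  families ['lightgbm']

Correction factors (median obs/pred on reference extremes):
   pm25: mean 1.738  range [1.589, 1.831]

Mean alert-day effects by tier (cross-city mean ± SE):
    none  pm25:     -0.1 ±   0.0 ug/m3     -0.5 ±   0.1 %   (n=4)
  yellow  pm25:    -31.7 ±   5.0 ug/m3    -21.2 ±   3.0 %   (n=4)
  orange  pm25:    -10.7 ±   4.1 ug/m3     -5.8 ±   2.7 %   (n=4)
```

and the mortality comparison gives

```
alert-day PM2.5 burden: observed 3260.8 vs counterfactual 3629.9 deaths
avoided deaths: 369.1  [216.8, 572.8]  (10.2%)
```

Reading it: the baseline clears the IOA ≥ 0.7 skill floor; factors of
~1.7 quantify how badly a clean-day model under-predicts extreme winter
days; control days ("none") sit at zero while alert days show tens of
μg m⁻³ reductions; and the counterfactual world without alerts would have
carried ~10% more short-term PM2.5 mortality. The tier pattern is not
monotone — yellow alerts show larger apparent effects than red ones —
because higher tiers fire deeper into pollution episodes and the default
scenario ramps the intervention in over two days.

The pipeline persists every stage (records, mask counts, predictions,
factors, effects, summaries, a run manifest) as plain CSV/JSON under the
output directory, and the same run is available from the shell:

```bash
alerteval run-all --config config.yaml --outdir runs/demo
alerteval simulate --config config.yaml --outdir runs/sim
alerteval compare-sources --config config.yaml --alt other_source.csv --outdir runs/cmp
```

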