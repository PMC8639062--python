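# cyclecast

Bayesian counterfactual analysis of monthly time series with a
second-order random-walk latent trend — built for estimating the
time-varying effect of an intervention (a pandemic lockdown, a policy
change) on an urban bike-sharing system, in the same spirit as
excess-mortality estimation.

## Who this is for and what it does

Given a monthly table of outcomes (total cycle hires; average hire time
in minutes) with weather covariates, `cyclecast`:

1. fits a Bayesian hierarchical regression to the pre-intervention
   window,

       y_t ~ Normal(λ_t, v),   λ_t = β0 + X_t·β + γ·y_{t−12} + u_t,

   where `u_t` is a second-order random walk (RW2) — a Gaussian Markov
   random field penalizing squared second differences, which captures
   smooth non-linear drift in demand while the lag-12 term and weather
   covariates carry the annual seasonality;
2. predicts the **counterfactual** for each post-intervention month —
   what the outcome would have been had the intervention not occurred —
   as a full posterior predictive (parameter + trend-forecast +
   observation noise);
3. reports the **estimated change** per month, observed minus
   counterfactual, as a median with an equal-tailed 95% credible
   interval, flagging months whose interval excludes zero;
4. validates the model by **leave-one-year-out cross-validation**
   (pooled adjusted R² and 95% coverage probability) and a residual
   normality check.

Everything is estimated by a blocked Gibbs sampler (exact joint Gaussian
updates of coefficients and trend; conjugate precision updates) with the
standard non-informative priors: Normal(0, 1000) coefficients,
Gamma(1, 0.01) precisions.

A first-class synthetic-data generator reproduces the statistical
structure the model assumes (seasonal weather with realistic marginal
moments, RW2 trend, lag-12 autocorrelation, injectable post-period
shocks), so the entire pipeline is testable — including parameter
recovery and shock-recovery experiments — without downloading anything.

## Worked example

Simulate an 11-year series, inject hire-time shocks of +16.5, +13.7 and
+10.1 minutes into April–June of the final year (emulating longer
pandemic-era trips), train through February, and estimate the monthly
change:

```python
import cyclecast as cc

truth = cc.default_truth(7)
truth.shocks["hire_time"] = {(2020, 4): 16.5, (2020, 5): 13.7, (2020, 6): 10.1}
series, truth = cc.simulate_series(126, truth=truth)

config = cc.ModelConfig(outcome_name="hire_time", n_chains=4,
                        n_iter=4000, n_burnin=2000, thin=4, seed=11)
result = cc.counterfactual_analysis(series, "hire_time",
                                    train_end=(2020, 2), horizon=10, config=config)
print(result.coefficient_table.round(3).to_string(index=False))
print(result.change_table.round(2).to_string(index=False))
```

Coefficients (medians with 95% credible intervals, back-transformed to
original units):

```
  parameter  median  lower  upper                          units
  intercept  19.256 18.927 19.603                hire_time units
temperature   0.214  0.091  0.335 hire_time per temperature unit
   humidity  -0.091 -0.174 -0.001    hire_time per humidity unit
      lag12   0.179 -0.010  0.356                       unitless
```

Warmer months mean longer hires (+0.21 min/°C), more humid ones shorter
(−0.09 min per % point), and this year's hire time tracks last year's
(γ ≈ 0.18) — matching the generating signs. The change table:

```
 year  month  observed  cf_median  change_median  change_lo  change_hi  important
 2020      3     15.96      17.43          -1.46      -5.62       2.66      False
 2020      4     33.80      19.86          13.94       9.15      18.42       True
 2020      5     32.86      20.81          12.06       7.11      17.18       True
 2020      6     29.89      22.03           7.86       2.20      13.54       True
 2020      7     18.27      21.27          -3.00      -9.30       3.54      False
 ...
 2020     12     17.95      17.12           0.83      -9.21      10.86      False
```

The three injected effects are recovered (estimates 13.9, 12.1, 7.9
minutes, each 95% interval covering the injected value) and exactly
those months are flagged `important` — the change interval excludes
zero precisely when the observed value falls outside the
counterfactual's 95% band. Intervals widen with horizon as the trend
forecast's uncertainty accumulates.

The same workflow runs from the shell:

```bash
cyclecast simulate --t 126 --seed 7 --shock "2020-04:+16.5,2020-05:+13.7,2020-06:+10.1" \
                   --out series.csv --truth-out truth.json
cyclecast predict  --data series.csv --outcome hire_time --train-end 2020-02 \
                   --horizon 10 --seed 11 --out change.csv
cyclecast cv       --data series.csv --outcome hires --seed 3
cyclecast fit      --data series.csv --outcome hire_time --seed 1
```

Input CSVs carry the header
`year,month,hires,hire_time,temperature,rainfall,wind,humidity,docking_stations`.

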