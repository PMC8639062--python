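# Methods

## The model

`cyclecast` estimates the time-varying effect of an intervention on a
monthly outcome by counterfactual comparison, in the style of
excess-mortality estimation: fit a model to the pre-intervention window,
predict what each post-intervention month *would have been*, and report
the posterior of observed minus counterfactual.

On the standardized scale (every variable centred and scaled to unit
sample sd over the training rows), the observation model is

    y_t ~ Normal(λ_t, v)
    λ_t = β0 + X_t·β + γ·y_{t−12} + u_t ,      t = 1, …, T′

where `X_t` holds the weather covariates (temperature, rainfall, wind for
hire counts; temperature, humidity for hire time), `y_{t−12}` is the
outcome one year earlier (annual seasonality in travel behaviour), and
`u_t` is a latent trend following a second-order random walk (RW2): an
intrinsic GMRF with density ∝ exp(−‖D u‖² / 2v_e), `D` the
second-difference operator. The RW2 penalizes curvature, not level or
slope — its null space is spanned by constants and the linear trend — so
it captures smooth non-linear drift in demand (system growth, gradual
behavioural change) without competing with the intercept for the mean.

Priors: Normal(0, 1000) on β0, β, γ; Gamma(shape 1, rate 0.01) on the
precisions 1/v and 1/v_e (the BUGS convention for "a Gamma prior on the
variance"; a literal variance prior is available via
`ModelConfig(prior_on="variance")`, sampled by log-scale Metropolis
steps). The first 12 months of a series are dropped from the outcome
side of the design rather than imputing unavailable lags.

### Identifiability and the constraint

The RW2's level is aliased with β0 (only the weak coefficient prior
separates them), so the sampler by default projects every joint draw
onto {Σu = 0} by conditioning-by-kriging — an exact draw from the
constrained posterior that pins the trend's level to the intercept's
benefit. The trend's *slope* is deliberately left free: the linear
predictor contains no other linear-time term, so the slope is identified
by the data, and constraining it away (the common pairing of Σt·u = 0
*with* an explicit linear covariate, which this model does not have)
would remove the model's ability to follow and forecast a local drift.
`constraint="projected"` additionally pins the slope;
`"unconstrained"` samples the literal model. All three agree on λ-scale
functionals up to the weak-prior level effect; tests validate the
sampler against an exactly marginalized quadrature oracle in both
constrained modes.

### Sampling

Blocked Gibbs: given (v, v_e), the full vector (β0, β, γ, u) is jointly
Gaussian and is drawn exactly through a Cholesky factor of its posterior
precision (the sparse RW2 structure plus the regression cross-products);
the two variances then follow by Gamma conjugacy on the precisions.
Chains are seeded `seed + chain`; runs are bit-reproducible. Defaults
are 4 chains × 20,000 iterations (half burn-in, thin 5); simulation
studies in the test-suite use 2–4 chains × 1,000–4,000 iterations,
which the quadrature-oracle comparisons show is sufficient for this
model's posterior means at T′ ≈ 40–114. Convergence is monitored by
split R-hat (arviz); values above 1.05 set a warning flag on the output
rather than raising, since short exploratory runs are legitimate.

### Counterfactual prediction

For each retained draw, the trend is extended by the RW2's own
predictive recursion u_{T+h} ~ Normal(2u_{T+h−1} − u_{T+h−2}, v_e) — the
exact conditional of the walk given its history (Markov in pairs), whose
mean is the straight-line continuation of the last two values and whose
variance grows cubically with horizon. The linear predictor uses the
*observed* post-period covariates and the observed lag-12 outcomes
(which predate the intervention and therefore cannot contaminate the
counterfactual), observation noise Normal(0, v) is added, and the result
is back-transformed to original units. Counterfactual uncertainty is
thus full posterior-predictive: parameter + trend-forecast + observation
noise — consistent with change intervals that widen with horizon.

The change table reports, per month, the observed value, the
counterfactual median and equal-tailed 95% interval (empirical
type-7 quantiles of the draws), and the change (observed −
counterfactual) whose interval is derived from the counterfactual's with
endpoints swapped — so the interval identities, and the equivalence
between "change interval excludes zero" and "observed outside the
counterfactual interval", hold exactly by construction. Months whose
change interval excludes zero are flagged statistically distinguishable.

## Validation machinery

*Leave-one-year-out CV*: each complete calendar year's outcomes are
treated as missing in turn (no likelihood contribution; the RW2 bridges
the gap through its conditionals, and lag-12 regressors remain observed
because held-out years are never adjacent), the twelve months are scored
at their posterior predictive, and all folds are pooled into an adjusted
R² (squared Pearson correlation of observed and predicted medians,
penalized by k = covariates + lag term) and the 95% coverage
probability. Per-year metrics are reported alongside the pooled ones.
*Residual normality*: Shapiro–Wilk on posterior-mean residuals y − λ̄.

## The synthetic generator

The generator emulates an 11-year London-style bike-share series so the
whole pipeline is testable without any data download:

- **Covariates**: temperature 12.14 + 6.3·sin(2π(m−4)/12) + N(0, 1.95²)
  °C (sample sd ≈ 4.85, July peak); rainfall log-normal with mean 1.73
  mm, sd 0.99 mm; wind Normal(4.90, 1.01²) mph floored at 0.1; humidity
  75.54 + 7·cos(2π(m−1)/12) + N(0, 4²) %, clipped to [60, 91]
  (winter-peaking); docking stations a saturating ramp 315 → 834.
  Seasonality shapes are this package's inventions tuned to the observed
  marginal moments; only those moments are treated as targets.
- **Outcomes**: generated from the model equations themselves (the same
  mean construction the sampler fits, so recovery failures indicate
  sampler bugs, not model mismatch) on the standardized scale, then
  mapped to original units with the observed location/scale (hires
  785,366 ± 237,648; hire time 19.28 ± 3.63 min). Default truth:
  β(temperature) = +0.35 (+0.30 for hire time), β(rainfall) = −0.12,
  β(wind) = −0.07, β(humidity) = −0.10, γ = 0.2, v = 0.25 — signs and
  rough sizes mirroring the reported coefficient table, documented as
  loosely data-inspired rather than ground truth.
- **Trend**: drawn from the RW2 restricted to the orthogonal complement
  of its null space, with v_e = 2.1e−4, giving a marginal trend sd ≈ 1.0
  on the standardized scale at T = 126. The observed hires range spans
  roughly five standard deviations across the study window, so a
  trend of order one standard deviation is the realistic emulation; it
  also places v_e where the Gamma(1, 0.01) precision prior has support.
  (The constrained RW2's marginal variance grows steeply with T —
  roughly T⁴ — so v_e values far below this make the truth smoother
  than anything the prior admits and the fitted trend overfits noise.)
- **Stream separation**: covariate noise and outcome noise use
  independently derived rng streams; seeding both from the same integer
  would alias the underlying bit streams and correlate "independent"
  noise with the covariates.
- **First-year lags**: the initial 12 lag values are drawn from the
  standardized marginal and are never part of any fitting window.
- **Shocks**: `inject_shock` adds the scheduled effects to the outcome
  column only, emulating an intervention for end-to-end recovery tests.
- Generated hires are rounded and floored at zero; at the default truth
  this censoring touches at most the odd month in a rare replicate.

What the generator does *not* emulate: multiplicative/heteroscedastic
noise, outcome skewness (real hire-time distributions are
right-skewed), station-level or user-segment structure, and weather
autocorrelation beyond the seasonal cycle. Passing tests therefore
demonstrate correctness of the machinery and calibration under the
model's own assumptions, not real-data validity — the CV and residual
checks are the tools for the latter.

## Numerical choices

- Standardization uses ddof = 1; constant columns raise a degenerate-
  scale error; round-trip identity is exact to 1e−12.
- The RW2 log-density uses the rank-(T−2) pseudo-determinant
  normalizer (constant in location, proper in v_e).
- Structure matrices D and Q are built in integer arithmetic, so the
  null-space identities Q·1 = 0 and Q·t = 0 are exact.
- Quantiles everywhere are empirical type-7 (numpy default); medians
  are reported, with posterior means available for CV scoring.
- Non-positive variances in `log_posterior` return −inf (a rejected
  state), not an exception.
- `sample_rw2_constrained` projects the null space out explicitly after
  the eigen-basis draw (eigenvectors of near-zero eigenvalues mix with
  the null space at machine precision).

## Problem sizes in tests and the acceptance script

Simulation studies run at the study scale (T = 126, lagged training
length 114): 20 replicates for coefficient recovery and shock recovery,
a 132-month series (ten complete held-out years, 120 pooled months) for
CV calibration, with 2–4 chains of 1,000–1,200 iterations — sizes at
which the oracle comparisons show the posterior summaries are stable.
The acceptance script uses 12 replicates per experiment.

## Known limitations

- Hire counts are modelled as a standardized continuous outcome, exactly
  as specified; no count likelihood is offered.
- The Gamma(1, 0.01) precision priors keep posterior v_e away from very
  small values, so very smooth truths are fitted with extra trend
  roughness; forecast intervals are correspondingly conservative at long
  horizons.
- RW2 forecasting extrapolates the trend's local gradient; its point
  forecasts degrade linearly in horizon when the trend turns, which is
  the price of the model's smoothness assumption and the reason the
  predictive intervals grow as they do.
- A single fixed v_e governs the whole window (no time-varying
  smoothness).
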