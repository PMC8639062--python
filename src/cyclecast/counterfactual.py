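"""Post-period counterfactual prediction and change estimation.

Given a model fitted to the pre-intervention window, the counterfactual
for each post-period month is the posterior predictive of the outcome had
the intervention not occurred: the latent trend is extended by the RW2
forecast recursion, the regression part uses the post-period covariates
and the observed lag-12 outcomes (which predate the intervention), and
Normal observation noise is added before back-transforming to original
units.  The estimated change is the posterior of observed minus
counterfactual, summarized as a median and an equal-tailed 95% credible
interval per month — months whose change interval excludes zero are
flagged as statistically distinguishable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_fit import ModelConfig, PosteriorDraws, fit_mcmc, summarize_posterior
from .timeseries_io import (
    DEFAULT_COVARIATES,
    MonthlySeries,
    RegressionData,
    StandardizationParams,
    build_design,
)

__all__ = [
    "PredictiveDraws",
    "predict_counterfactual",
    "estimate_change",
    "CounterfactualResult",
    "counterfactual_analysis",
    "plot_counterfactual",
]


@dataclass
class PredictiveDraws:
    """Counterfactual posterior-predictive draws on the original scale.

    ``draws[i, h]`` is draw i for post-period month ``months[h]``; the
    observation noise is included, so these are predictive, not mean, draws.
    """

    months: list[tuple[int, int]]
    draws: np.ndarray

    @property
    def horizon(self) -> int:
        return self.draws.shape[1]


def predict_counterfactual(
    draws: PosteriorDraws,
    post_covariates: pd.DataFrame,
    post_lag_values: np.ndarray,
    y_params: StandardizationParams,
    x_params: dict[str, StandardizationParams],
    rng_seed=0,
    months: list[tuple[int, int]] | None = None,
) -> PredictiveDraws:
    """Posterior-predictive counterfactual for the post-period months.

    Parameters
    ----------
    post_covariates
        One row per post month, original units, columns covering the
        fitted covariate names.
    post_lag_values
        Observed outcome 12 months before each post month, original units
        (these precede the intervention, so they do not contaminate the
        counterfactual).
    y_params, x_params
        The training-window standardizers from the fitted design.
    """
    horizon = len(post_covariates)
    if horizon == 0:
        raise ValueError("no post-period rows supplied")
    for name in draws.covariate_names:
        if name not in post_covariates.columns:
            raise ValueError(f"missing post-period covariate column {name!r}")
    post_lag_values = np.asarray(post_lag_values, dtype=float)
    if len(post_lag_values) != horizon:
        raise ValueError("post_lag_values length must match the horizon")
    if months is None:
        if {"year", "month"} <= set(post_covariates.columns):
            months = list(
                zip(
                    post_covariates["year"].astype(int),
                    post_covariates["month"].astype(int),
                )
            )
        else:
            months = [(0, h + 1) for h in range(horizon)]

    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    n = draws.n_draws

    Xs = np.column_stack(
        [
            x_params[name].apply(post_covariates[name].to_numpy(dtype=float))
            for name in draws.covariate_names
        ]
    ) if draws.covariate_names else np.empty((horizon, 0))
    lag_s = y_params.apply(post_lag_values)

    # RW2 forecast of the trend, one path per retained draw (vectorized
    # over draws, recursive over the horizon)
    sd_e = np.sqrt(draws.v_e)
    prev2, prev1 = draws.u[:, -2].copy(), draws.u[:, -1].copy()
    u_f = np.empty((n, horizon))
    for h in range(horizon):
        step = 2.0 * prev1 - prev2 + sd_e * rng.standard_normal(n)
        u_f[:, h] = step
        prev2, prev1 = prev1, step

    lam = (
        draws.beta0[:, None]
        + draws.beta @ Xs.T
        + draws.gamma[:, None] * lag_s[None, :]
        + u_f
    )
    y_std = lam + np.sqrt(draws.v)[:, None] * rng.standard_normal((n, horizon))
    return PredictiveDraws(months=months, draws=y_params.invert(y_std))


def estimate_change(observed_post: np.ndarray, predictive: PredictiveDraws) -> pd.DataFrame:
    """Monthly change table: observed, counterfactual, observed - counterfactual.

    The change interval is derived from the counterfactual interval with
    endpoints swapped (``change_lo = observed - cf_hi``), so the
    CI-identities — and the equivalence between "change interval excludes
    zero" and "observed lies outside the counterfactual interval" — hold
    exactly by construction.
    """
    observed = np.asarray(observed_post, dtype=float)
    if len(observed) != predictive.horizon:
        raise ValueError(
            f"observed has {len(observed)} months, predictive has {predictive.horizon}"
        )
    cf_lo, cf_med, cf_hi = np.quantile(predictive.draws, [0.025, 0.5, 0.975], axis=0)
    table = pd.DataFrame(
        {
            "year": [m[0] for m in predictive.months],
            "month": [m[1] for m in predictive.months],
            "observed": observed,
            "cf_median": cf_med,
            "cf_lo": cf_lo,
            "cf_hi": cf_hi,
            "change_median": observed - cf_med,
            "change_lo": observed - cf_hi,
            "change_hi": observed - cf_lo,
        }
    )
    table["important"] = (table["change_lo"] > 0) | (table["change_hi"] < 0)
    return table


@dataclass
class CounterfactualResult:
    """Everything the headline analysis produces."""

    data: RegressionData
    draws: PosteriorDraws
    predictive: PredictiveDraws
    change_table: pd.DataFrame
    coefficient_table: pd.DataFrame


def counterfactual_analysis(
    series: MonthlySeries,
    outcome_name: str,
    train_end: tuple[int, int] = (2020, 2),
    horizon: int = 10,
    config: ModelConfig | None = None,
    covariate_names=None,
) -> CounterfactualResult:
    """Fit on the pre-intervention window and estimate the monthly change.

    ``train_end`` is the last (year, month) used for fitting; the next
    ``horizon`` months are the post period whose observed covariates (and
    observed lag-12 outcomes) drive the counterfactual.
    """
    if config is None:
        config = ModelConfig(outcome_name=outcome_name)
    if covariate_names is None:
        covariate_names = config.covariate_names or DEFAULT_COVARIATES[outcome_name]

    months = series.months
    key = train_end[0] * 12 + train_end[1]
    codes = np.array([y * 12 + m for y, m in months])
    if key not in codes:
        raise ValueError(f"train_end {train_end} not in series")
    cut = int(np.flatnonzero(codes == key)[0]) + 1
    if cut + horizon > len(months):
        raise ValueError(
            f"series ends before train_end + horizon ({horizon} months needed)"
        )

    train = series.subset(np.arange(len(months)) < cut)
    data = build_design(train, outcome_name, covariate_names, lag=config.lag)
    draws = fit_mcmc(data, config)

    post = series.frame.iloc[cut : cut + horizon]
    lag_idx = np.arange(cut, cut + horizon) - config.lag
    if lag_idx[0] < 0:
        raise ValueError("post-period lag values precede the series start")
    post_lag = series.column(outcome_name)[lag_idx]
    predictive = predict_counterfactual(
        draws,
        post,
        post_lag,
        data.y_params,
        data.x_params,
        rng_seed=np.random.default_rng(config.seed + 10_000),
    )
    observed_post = post[outcome_name].to_numpy(dtype=float)
    change = estimate_change(observed_post, predictive)
    coef = summarize_posterior(draws, data)
    return CounterfactualResult(
        data=data,
        draws=draws,
        predictive=predictive,
        change_table=change,
        coefficient_table=coef,
    )


def plot_counterfactual(result: CounterfactualResult, path, title: str | None = None):
    """Observed vs counterfactual band for the post period (PNG export)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = result.change_table
    x = np.arange(len(t))
    labels = [f"{int(y)}-{int(m):02d}" for y, m in zip(t["year"], t["month"])]
    fig, ax = plt.subplots(figsize=(8, 4.5))
    ax.fill_between(x, t["cf_lo"], t["cf_hi"], alpha=0.3, label="counterfactual 95% CI")
    ax.plot(x, t["cf_median"], "--", label="counterfactual median")
    ax.plot(x, t["observed"], "o-", label="observed")
    ax.set_xticks(x, labels, rotation=45)
    ax.set_ylabel(result.data.outcome_name)
    ax.legend()
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
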