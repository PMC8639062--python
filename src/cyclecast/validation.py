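"""Model-adequacy checks: leave-one-year-out CV, adjusted R², coverage,
and a residual-normality test.

Leave-one-year-out cross-validation refits the model with one calendar
year's outcomes treated as missing; the RW2 bridges the held-out gap
through its conditionals, while covariates and the lag-12 outcome use
observed values (known at prediction time, since held-out years are never
adjacent).  The twelve months of each fold are scored at their posterior
predictive, and predictions from all folds are pooled into the two
overall metrics: adjusted R² and the 95% coverage probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model_fit import ModelConfig, PosteriorDraws, fit_mcmc, linear_predictor
from .timeseries_io import DEFAULT_COVARIATES, MonthlySeries, RegressionData, build_design

__all__ = [
    "UndefinedMetricError",
    "adjusted_r2",
    "adjusted_r2_from_r2",
    "coverage_probability",
    "NormalityResult",
    "residual_normality",
    "fitted_residuals",
    "CVReport",
    "leave_one_year_out",
]


class UndefinedMetricError(ValueError):
    """Metric undefined for this input (e.g. zero variance)."""


def adjusted_r2_from_r2(r2: float, n: int, k: int) -> float:
    if n <= k + 1:
        raise UndefinedMetricError(f"need n > k + 1 (n={n}, k={k})")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)


def adjusted_r2(observed, predicted, n: int | None = None, k: int = 1) -> float:
    """1 - (1 - R²)(n-1)/(n-k-1) with R² the squared Pearson correlation."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must have equal length")
    if np.std(obs) == 0 or np.std(pred) == 0:
        raise UndefinedMetricError("zero variance in observed or predicted")
    if n is None:
        n = len(obs)
    r2 = float(np.corrcoef(obs, pred)[0, 1]) ** 2
    return adjusted_r2_from_r2(r2, n, k)


def coverage_probability(observed, lower, upper) -> float:
    """Fraction of observations inside their [lower, upper] interval."""
    obs = np.asarray(observed, dtype=float)
    lo = np.asarray(lower, dtype=float)
    hi = np.asarray(upper, dtype=float)
    if not (obs.shape == lo.shape == hi.shape):
        raise ValueError("all three vectors must have equal length")
    if np.any(lo > hi):
        raise ValueError("crossed interval bounds (lower > upper)")
    return float(np.mean((lo <= obs) & (obs <= hi)))


@dataclass(frozen=True)
class NormalityResult:
    statistic: float
    pvalue: float
    normal: bool


def residual_normality(residuals, alpha: float = 0.05) -> NormalityResult:
    """Shapiro–Wilk test on point (posterior-mean) residuals."""
    x = np.asarray(residuals, dtype=float)
    if len(x) < 8:
        raise ValueError("need at least 8 residuals")
    if np.std(x) == 0:
        raise UndefinedMetricError("constant residuals")
    stat, p = stats.shapiro(x)
    return NormalityResult(statistic=float(stat), pvalue=float(p), normal=bool(p >= alpha))


def fitted_residuals(draws: PosteriorDraws, data: RegressionData) -> np.ndarray:
    """y - posterior mean of lambda, on the standardized scale, observed rows."""
    lam_bar = linear_predictor(draws, data).mean(axis=0)
    return (data.y - lam_bar)[data.obs_mask]


@dataclass
class CVReport:
    """Per-month held-out predictions plus pooled and per-year metrics."""

    monthly: pd.DataFrame
    adjusted_r2: float
    coverage: float
    per_year: pd.DataFrame


def _complete_years(series: MonthlySeries, lag: int) -> list[int]:
    months = series.months[lag:]
    by_year: dict[int, int] = {}
    for y, _ in months:
        by_year[y] = by_year.get(y, 0) + 1
    return sorted(y for y, c in by_year.items() if c == 12)


def leave_one_year_out(
    series: MonthlySeries,
    config: ModelConfig | None = None,
    years=None,
    point: str = "median",
) -> CVReport:
    """Leave-one-year-out cross-validation of the fitted model class.

    ``years`` defaults to every calendar year fully inside the lagged
    design window.  ``point`` selects the prediction scored by adjusted R²
    (posterior "median", or "mean").  Deterministic given ``config.seed``.
    """
    if config is None:
        config = ModelConfig()
    if point not in ("median", "mean"):
        raise ValueError("point must be 'median' or 'mean'")
    covariates = config.covariate_names or DEFAULT_COVARIATES[config.outcome_name]
    available = _complete_years(series, config.lag)
    if years is None:
        years = available
    years = sorted(int(y) for y in years)
    missing = [y for y in years if y not in available]
    if missing:
        raise ValueError(f"year(s) {missing} not complete in the series")
    if len(years) < 3:
        raise ValueError("need at least 3 complete years for cross-validation")

    raw_years = np.array([y for y, _ in series.months])
    rows = []
    year_metrics = []
    for fold, year in enumerate(years):
        train_mask = raw_years != year
        data = build_design(series, config.outcome_name, covariates, config.lag, train_mask)
        # one held-out year at a time: its lag-12 neighbours are observed
        held = ~data.obs_mask
        assert held.sum() == 12
        fold_config = ModelConfig(
            **{
                **config.__dict__,
                "covariate_names": tuple(covariates),
                "seed": config.seed + fold,
            }
        )
        draws = fit_mcmc(data, fold_config)
        rng = np.random.default_rng(config.seed + 50_000 + fold)
        lam = linear_predictor(draws, data)[:, held]
        y_pred = lam + np.sqrt(draws.v)[:, None] * rng.standard_normal(lam.shape)
        y_pred = data.y_params.invert(y_pred)
        lo, med, hi = np.quantile(y_pred, [0.025, 0.5, 0.975], axis=0)
        center = med if point == "median" else y_pred.mean(axis=0)
        obs = data.y_params.invert(data.y[held])
        held_months = [m for m, h in zip(data.months, held) if h]
        for (yy, mm), o, c, l, h in zip(held_months, obs, center, lo, hi):
            rows.append((yy, mm, o, c, l, h))
        k = data.k + 1  # covariates plus the lag term
        year_metrics.append(
            (
                year,
                adjusted_r2(obs, center, k=k),
                coverage_probability(obs, lo, hi),
            )
        )

    monthly = pd.DataFrame(
        rows,
        columns=["year", "month", "observed", "predicted", "lower", "upper"],
    )
    k = len(covariates) + 1
    pooled_r2 = adjusted_r2(monthly["observed"], monthly["predicted"], k=k)
    pooled_cov = coverage_probability(monthly["observed"], monthly["lower"], monthly["upper"])
    per_year = pd.DataFrame(year_metrics, columns=["year", "adjusted_r2", "coverage"])
    return CVReport(
        monthly=monthly,
        adjusted_r2=pooled_r2,
        coverage=pooled_cov,
        per_year=per_year,
    )
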