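"""Reading, validation and design construction for monthly bike-share series.

A :class:`MonthlySeries` is the raw pipeline input: a strictly consecutive
monthly table of the two outcomes (total cycle hires and average hire time in
minutes), weather covariates and the docking-station count.  Before model
fitting, every variable is standardized (centred and scaled to unit sample
standard deviation) and the rows are aligned with the lagged outcome into a
:class:`RegressionData` design.

Standardization statistics are always computed on the training rows only, so
that held-out or post-intervention rows never leak into the scaling used to
build their own counterfactual.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "ContinuityError",
    "SeriesValidationError",
    "DegenerateScaleError",
    "InsufficientDataError",
    "MonthlySeries",
    "StandardizationParams",
    "RegressionData",
    "load_monthly_series",
    "standardize",
    "back_transform",
    "build_design",
    "REQUIRED_COLUMNS",
    "DEFAULT_COVARIATES",
    "VALID_LAGS",
]


class SchemaError(ValueError):
    """A required column is missing from the input table."""


class ContinuityError(ValueError):
    """Months are not strictly consecutive (gap or duplicate)."""


class SeriesValidationError(ValueError):
    """A cell violates a range or type constraint."""


class DegenerateScaleError(ValueError):
    """Standardization requested for a (near-)constant vector."""


class InsufficientDataError(ValueError):
    """Too few rows to build the requested lagged design."""


REQUIRED_COLUMNS = (
    "year",
    "month",
    "hires",
    "hire_time",
    "temperature",
    "rainfall",
    "wind",
    "humidity",
    "docking_stations",
)

OUTCOME_COLUMNS = ("hires", "hire_time")

#: Covariate sets with a reported effect for each outcome; the
#: docking-station count is validated but not a default regressor.
DEFAULT_COVARIATES: Mapping[str, tuple[str, ...]] = {
    "hires": ("temperature", "rainfall", "wind"),
    "hire_time": ("temperature", "humidity"),
}

VALID_LAGS = (1, 2, 6, 12)

#: Shortest series accepted: one lag-12 year plus the five RW2 branch cases.
MIN_LENGTH = 17


@dataclass(frozen=True)
class MonthlySeries:
    """A validated, chronologically ordered monthly table.

    Construct via :meth:`from_frame` or :func:`load_monthly_series`; the
    constructor itself performs no checks.
    """

    frame: pd.DataFrame

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "MonthlySeries":
        missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        df = frame.loc[:, list(REQUIRED_COLUMNS)].copy()
        for col in REQUIRED_COLUMNS:
            values = pd.to_numeric(df[col], errors="coerce")
            bad = values.isna() & df[col].notna()
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise SeriesValidationError(
                    f"non-numeric value in column '{col}' at row {row}: "
                    f"{df[col].iloc[row]!r}"
                )
            if values.isna().any():
                row = int(np.flatnonzero(values.isna().to_numpy())[0])
                raise SeriesValidationError(f"missing value in column '{col}' at row {row}")
            df[col] = values
        df = df.sort_values(["year", "month"], kind="mergesort").reset_index(drop=True)

        months = df["year"].to_numpy(dtype=int) * 12 + df["month"].to_numpy(dtype=int)
        if not np.all((df["month"] >= 1) & (df["month"] <= 12)):
            raise SeriesValidationError("month must be in 1..12")
        steps = np.diff(months)
        if np.any(steps == 0):
            i = int(np.flatnonzero(steps == 0)[0])
            raise ContinuityError(
                f"duplicate month {int(df['year'][i])}-{int(df['month'][i]):02d}"
            )
        if np.any(steps != 1):
            i = int(np.flatnonzero(steps != 1)[0])
            raise ContinuityError(
                f"gap after {int(df['year'][i])}-{int(df['month'][i]):02d}"
            )

        if (df["hires"] < 0).any():
            raise SeriesValidationError("hires must be non-negative")
        if (df["hire_time"] <= 0).any():
            raise SeriesValidationError("hire_time must be positive")
        if ((df["humidity"] < 0) | (df["humidity"] > 100)).any():
            raise SeriesValidationError("humidity must lie in [0, 100]")
        if (df["docking_stations"] < 0).any():
            raise SeriesValidationError("docking_stations must be non-negative")
        if len(df) < MIN_LENGTH:
            raise SeriesValidationError(
                f"series too short: {len(df)} rows < minimum {MIN_LENGTH}"
            )
        return cls(frame=df)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def T(self) -> int:
        return len(self.frame)

    @property
    def months(self) -> list[tuple[int, int]]:
        """``(year, month)`` pairs in chronological order."""
        return list(
            zip(
                self.frame["year"].astype(int).tolist(),
                self.frame["month"].astype(int).tolist(),
            )
        )

    def column(self, name: str) -> np.ndarray:
        return self.frame[name].to_numpy(dtype=float)

    def subset(self, mask: np.ndarray) -> "MonthlySeries":
        """Contiguous row subset (re-validated)."""
        return MonthlySeries.from_frame(self.frame.loc[np.asarray(mask, dtype=bool)])

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def load_monthly_series(path) -> MonthlySeries:
    """Read and validate the standard monthly CSV.

    The header must name every column in :data:`REQUIRED_COLUMNS`; cells are
    plain decimal numbers (UTF-8, no thousands separators).
    """
    frame = pd.read_csv(path)
    return MonthlySeries.from_frame(frame)


@dataclass(frozen=True)
class StandardizationParams:
    """Location/scale pair mapping original units to the model scale."""

    mean: float
    sd: float

    def apply(self, values: np.ndarray) -> np.ndarray:
        return (np.asarray(values, dtype=float) - self.mean) / self.sd

    def invert(self, values: np.ndarray) -> np.ndarray:
        return np.asarray(values, dtype=float) * self.sd + self.mean


def standardize(values) -> tuple[np.ndarray, StandardizationParams]:
    """Centre and scale to sample mean 0, sample sd 1 (ddof=1)."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("standardize expects a 1-d vector of length >= 2")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    if sd == 0.0 or not np.isfinite(sd):
        raise DegenerateScaleError("cannot standardize a constant vector")
    params = StandardizationParams(mean=mean, sd=sd)
    return params.apply(x), params


def back_transform(values, params: StandardizationParams) -> np.ndarray:
    """Undo :func:`standardize`: ``values * sd + mean``."""
    return params.invert(values)


@dataclass
class RegressionData:
    """Model-ready aligned design on the standardized scale.

    Row ``i`` pairs the outcome at month ``lag + i`` of the raw series with
    its covariates and the outcome ``lag`` months earlier.  ``obs_mask``
    marks rows whose outcome enters the likelihood; rows with ``False`` are
    treated as missing (their latent trend is still estimated, which is how
    leave-one-year-out prediction bridges a held-out year).
    """

    y: np.ndarray
    X: np.ndarray
    y_lag: np.ndarray
    time_index: np.ndarray
    outcome_name: str
    covariate_names: tuple[str, ...]
    y_params: StandardizationParams
    x_params: dict[str, StandardizationParams]
    months: list[tuple[int, int]]
    obs_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    lag: int = 12

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        self.y_lag = np.asarray(self.y_lag, dtype=float)
        self.time_index = np.asarray(self.time_index, dtype=int)
        if self.obs_mask is None:
            self.obs_mask = np.ones(len(self.y), dtype=bool)
        self.obs_mask = np.asarray(self.obs_mask, dtype=bool)

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def k(self) -> int:
        return self.X.shape[1]


def _masked_params(values: np.ndarray, mask: np.ndarray) -> StandardizationParams:
    sel = values[mask]
    if len(sel) < 2:
        raise InsufficientDataError("fewer than 2 training rows for standardization")
    sd = float(np.std(sel, ddof=1))
    if sd == 0.0:
        raise DegenerateScaleError("constant training column")
    return StandardizationParams(mean=float(np.mean(sel)), sd=sd)


def build_design(
    series: MonthlySeries,
    outcome_name: str,
    covariate_names: Sequence[str] | None = None,
    lag: int = 12,
    train_mask: np.ndarray | None = None,
) -> RegressionData:
    """Align outcome, covariates and the lagged outcome into a design.

    The first ``lag`` months are dropped from the outcome side (no imputation
    of unavailable lags).  Standardization statistics use only rows marked
    ``True`` in ``train_mask`` (a boolean over the raw months; default all).

    Parameters
    ----------
    lag
        Lag of the autoregressive outcome term, one of {1, 2, 6, 12}.
    """
    if outcome_name not in OUTCOME_COLUMNS:
        raise ValueError(f"unknown outcome {outcome_name!r}; expected one of {OUTCOME_COLUMNS}")
    if lag not in VALID_LAGS:
        raise ValueError(f"lag must be one of {VALID_LAGS}, got {lag}")
    if covariate_names is None:
        covariate_names = DEFAULT_COVARIATES[outcome_name]
    covariate_names = tuple(covariate_names)
    for name in covariate_names:
        if name not in series.frame.columns:
            raise SchemaError(f"covariate {name!r} not a series column")

    T = series.T
    if T <= lag + 4:
        raise InsufficientDataError(f"need T > lag + 4 = {lag + 4} rows, got {T}")
    if train_mask is None:
        train_mask = np.ones(T, dtype=bool)
    train_mask = np.asarray(train_mask, dtype=bool)
    if train_mask.shape != (T,):
        raise ValueError("train_mask must be boolean of length T")

    y_raw = series.column(outcome_name)
    obs_mask = train_mask[lag:]
    y_params = _masked_params(y_raw[lag:], obs_mask)
    y = y_params.apply(y_raw[lag:])
    y_lag = y_params.apply(y_raw[:-lag])

    x_params: dict[str, StandardizationParams] = {}
    cols = []
    for name in covariate_names:
        raw = series.column(name)[lag:]
        p = _masked_params(raw, obs_mask)
        x_params[name] = p
        cols.append(p.apply(raw))
    X = np.column_stack(cols) if cols else np.empty((T - lag, 0))

    return RegressionData(
        y=y,
        X=X,
        y_lag=y_lag,
        time_index=np.arange(1, T - lag + 1),
        outcome_name=outcome_name,
        covariate_names=covariate_names,
        y_params=y_params,
        x_params=x_params,
        months=series.months[lag:],
        obs_mask=obs_mask,
        lag=lag,
    )
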