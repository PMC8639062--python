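import warnings

import numpy as np
import pytest

from cyclecast import ModelConfig, build_design, simulate_series

# short-chain fits in tests may legitimately trip the R-hat warning flag
warnings.filterwarnings("ignore", message="MCMC may not have converged")


@pytest.fixture(scope="session")
def small_series():
    """A 52-month synthetic series (T'=40 under lag 12)."""
    series, truth = simulate_series(52, seed=9)
    return series, truth


@pytest.fixture(scope="session")
def study_series():
    """A study-scale 126-month synthetic series (T'=114 under lag 12)."""
    series, truth = simulate_series(126, seed=1)
    return series, truth


@pytest.fixture(scope="session")
def quick_config():
    """Short-but-usable MCMC settings for unit tests."""
    return ModelConfig(
        outcome_name="hires", n_chains=2, n_iter=1200, n_burnin=400, thin=2, seed=3
    )


@pytest.fixture(scope="session")
def fitted_hires(study_series, quick_config):
    """One fitted model on the study-scale series, shared across tests."""
    from cyclecast import fit_mcmc

    series, _ = study_series
    data = build_design(series, "hires")
    draws = fit_mcmc(data, quick_config)
    return data, draws


def constrained_basis(n: int, n_con: int = 2) -> np.ndarray:
    """Orthonormal basis of the trend subspace under the level (and,
    with ``n_con=2``, slope) constraint."""
    C = np.column_stack([np.ones(n), np.arange(1, n + 1)])[:, :n_con]
    Qfull, _ = np.linalg.qr(C, mode="complete")
    return Qfull[:, n_con:]
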