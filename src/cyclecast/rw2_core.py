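"""Second-order random-walk (RW2) latent trend.

The RW2 is an intrinsic Gaussian Markov random field penalizing squared
second differences of the latent path u_1..u_T: with D the (T-2) x T
second-difference operator, the joint (improper) density is

    p(u | v_e)  ∝  exp( -||D u||^2 / (2 v_e) ),

with precision Q/v_e, Q = DᵀD of rank T-2.  Its null space is spanned by
constants and the linear trend, so the RW2 smooths without fighting a level
or a drift.  The full conditionals of this field have five branches (two at
each boundary, one interior); both forms are implemented here independently
and must agree, which the test-suite asserts against a Schur-complement
oracle.

Forecasting extends the walk sequentially: u_{T+h} ~ Normal(2 u_{T+h-1} -
u_{T+h-2}, v_e), so the predictive mean follows the straight-line
extrapolation of the last two values and the predictive variance grows with
the horizon.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

__all__ = [
    "RW2Structure",
    "second_difference_matrix",
    "rw2_structure",
    "rw2_conditional",
    "rw2_logdensity",
    "sample_rw2_forecast",
    "sample_rw2_constrained",
]

#: smallest T at which all five conditional branches are distinct
MIN_T = 5


def second_difference_matrix(T: int) -> np.ndarray:
    """The (T-2) x T operator with rows (1, -2, 1); integer dtype."""
    if T < MIN_T:
        raise ValueError(f"T must be >= {MIN_T}, got {T}")
    D = np.zeros((T - 2, T), dtype=np.int64)
    idx = np.arange(T - 2)
    D[idx, idx] = 1
    D[idx, idx + 1] = -2
    D[idx, idx + 2] = 1
    return D


@dataclass(frozen=True)
class RW2Structure:
    """Second-difference operator D and structure matrix Q = DᵀD."""

    D: np.ndarray
    Q: np.ndarray


def rw2_structure(T: int) -> RW2Structure:
    D = second_difference_matrix(T)
    return RW2Structure(D=D, Q=D.T @ D)


def rw2_conditional(t: int, u: np.ndarray, v_e: float) -> tuple[float, float]:
    """Full conditional mean and variance of u_t given the rest.

    ``t`` is 1-based.  The five branches (t = 1, 2, interior, T-1, T) carry
    conditional variances v_e, v_e/5, v_e/6, v_e/5, v_e respectively — the
    more second-order neighbours, the smaller the variance.
    """
    u = np.asarray(u, dtype=float)
    T = len(u)
    if T < MIN_T:
        raise ValueError(f"need T >= {MIN_T}")
    if not 1 <= t <= T:
        raise IndexError(f"t={t} out of range 1..{T}")
    i = t - 1  # 0-based
    if t == 1:
        return 2.0 * u[1] - u[2], v_e
    if t == 2:
        return 0.4 * u[0] + 0.8 * u[2] - 0.2 * u[3], v_e / 5.0
    if t == T - 1:
        return -0.2 * u[i - 2] + 0.8 * u[i - 1] + 0.4 * u[i + 1], v_e / 5.0
    if t == T:
        return -u[i - 2] + 2.0 * u[i - 1], v_e
    mean = (-u[i - 2] + 4.0 * (u[i - 1] + u[i + 1]) - u[i + 2]) / 6.0
    return mean, v_e / 6.0


@lru_cache(maxsize=64)
def _log_pdet_Q(T: int) -> float:
    # pdet(DᵀD) = det(D Dᵀ) since D has full row rank
    D = second_difference_matrix(T).astype(float)
    sign, logdet = np.linalg.slogdet(D @ D.T)
    return float(logdet)


def rw2_logdensity(u: np.ndarray, v_e: float) -> float:
    """Log density of the intrinsic RW2 field (rank T-2 normalization).

    Uses the pseudo-determinant normalizer: ((T-2)/2) log(1/(2 pi v_e)) +
    (1/2) log pdet(Q) - ||D u||^2 / (2 v_e).  Improper over the 2-dim null
    space {1, t}.
    """
    if v_e <= 0:
        raise ValueError("v_e must be positive")
    u = np.asarray(u, dtype=float)
    T = len(u)
    D = second_difference_matrix(T)
    quad = float(np.sum((D @ u) ** 2))
    rank = T - 2
    return (
        -0.5 * rank * np.log(2.0 * np.pi * v_e)
        + 0.5 * _log_pdet_Q(T)
        - quad / (2.0 * v_e)
    )


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_rw2_forecast(
    u_train: np.ndarray,
    v_e: float,
    horizon: int,
    rng_seed,
    n_draws: int = 1,
) -> np.ndarray:
    """Sequential RW2 extrapolation past the end of a fitted path.

    Returns an array of shape ``(n_draws, horizon)``; draw ``j``, column
    ``h`` is u_{T+h+1} generated recursively from Normal(2 u_prev - u_prev2,
    v_e).  With v_e -> 0 this is exactly the straight line through the last
    two training values.
    """
    if horizon <= 0:
        raise ValueError("horizon must be >= 1")
    u_train = np.asarray(u_train, dtype=float)
    if len(u_train) < 2:
        raise ValueError("need at least two trailing trend values")
    if v_e < 0:
        raise ValueError("v_e must be non-negative")
    rng = _as_rng(rng_seed)
    sd = float(np.sqrt(v_e))
    prev2 = np.full(n_draws, u_train[-2])
    prev1 = np.full(n_draws, u_train[-1])
    out = np.empty((n_draws, horizon))
    for h in range(horizon):
        mean = 2.0 * prev1 - prev2
        step = mean + sd * rng.standard_normal(n_draws) if sd > 0 else mean
        out[:, h] = step
        prev2, prev1 = prev1, step
    return out


@lru_cache(maxsize=16)
def _constrained_factor(T: int) -> np.ndarray:
    """B with B Bᵀ = pseudo-inverse of Q; columns span the non-null space."""
    Q = rw2_structure(T).Q.astype(float)
    w, V = np.linalg.eigh(Q)
    nz = w > w[-1] * 1e-12
    return V[:, nz] / np.sqrt(w[nz])


def sample_rw2_constrained(T: int, v_e: float, rng_seed) -> np.ndarray:
    """Draw an RW2 path orthogonal to its null space (sum 0, zero slope).

    Used by the synthetic generator; the orthogonality to {1, t} matches the
    identifiability constraint imposed at fitting time.
    """
    if v_e < 0:
        raise ValueError("v_e must be non-negative")
    rng = _as_rng(rng_seed)
    if v_e == 0:
        # keep the rng stream position consistent with the noisy path
        rng.standard_normal(T - 2)
        return np.zeros(T)
    B = _constrained_factor(T)
    u = np.sqrt(v_e) * (B @ rng.standard_normal(B.shape[1]))
    # eigenvectors of near-zero eigenvalues mix slightly with the null
    # space at machine precision; project it out explicitly
    ones = np.ones(T) / np.sqrt(T)
    t = np.arange(1, T + 1, dtype=float)
    t -= t @ ones * ones
    t /= np.linalg.norm(t)
    u -= (u @ ones) * ones + (u @ t) * t
    return u
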