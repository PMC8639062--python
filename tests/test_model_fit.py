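import numpy as np
import pytest
from scipy.stats import gamma as gamma_dist, multivariate_normal, norm

from cyclecast import (
    ModelConfig,
    PosteriorDraws,
    RegressionData,
    StandardizationParams,
    build_design,
    fit_mcmc,
    gelman_rubin,
    log_posterior,
    simulate_series,
    summarize_posterior,
)
from cyclecast.rw2_core import rw2_structure, second_difference_matrix

from conftest import constrained_basis


def independent_log_posterior(p, data, config):
    """Separately coded model density (different summation order, scipy pdfs)."""
    u = np.asarray(p["u"], dtype=float)
    beta = np.atleast_1d(np.asarray(p["beta"], dtype=float))
    lam = p["beta0"] + data.X @ beta + p["gamma"] * data.y_lag + u
    total = 0.0
    for t in np.flatnonzero(data.obs_mask):
        total += norm.logpdf(data.y[t], lam[t], np.sqrt(p["v"]))
    T = data.n
    D = second_difference_matrix(T).astype(float)
    _, logpdet = np.linalg.slogdet(D @ D.T)
    d2 = D @ u
    total += (
        -0.5 * (T - 2) * np.log(2 * np.pi * p["v_e"])
        + 0.5 * logpdet
        - (d2 @ d2) / (2 * p["v_e"])
    )
    for coef in [p["beta0"], *beta, p["gamma"]]:
        total += norm.logpdf(coef, 0.0, np.sqrt(config.coef_prior_variance))
    for var in (p["v"], p["v_e"]):
        total += gamma_dist.logpdf(
            1.0 / var, config.var_prior_shape, scale=1.0 / config.var_prior_rate
        )
    return total


def random_state(rng, data):
    return dict(
        beta0=rng.standard_normal(),
        beta=rng.standard_normal(data.k),
        gamma=rng.standard_normal(),
        u=rng.standard_normal(data.n),
        v=float(rng.uniform(0.1, 3.0)),
        v_e=float(rng.uniform(0.1, 3.0)),
    )


class TestLogPosterior:
    def test_matches_independent_implementation(self, small_series):
        series, _ = small_series
        data = build_design(series, "hires")
        config = ModelConfig(outcome_name="hires")
        rng = np.random.default_rng(0)
        for _ in range(100):
            p = random_state(rng, data)
            assert log_posterior(p, data, config) == pytest.approx(
                independent_log_posterior(p, data, config), abs=1e-9
            )

    def test_finite_on_simulated_design(self):
        series, _ = simulate_series(62, seed=6)  # T'=50
        data = build_design(series, "hires")
        config = ModelConfig(outcome_name="hires")
        p = random_state(np.random.default_rng(1), data)
        assert np.isfinite(log_posterior(p, data, config))

    def test_nonpositive_variance_is_rejected_state(self, small_series):
        series, _ = small_series
        data = build_design(series, "hires")
        config = ModelConfig(outcome_name="hires")
        p = random_state(np.random.default_rng(2), data)
        p["v"] = 0.0
        assert log_posterior(p, data, config) == -np.inf
        p["v"], p["v_e"] = 1.0, -0.5
        assert log_posterior(p, data, config) == -np.inf


def quadrature_posterior_means(data, config, n_con, n_grid=(50, 60)):
    """Exact oracle: theta integrated analytically, 2-d grid over (v, v_e).

    Works on the constrained parameterization u = Z w, matching the
    projection constraint the sampler imposes.
    """
    n, k = data.n, data.k
    Q = rw2_structure(n).Q.astype(float)
    Z = constrained_basis(n, n_con)
    # prior covariance of the trend coordinates: inverse of Z'QZ on its
    # range; with the level-only constraint the slope direction is flat
    # (improper), integrated here as a near-flat direction with a huge
    # variance (exact in the limit; the error is O(posterior var / BIG))
    ZQZ = Z.T @ Q @ Z
    w, V = np.linalg.eigh(ZQZ)
    proper = w > w[-1] * 1e-9
    BIG = 1e7
    M = (V[:, proper] / w[proper]) @ V[:, proper].T
    M_flat = V[:, ~proper] @ V[:, ~proper].T
    A = np.column_stack([np.ones(n), data.X, data.y_lag, Z])
    A = A[data.obs_mask]
    y = data.y[data.obs_mask]
    c = config.coef_prior_variance
    a0, r0 = config.var_prior_shape, config.var_prior_rate

    lvs = np.linspace(np.log(0.05), np.log(2.0), n_grid[0])
    lves = np.linspace(np.log(1e-6), np.log(2.0), n_grid[1])
    logw = np.full((len(lvs), len(lves)), -np.inf)
    cond = np.zeros((len(lvs), len(lves), k + 2))
    p_dim = A.shape[1]
    for i, lv in enumerate(lvs):
        v = np.exp(lv)
        for j, lve in enumerate(lves):
            ve = np.exp(lve)
            S0 = np.zeros((p_dim, p_dim))
            S0[: k + 2, : k + 2] = c * np.eye(k + 2)
            S0[k + 2 :, k + 2 :] = ve * M + BIG * M_flat
            cov = A @ S0 @ A.T + v * np.eye(len(y))
            ll = multivariate_normal.logpdf(y, mean=np.zeros(len(y)), cov=cov)
            # Gamma prior on each precision, with the change of measure to
            # the log-variance grid
            prior = (
                gamma_dist.logpdf(1 / v, a0, scale=1 / r0)
                + gamma_dist.logpdf(1 / ve, a0, scale=1 / r0)
                - lv
                - lve
            )
            logw[i, j] = ll + prior
            G = S0 @ A.T @ np.linalg.solve(cov, y)
            cond[i, j] = G[: k + 2]
    W = np.exp(logw - logw.max())
    W /= W.sum()
    return (W[..., None] * cond).sum(axis=(0, 1))


class TestSampler:
    def test_seeded_runs_identical(self, small_series):
        series, _ = small_series
        data = build_design(series, "hires")
        config = ModelConfig(
            outcome_name="hires", n_chains=2, n_iter=300, n_burnin=100, thin=2, seed=5
        )
        a, b = fit_mcmc(data, config), fit_mcmc(data, config)
        assert np.array_equal(a.beta0, b.beta0)
        assert np.array_equal(a.u, b.u)
        assert np.array_equal(a.v_e, b.v_e)

    @pytest.mark.parametrize("constraint,n_con", [("sum", 1), ("projected", 2)])
    def test_posterior_means_match_exact_quadrature(self, small_series, constraint, n_con):
        """Gibbs vs the analytically marginalized posterior (deterministic)."""
        series, _ = small_series
        data = build_design(series, "hires", covariate_names=("temperature",))
        config = ModelConfig(
            outcome_name="hires",
            covariate_names=("temperature",),
            constraint=constraint,
            n_chains=2,
            n_iter=4000,
            n_burnin=1000,
            thin=2,
            seed=2,
        )
        draws = fit_mcmc(data, config)
        oracle = quadrature_posterior_means(data, config, n_con)
        got = np.array(
            [draws.beta0.mean(), draws.beta[:, 0].mean(), draws.gamma.mean()]
        )
        assert np.all(np.abs(got - oracle) < 0.03)

    def test_metropolis_crosscheck(self, small_series):
        """An independent Metropolis chain on log_posterior agrees in mean."""
        series, _ = small_series
        data = build_design(series, "hires", covariate_names=("temperature",))
        config = ModelConfig(
            outcome_name="hires",
            covariate_names=("temperature",),
            constraint="projected",
            n_chains=2,
            n_iter=4000,
            n_burnin=1000,
            thin=2,
            seed=2,
        )
        draws = fit_mcmc(data, config)

        n, k = data.n, data.k
        Z = constrained_basis(n, 2)
        p = k + 2 + Z.shape[1]
        rng = np.random.default_rng(12)

        def lp(x, lv, lve):
            state = dict(
                beta0=x[0],
                beta=x[1 : 1 + k],
                gamma=x[1 + k],
                u=Z @ x[k + 2 :],
                v=np.exp(lv),
                v_e=np.exp(lve),
            )
            return log_posterior(state, data, config) + lv + lve

        # quadratic extraction of a preconditioner (exact for the Gaussian block)
        f0 = lp(np.zeros(p), 0.0, -3.0)
        e = np.eye(p)
        fi = np.array([lp(e[i], 0.0, -3.0) for i in range(p)])
        P = np.empty((p, p))
        for i in range(p):
            for j in range(i, p):
                P[i, j] = P[j, i] = -(lp(e[i] + e[j], 0.0, -3.0) - fi[i] - fi[j] + f0)
        w, V = np.linalg.eigh(P)
        L = V / np.sqrt(np.maximum(w, 1e-6))

        x, lv, lve = np.zeros(p), 0.0, -3.0
        cur = lp(x, lv, lve)
        kept = []
        for it in range(60_000):
            xp = x + 0.22 * (L @ rng.standard_normal(p))
            lvp = lv + 0.15 * rng.standard_normal()
            lvep = lve + 0.3 * rng.standard_normal()
            prop = lp(xp, lvp, lvep)
            if np.log(rng.uniform()) < prop - cur:
                x, lv, lve, cur = xp, lvp, lvep, prop
            if it >= 20_000 and it % 20 == 0:
                kept.append([x[0], x[1], x[1 + k]])
        kept = np.array(kept)

        gibbs = np.column_stack([draws.beta0, draws.beta[:, 0], draws.gamma])
        # generous MC-error budget: both chains autocorrelated
        se = np.sqrt(
            gibbs.var(axis=0) / (draws.n_draws / 10)
            + kept.var(axis=0) / (len(kept) / 10)
        )
        assert np.all(np.abs(gibbs.mean(axis=0) - kept.mean(axis=0)) < 5 * se)

    def test_intercept_only_limit(self):
        """With no covariates and an inert lag, beta0 recovers the mean of y."""
        rng = np.random.default_rng(3)
        n = 40
        y = 1.7 + 0.3 * rng.standard_normal(n)
        data = RegressionData(
            y=y,
            X=np.empty((n, 0)),
            y_lag=np.zeros(n),
            time_index=np.arange(1, n + 1),
            outcome_name="hires",
            covariate_names=(),
            y_params=StandardizationParams(0.0, 1.0),
            x_params={},
            months=[(2000 + t // 12, t % 12 + 1) for t in range(n)],
        )
        config = ModelConfig(
            outcome_name="hires",
            covariate_names=(),
            n_chains=2,
            n_iter=2000,
            n_burnin=500,
            thin=2,
            seed=4,
        )
        draws = fit_mcmc(data, config)
        assert draws.beta0.mean() == pytest.approx(y.mean(), abs=0.1)

    def test_positive_variances_and_level_constraint_in_every_draw(self, fitted_hires):
        data, draws = fitted_hires
        assert np.all(draws.v > 0) and np.all(draws.v_e > 0)
        assert np.max(np.abs(draws.u.sum(axis=1))) < 1e-8

    def test_projected_mode_pins_level_and_slope(self, small_series):
        series, _ = small_series
        data = build_design(series, "hires")
        config = ModelConfig(
            outcome_name="hires",
            constraint="projected",
            n_chains=2,
            n_iter=400,
            n_burnin=200,
            thin=2,
            seed=6,
        )
        draws = fit_mcmc(data, config)
        t = np.arange(1, data.n + 1)
        assert np.max(np.abs(draws.u.sum(axis=1))) < 1e-8
        assert np.max(np.abs(draws.u @ t)) < 1e-6

    def test_recovery_with_negligible_trend(self):
        """With v_e ~ 0 truth, beta lands within 2 posterior sd of truth."""
        from cyclecast import default_truth
        from dataclasses import replace

        misses = 0
        for rep in range(3):
            truth = default_truth(600 + rep)
            for name in truth.outcomes:
                truth.outcomes[name] = replace(truth.outcomes[name], v_e=1e-12)
            series, truth = simulate_series(92, truth=truth)
            data = build_design(series, "hires")
            config = ModelConfig(
                outcome_name="hires",
                n_chains=2,
                n_iter=1200,
                n_burnin=400,
                thin=2,
                seed=700 + rep,
            )
            draws = fit_mcmc(data, config)
            ot = truth.outcomes["hires"]
            for j, name in enumerate(data.covariate_names):
                true_fit_scale = (
                    truth.original_unit_slope("hires", name)
                    * data.x_params[name].sd
                    / data.y_params.sd
                )
                sample = draws.beta[:, j]
                if abs(sample.mean() - true_fit_scale) > 2 * sample.std():
                    misses += 1
        assert misses <= 2  # 9 checks at nominal ~95%


def synthetic_draws(n=500, k=1, T=20, seed=0):
    rng = np.random.default_rng(seed)
    half = n // 2
    return PosteriorDraws(
        beta0=rng.standard_normal(n),
        beta=1.0 + 0.05 * rng.standard_normal((n, k)),
        gamma=0.2 + 0.05 * rng.standard_normal(n),
        u=rng.standard_normal((n, T)),
        v=np.exp(rng.standard_normal(n) * 0.1),
        v_e=np.exp(rng.standard_normal(n) * 0.1),
        chain=np.repeat([0, 1], half),
        covariate_names=tuple(f"x{j}" for j in range(k)),
        n_chains=2,
    )


def dummy_data(k=1, T=20, sd_y=10.0, sd_x=2.0):
    return RegressionData(
        y=np.zeros(T),
        X=np.zeros((T, k)),
        y_lag=np.zeros(T),
        time_index=np.arange(1, T + 1),
        outcome_name="hires",
        covariate_names=tuple(f"x{j}" for j in range(k)),
        y_params=StandardizationParams(0.0, sd_y),
        x_params={f"x{j}": StandardizationParams(0.0, sd_x) for j in range(k)},
        months=[(2000, t % 12 + 1) for t in range(T)],
    )


class TestSummaries:
    def test_symmetric_posterior_median_near_mean(self):
        draws = synthetic_draws(n=4000)
        table = summarize_posterior(draws, dummy_data()).set_index("parameter")
        assert table.loc["x0", "median"] == pytest.approx(
            float(draws.beta[:, 0].mean()) * 10.0 / 2.0, rel=0.02
        )

    def test_back_transform_chain_rule(self):
        # coefficient 1 on a standardized covariate: sd_x 2, sd_y 10 -> 5/unit
        draws = synthetic_draws(n=500)
        draws.beta = np.ones((500, 1))
        table = summarize_posterior(draws, dummy_data()).set_index("parameter")
        assert table.loc["x0", "median"] == pytest.approx(5.0)
        assert table.loc["x0", "lower"] == pytest.approx(5.0)

    def test_too_few_draws_rejected(self):
        draws = synthetic_draws(n=50)
        with pytest.raises(ValueError, match="100"):
            summarize_posterior(draws, dummy_data())


class TestGelmanRubin:
    def test_identical_chains_near_one(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(400)
        draws = synthetic_draws(n=800)
        draws.beta0 = np.concatenate([x, x])
        r = gelman_rubin(draws)
        assert r["beta0"] == pytest.approx(1.0, abs=0.02)

    def test_disjoint_chains_blow_up(self):
        rng = np.random.default_rng(6)
        draws = synthetic_draws(n=800)
        draws.beta0 = np.concatenate(
            [rng.standard_normal(400), 50.0 + rng.standard_normal(400)]
        )
        assert gelman_rubin(draws)["beta0"] > 1.5

    def test_single_chain_rejected(self):
        draws = synthetic_draws(n=400)
        draws.n_chains = 1
        draws.chain = np.zeros(400, dtype=int)
        with pytest.raises(ValueError):
            gelman_rubin(draws)

    def test_converged_fit_has_small_rhat(self, fitted_hires):
        _, draws = fitted_hires
        assert max(draws.rhat.values()) < 1.1
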