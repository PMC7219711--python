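"""Gibbs sampler: conjugate-block correctness, recovery, reproducibility."""

import numpy as np
import pytest

import obesity_elasticity as oe
from obesity_elasticity.gibbs import (
    _draw_invwishart,
    draw_country_coefficients,
    draw_error_variances,
    draw_second_stage,
)


def _toy_stats(rng, n=5, T=12):
    XtX, Xty = [], []
    for _ in range(n):
        x = rng.normal(8, 0.5, T)
        X = np.column_stack([np.ones(T), x])
        y = rng.normal(0, 1, T)
        XtX.append(X.T @ X)
        Xty.append(X.T @ y)
    return np.array(XtX), np.array(Xty)


class TestConjugateBlocks:
    """Each block's draws must match its closed-form conditional."""

    def test_country_block_matches_closed_form(self):
        rng = np.random.default_rng(10)
        XtX, Xty = _toy_stats(rng)
        n = len(XtX)
        sigma2 = rng.uniform(0.5, 2.0, n)
        Sigma = np.array([[0.5, 0.1], [0.1, 0.3]])
        Si = np.linalg.inv(Sigma)
        pm = rng.normal(0, 1, (n, 2))
        # oracle: precision-weighted normal moments, written independently
        means = np.array(
            [np.linalg.solve(XtX[c] / sigma2[c] + Si, Xty[c] / sigma2[c] + Si @ pm[c]) for c in range(n)]
        )
        covs = np.array([np.linalg.inv(XtX[c] / sigma2[c] + Si) for c in range(n)])
        S = 20_000
        d = np.array([draw_country_coefficients(XtX, Xty, sigma2, Si, pm, rng) for _ in range(S)])
        se = np.sqrt(np.array([np.diag(covs[c]) for c in range(n)]) / S)
        assert np.abs(d.mean(axis=0) - means).max() < (3 * se).max() * 1.2
        emp_cov = np.array([np.cov(d[:, c, :].T) for c in range(n)])
        assert np.abs(emp_cov - covs).max() / np.abs(covs).max() < 0.05

    def test_error_variance_block_matches_inverse_gamma_moments(self):
        rng = np.random.default_rng(11)
        ssr = np.array([2.0, 3.0, 4.0, 5.0, 6.0])
        T = np.full(5, 12.0)
        S = 20_000
        draws = np.array([draw_error_variances(ssr, T, 3.0, 1.0, rng) for _ in range(S)])
        mean_true = (3.0 + ssr) / (3.0 + 12.0 - 2.0)  # inverse-gamma mean
        se = draws.std(axis=0) / np.sqrt(S)
        assert np.abs(draws.mean(axis=0) - mean_true).max() < (3 * se).max() * 1.2

    def test_second_stage_block_matches_closed_form(self):
        rng = np.random.default_rng(12)
        n, p = 5, 3
        Z = np.column_stack([np.ones(n), rng.normal(0, 1, (n, 2))])
        delta = rng.normal(0, 1, (n, 2))
        A = 0.01 * np.eye(p)
        Db = np.zeros((p, 2))
        nu, V = 5, 5 * np.eye(2)
        Dt = np.linalg.solve(Z.T @ Z + A, Z.T @ delta)
        E = delta - Z @ Dt
        Sm = E.T @ E + Dt.T @ A @ Dt
        S = 20_000
        res = [draw_second_stage(delta, Z, A, Db, nu, V, rng) for _ in range(S)]
        Ds = np.array([r[0] for r in res])
        Ss = np.array([r[1] for r in res])
        se = Ds.std(axis=0) / np.sqrt(S)
        assert np.abs(Ds.mean(axis=0) - Dt).max() < (3 * se).max() * 1.2
        np.testing.assert_allclose(Ss.mean(axis=0), (V + Sm) / (nu + n - 3), rtol=0.05)

    def test_invwishart_mean(self):
        rng = np.random.default_rng(13)
        scale = np.array([[2.0, 0.3], [0.3, 1.0]])
        draws = np.array([_draw_invwishart(10, scale, rng) for _ in range(20_000)])
        np.testing.assert_allclose(draws.mean(axis=0), scale / (10 - 3), rtol=0.05)

    def test_flat_prior_limit_recovers_ols(self):
        """With Sigma^{-1} → 0 the country conditional collapses onto OLS."""
        rng = np.random.default_rng(14)
        XtX, Xty = _toy_stats(rng, n=1, T=30)
        ols = np.linalg.solve(XtX[0], Xty[0])
        d = np.array(
            [
                draw_country_coefficients(
                    XtX, Xty, np.array([1.0]), np.zeros((2, 2)), np.array([[5.0, 5.0]]), rng
                )
                for _ in range(20_000)
            ]
        )[:, 0, :]
        post_sd = d.std(axis=0)
        assert np.abs(d.mean(axis=0) - ols).max() < 3 * post_sd.max() / np.sqrt(20_000) * 1.5

    def test_shrinkage_between_ols_and_prior_prediction(self):
        """With an orthogonal design the conditional mean of each coefficient
        is a convex combination of its OLS estimate and its second-stage
        prediction, hence lies between them."""
        rng = np.random.default_rng(15)
        n, T = 6, 10
        XtX, Xty = [], []
        for _ in range(n):
            x = rng.normal(8, 0.5, T)
            x = x - x.mean()  # centered → XtX diagonal
            X = np.column_stack([np.ones(T), x])
            XtX.append(X.T @ X)
            Xty.append(X.T @ rng.normal(0, 1, T))
        XtX, Xty = np.array(XtX), np.array(Xty)
        sigma2 = np.full(n, 1.0)
        Si = np.linalg.inv(np.diag([0.4, 0.2]))
        pm = rng.normal(0, 1, (n, 2))
        ols = np.array([np.linalg.solve(XtX[c], Xty[c]) for c in range(n)])
        mean = np.array(
            [
                np.linalg.solve(XtX[c] / sigma2[c] + Si, Xty[c] / sigma2[c] + Si @ pm[c])
                for c in range(n)
            ]
        )
        gap = (mean - ols) * (mean - pm)
        assert (gap <= 1e-10).all()


class TestSampler:
    def test_exact_reproducibility(self, tiny_dataset):
        mcmc = oe.MCMCConfig(n_iter=400, burn_in=100, thin=3, seed=9)
        a = oe.run_gibbs(tiny_dataset.panel, tiny_dataset.moderators, mcmc=mcmc)
        b = oe.run_gibbs(tiny_dataset.panel, tiny_dataset.moderators, mcmc=mcmc)
        np.testing.assert_array_equal(a.country_coeffs, b.country_coeffs)
        np.testing.assert_array_equal(a.second_stage, b.second_stage)

    def test_retained_draw_count(self, tiny_dataset):
        mcmc = oe.MCMCConfig(n_iter=500, burn_in=200, thin=10, seed=1)
        draws = oe.run_gibbs(tiny_dataset.panel, tiny_dataset.moderators, mcmc=mcmc)
        assert draws.n_draws == 30  # (500 - 200) / 10

    def test_noiseless_posterior_concentrates_on_truth(self):
        """Likelihood dominance: long noiseless series pin beta_c."""
        cfg = oe.GeneratorConfig(
            n_countries=8, n_years=300, start_year=1700, strata=("overall",),
            sigma_y=0.0, Sigma=np.zeros((2, 2)), growth_mean=0.0, growth_sd=0.0,
            growth_shock_sd=0.08,
        )
        ds = oe.generate_dataset(cfg, seed=2)
        draws = oe.run_gibbs(
            ds.panel, ds.moderators,
            mcmc=oe.MCMCConfig(n_iter=6000, burn_in=1000, thin=1, seed=3),
        )
        post_mean = draws.beta.mean(axis=0)
        assert np.abs(post_mean - ds.truth.beta["overall"]).max() < 1e-3

    def test_unmatched_country_raises(self, tiny_dataset):
        mods = tiny_dataset.moderators
        clipped = oe.ModeratorTable(
            values=mods.values.iloc[:-1],
            dimensions=mods.dimensions,
            is_dummy=mods.is_dummy,
        )
        with pytest.raises(ValueError, match="missing from the moderator table"):
            oe.run_gibbs(tiny_dataset.panel, clipped, mcmc=oe.MCMCConfig(300, 1, 100, 0))


class TestSummaries:
    def _draws_from(self, beta_draws, predictors=2):
        S, n = beta_draws.shape
        cc = np.zeros((S, n, 2))
        cc[:, :, 1] = beta_draws
        return oe.PosteriorDraws(
            country_coeffs=cc,
            second_stage=np.zeros((S, predictors, 2)),
            Sigma=np.tile(np.eye(2), (S, 1, 1)),
            sigma2=np.ones((S, n)),
            countries=[f"C{i}" for i in range(n)],
            predictors=["intercept"] + [f"m{i}" for i in range(predictors - 1)],
            stratum="overall",
        )

    def test_constant_draws_degenerate_interval(self):
        draws = self._draws_from(np.full((500, 3), 1.7))
        s = oe.summarize_posterior(draws)
        for key in ("mean", "lower", "upper"):
            assert s.mean_elasticity[key] == pytest.approx(1.7, abs=1e-12)
        assert s.mean_elasticity["lower"] <= s.mean_elasticity["upper"]

    def test_normal_draw_quantiles(self):
        rng = np.random.default_rng(21)
        draws = self._draws_from(rng.standard_normal((10_000, 1)))
        s = oe.summarize_posterior(draws)
        row = s.country.iloc[0]
        assert row.lower == pytest.approx(-1.96, abs=0.08)
        assert row.upper == pytest.approx(1.96, abs=0.08)

    def test_interval_excluding_zero_flagged_significant(self):
        rng = np.random.default_rng(22)
        S = 4000
        second = np.zeros((S, 2, 2))
        second[:, 0, 1] = rng.normal(0.32, 0.10, S)  # excludes zero
        second[:, 1, 1] = rng.normal(0.01, 0.09, S)  # includes zero
        draws = self._draws_from(rng.standard_normal((S, 1)))
        draws.second_stage[:] = second
        s = oe.summarize_posterior(draws)
        assert bool(s.second_stage_beta.significant[0]) is True
        assert bool(s.second_stage_beta.significant[1]) is False

    def test_few_draws_warns(self):
        draws = self._draws_from(np.full((50, 2), 1.0))
        with pytest.warns(UserWarning, match="retained draws"):
            oe.summarize_posterior(draws)
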