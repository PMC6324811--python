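"""Likelihood primitives: mass functions, scores, dispersion, sampling."""

import numpy as np
import pytest
from numpy.testing import assert_allclose

import nbgmifs as nbg
from nbgmifs.families import (
    estimate_alpha_ml,
    estimate_alpha_pearson,
    fit_unpenalized_mle,
)


class TestNBLogPmf:
    @pytest.mark.parametrize(
        "y, mu, alpha, expected",
        [
            (0, 1.0, 1.0, np.log(0.5)),
            (1, 1.0, 1.0, np.log(0.25)),
            (2, 1.0, 1.0, np.log(0.125)),
        ],
    )
    def test_hand_evaluated_values(self, y, mu, alpha, expected):
        assert_allclose(nbg.nb_log_pmf(y, mu, alpha), expected, rtol=1e-12)

    @pytest.mark.parametrize(
        "mu, alpha", [(3.0, 0.4), (0.5, 1.2), (10.0, 0.1), (1.0, 2.0)]
    )
    def test_pmf_normalizes(self, mu, alpha):
        ys = np.arange(3000)
        total = np.exp(nbg.nb_log_pmf(ys, mu, alpha)).sum()
        assert abs(total - 1.0) < 1e-8

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            nbg.nb_log_pmf(1, -1.0, 1.0)
        with pytest.raises(ValueError):
            nbg.nb_log_pmf(1, 1.0, 0.0)
        with pytest.raises(ValueError):
            nbg.nb_log_pmf(-1, 1.0, 1.0)
        with pytest.raises(ValueError):
            nbg.nb_log_pmf(1.5, 1.0, 1.0)

    def test_finite_for_large_counts(self):
        # Gamma ratios would overflow near y ~ 170 if not in log space
        val = nbg.nb_log_pmf(5000, 10.0, 0.5)
        assert np.isfinite(val)


class TestPmfProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        mu=st.floats(0.1, 20.0),
        alpha=st.floats(0.05, 3.0),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_normalizes_and_matches_moments(self, mu, alpha):
        ys = np.arange(6000)
        pmf = np.exp(nbg.nb_log_pmf(ys, mu, alpha))
        assert abs(pmf.sum() - 1.0) < 1e-8
        mean = float(np.sum(ys * pmf))
        var = float(np.sum((ys - mean) ** 2 * pmf))
        assert abs(mean - mu) < 1e-6 * max(1.0, mu)
        assert abs(var - (mu + alpha * mu**2)) < 1e-4 * max(1.0, var)


class TestLogLikelihoods:
    def test_nb_loglik_is_pmf_sum(self):
        rng = np.random.default_rng(1)
        y = rng.poisson(3.0, 25)
        mu = np.exp(rng.normal(0.8, 0.4, 25))
        assert_allclose(
            nbg.nb_loglik(y, mu, 0.7),
            np.sum(nbg.nb_log_pmf(y, mu, 0.7)),
            rtol=1e-12,
        )

    def test_single_observation_hand_value(self):
        # y=2, gamma0=0, c=1, no covariates, alpha=1 -> log(1/8)
        assert_allclose(nbg.nb_loglik([2], [1.0], 1.0), np.log(0.125), rtol=1e-12)

    def test_poisson_hand_value(self):
        assert_allclose(nbg.poisson_loglik([1], [1.0]), -1.0, rtol=1e-12)

    def test_poisson_limit_of_nb(self):
        rng = np.random.default_rng(0)
        y = rng.poisson(3.0, 40)
        mu = np.exp(rng.normal(0.7, 0.5, 40))
        gap = abs(nbg.nb_loglik(y, mu, 1e-10) - nbg.poisson_loglik(y, mu))
        assert gap < 1e-4

    def test_offset_invariance(self):
        # doubling exposures while shifting gamma0 by -log 2 leaves the
        # rate-model likelihood and score unchanged
        rng = np.random.default_rng(3)
        n, k = 30, 4
        y = rng.poisson(4.0, n)
        X = rng.standard_normal((n, k))
        c = rng.uniform(0.5, 2.0, n)
        gamma0, beta, alpha = 0.3, rng.normal(0, 0.2, k), 0.5
        Xe = np.hstack([X, -X])
        for c_use, g0_use in [(c, gamma0), (2 * c, gamma0 - np.log(2))]:
            mu = c_use * np.exp(g0_use + X @ beta)
            if c_use is c:
                ref_ll = nbg.nb_loglik(y, mu, alpha)
                ref_sc = nbg.nb_score_expanded(y, mu, alpha, Xe)
            else:
                assert_allclose(nbg.nb_loglik(y, mu, alpha), ref_ll, rtol=1e-12)
                assert_allclose(nbg.nb_score_expanded(y, mu, alpha, Xe), ref_sc,
                                rtol=1e-10)


class TestExpandedScores:
    def _instance(self, seed, n=30, k=5):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n, k))
        beta = rng.normal(0, 0.3, 2 * k)
        y = rng.poisson(3.0, n)
        eta0 = rng.normal(0.5, 0.2, n)
        return y, eta0, np.hstack([X, -X]), beta

    @pytest.mark.parametrize("family", ["negbin", "poisson"])
    @pytest.mark.parametrize("seed", range(6))
    def test_matches_central_finite_differences(self, family, seed):
        y, eta0, Xe, beta = self._instance(seed)
        alpha = 0.6

        def ll(b):
            mu = np.exp(eta0 + Xe @ b)
            if family == "negbin":
                return nbg.nb_loglik(y, mu, alpha)
            return nbg.poisson_loglik(y, mu)

        mu = np.exp(eta0 + Xe @ beta)
        if family == "negbin":
            analytic = nbg.nb_score_expanded(y, mu, alpha, Xe)
        else:
            analytic = nbg.poisson_score_expanded(y, mu, Xe)
        h = 1e-6
        for j in range(Xe.shape[1]):
            e = np.zeros_like(beta)
            e[j] = h
            fd = (ll(beta + e) - ll(beta - e)) / (2 * h)
            assert abs(analytic[j] - fd) <= 1e-6 * max(1.0, abs(fd))

    def test_halves_negate_and_zero_at_fit(self):
        y, eta0, Xe, beta = self._instance(11)
        mu = np.exp(eta0 + Xe @ beta)
        s = nbg.nb_score_expanded(y, mu, 0.4, Xe)
        k = Xe.shape[1] // 2
        assert_allclose(s[:k], -s[k:], rtol=1e-12)
        # y == mu -> residual term vanishes
        z = nbg.nb_score_expanded(mu.round(), mu.round(), 0.4, Xe)
        assert_allclose(z, 0.0, atol=1e-12)

    def test_single_observation_hand_value(self):
        # x=1, y=2, mu=1, alpha=1 -> (2-1)/(1+1) = 0.5
        s = nbg.nb_score_expanded([2], [1.0], 1.0, [[1.0]])
        assert_allclose(s, [0.5], rtol=1e-12)

    def test_alpha_domain(self):
        with pytest.raises(ValueError):
            nbg.nb_score_expanded([1], [1.0], 0.0, [[1.0]])


class TestAlphaEstimators:
    def test_equidispersed_hits_floor(self):
        mu = np.full(50, 3.0)
        assert nbg.estimate_alpha_mom(mu, mu) == nbg.ALPHA_FLOOR

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            nbg.estimate_alpha_mom([1.0], [1.0])

    @pytest.mark.parametrize("alpha", [0.3, 0.5])
    def test_monte_carlo_consistency(self, alpha):
        rng = np.random.default_rng(17)
        mu = np.full(100_000, 5.0)
        y = nbg.nb_sample(mu, alpha, rng)
        assert abs(nbg.estimate_alpha_mom(y, mu) - alpha) < 0.05

    def test_poisson_null_near_zero(self):
        rng = np.random.default_rng(18)
        mu = np.full(100_000, 5.0)
        y = rng.poisson(mu)
        assert nbg.estimate_alpha_mom(y, mu) < 0.02

    @pytest.mark.parametrize(
        "estimator", [estimate_alpha_pearson, estimate_alpha_ml]
    )
    def test_alternative_estimators_consistent(self, estimator):
        rng = np.random.default_rng(19)
        mu = np.exp(rng.normal(1.2, 0.4, 20_000))
        y = nbg.nb_sample(mu, 0.4, rng)
        assert abs(estimator(y, mu) - 0.4) < 0.06


class TestNBSample:
    def test_poisson_degenerate_moments(self):
        rng = np.random.default_rng(5)
        draws = nbg.nb_sample(np.full(200_000, 4.0), 0.0, rng)
        assert abs(draws.mean() - 4.0) < 0.05
        assert abs(draws.var() - 4.0) < 0.05

    def test_overdispersed_variance(self):
        rng = np.random.default_rng(6)
        draws = nbg.nb_sample(np.full(200_000, 4.0), 0.5, rng)
        assert abs(draws.mean() - 4.0) < 0.05
        assert abs(draws.var() - 12.0) < 0.3

    def test_seed_determinism(self):
        a = nbg.nb_sample(np.full(100, 3.0), 0.4, np.random.default_rng(9))
        b = nbg.nb_sample(np.full(100, 3.0), 0.4, np.random.default_rng(9))
        assert np.array_equal(a, b)

    def test_negative_alpha_rejected(self):
        with pytest.raises(ValueError):
            nbg.nb_sample([1.0], -0.1, np.random.default_rng(0))


class TestUnpenalizedMLE:
    def test_intercept_only_closed_form(self):
        rng = np.random.default_rng(7)
        y = rng.poisson(5.0, 80)
        A = np.ones((80, 1))
        theta, _ = fit_unpenalized_mle(y, A, np.zeros(80), "negbin", alpha=0.5)
        assert_allclose(theta[0], np.log(y.mean()), atol=1e-7)

    def test_constant_offset_shift(self):
        rng = np.random.default_rng(8)
        y = rng.poisson(5.0, 80)
        A = np.ones((80, 1))
        k = 3.0
        theta, _ = fit_unpenalized_mle(
            y, A, np.full(80, np.log(k)), "negbin", alpha=0.5
        )
        assert_allclose(theta[0], np.log(y.mean() / k), atol=1e-7)

    @pytest.mark.parametrize("family", ["poisson", "negbin"])
    def test_matches_statsmodels_glm(self, family):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(9)
        n = 200
        Xu = rng.standard_normal((n, 2))
        c = rng.choice([500.0, 1000.0, 2000.0], n)
        mu = c * np.exp(-6 + 0.4 * Xu[:, 0] - 0.3 * Xu[:, 1])
        y = nbg.nb_sample(mu, 0.3, rng)
        A = np.column_stack([np.ones(n), Xu])
        off = np.log(c)
        alpha = 0.3 if family == "negbin" else None
        theta, _ = fit_unpenalized_mle(y, A, off, family, alpha=alpha)
        fam = (
            sm.families.NegativeBinomial(alpha=0.3)
            if family == "negbin"
            else sm.families.Poisson()
        )
        ref = sm.GLM(y, A, family=fam, offset=off).fit()
        assert np.max(np.abs(theta - ref.params)) < 1e-4

    def test_full_nb_mle_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(10)
        n = 300
        x = rng.standard_normal(n)
        y = nbg.nb_sample(np.exp(1.0 + 0.5 * x), 0.4, rng)
        A = np.column_stack([np.ones(n), x])
        theta, alpha, ll = nbg.fit_nb_mle(y, A, np.zeros(n))
        ref = sm.NegativeBinomial(y, A).fit(disp=0)
        assert np.max(np.abs(theta - ref.params[:-1])) < 1e-3
        assert abs(alpha - ref.params[-1]) < 0.02
        assert abs(ll - ref.llf) < 1e-3
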