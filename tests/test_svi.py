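"""Variational engine: KL, ELBO estimators, gradients, fits, LOCO residuals."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from slabgwas.svi import (
    OptimizerConfig,
    PriorSpec,
    VariationalPosterior,
    batch_loss_and_grads,
    elbo_linear,
    elbo_logistic,
    fit_svi,
    kl_spike_slab,
    loco_residuals,
)

_LOG2PI = np.log(2 * np.pi)


def kl_monte_carlo(psi, mu, var, prior, n=200_000, seed=0):
    """Oracle: numerical KL between the two spike-and-slab mixtures.

    The spike components are mutually singular with the slabs, so the KL
    splits into the Bernoulli part plus psi times a Monte-Carlo estimate of
    the Gaussian KL; returns (estimate, standard error).
    """
    rng = np.random.default_rng(seed)
    x = rng.normal(mu, np.sqrt(var), size=n)
    logq = -0.5 * ((x - mu) ** 2 / var + np.log(var) + _LOG2PI)
    logp = -0.5 * (x**2 / prior.slab_var + np.log(prior.slab_var) + _LOG2PI)
    gauss = logq - logp
    pi = prior.slab_prob
    est = (
        psi * np.log(psi / pi)
        + (1 - psi) * np.log((1 - psi) / (1 - pi))
        + psi * gauss.mean()
    )
    return est, psi * gauss.std() / np.sqrt(n)


class TestKL:
    def test_zero_at_prior(self):
        prior = PriorSpec(0.3, 0.7, 1.0)
        q = VariationalPosterior(
            np.full(4, 0.3), np.zeros(4), np.full(4, 0.7)
        )
        np.testing.assert_allclose(kl_spike_slab(q, prior), 0.0, atol=1e-12)

    def test_spike_limit_is_log2(self):
        prior = PriorSpec(0.5, 1.0, 1.0)
        q = VariationalPosterior(np.array([1e-6]), np.zeros(1), np.ones(1))
        kl = kl_spike_slab(q, prior)[0]
        assert abs(kl - np.log(2)) < 1e-4

    def test_matches_monte_carlo_integration(self, rng):
        """20 random tuples against the numerical mixture KL, within 3 SE."""
        for _ in range(20):
            psi = rng.uniform(0.05, 0.95)
            mu = rng.normal(0, 1)
            var = rng.uniform(0.1, 2.0)
            prior = PriorSpec(rng.uniform(0.05, 0.95), rng.uniform(0.2, 2.0))
            q = VariationalPosterior(np.array([psi]), np.array([mu]),
                                     np.array([var]))
            exact = kl_spike_slab(q, prior)[0]
            mc, se = kl_monte_carlo(psi, mu, var, prior,
                                    seed=int(rng.integers(1 << 30)))
            assert abs(exact - mc) < 3 * se + 1e-8

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        psi=st.floats(1e-5, 1 - 1e-5),
        mu=st.floats(-5, 5),
        var=st.floats(1e-4, 10),
        pi=st.floats(1e-4, 1 - 1e-4),
        sv=st.floats(1e-4, 10),
    )
    def test_nonnegative(self, psi, mu, var, pi, sv):
        q = VariationalPosterior(np.array([psi]), np.array([mu]),
                                 np.array([var]))
        assert kl_spike_slab(q, PriorSpec(pi, sv))[0] >= -1e-10


@pytest.fixture
def small_problem(rng):
    N, M = 80, 10
    X = rng.standard_normal((N, M))
    X = (X - X.mean(0)) / X.std(0)
    y = X[:, 0] * 0.5 + rng.standard_normal(N)
    prior = PriorSpec(0.2, 0.3, 1.0)
    q = VariationalPosterior(
        rng.uniform(0.1, 0.9, M), rng.normal(0, 0.3, M), rng.uniform(0.1, 0.5, M)
    )
    return X, y, prior, q


class TestElboLinear:
    def test_near_null_posterior_data_term(self, small_problem):
        X, y, prior, _ = small_problem
        M = X.shape[1]
        q = VariationalPosterior(np.full(M, 1e-6), np.zeros(M),
                                 np.full(M, prior.slab_var))
        elbo = elbo_linear(q, prior, X, y, n_mc_samples=0)
        expected_data = -0.5 * float(y @ y) / prior.sigma_e2 - 0.5 * len(y) * (
            _LOG2PI + np.log(prior.sigma_e2)
        )
        kl = float(np.sum(kl_spike_slab(q, prior)))
        # KL reduces to (almost) the Bernoulli-only penalty at mu = 0; the
        # residual predictive variance contributes O(psi) ~ 1e-6 per entry
        assert abs(elbo - (expected_data - kl)) < 1e-3
        assert kl < len(q.mu) * 0.3  # far below the Gaussian-dominated regime

    def test_stochastic_estimate_unbiased_for_closed_form(self, small_problem):
        """Sampled ELBO matches the exact expected quadratic within 3 SE."""
        X, y, prior, q = small_problem
        exact = elbo_linear(q, prior, X, y, n_mc_samples=0)
        draws = np.array([
            elbo_linear(q, prior, X, y, n_mc_samples=512,
                        rng=np.random.default_rng(k))
            for k in range(20)
        ])
        sem = draws.std(ddof=1) / np.sqrt(len(draws))
        assert abs(draws.mean() - exact) < 3 * sem + 1e-9

    def test_antithetic_reduces_variance(self, small_problem):
        """Paired +/-z draws beat independent draws at equal sample count."""
        X, y, prior, q = small_problem
        anti = np.array([
            elbo_linear(q, prior, X, y, n_mc_samples=1, antithetic=True,
                        rng=np.random.default_rng(k))
            for k in range(100)
        ])
        indep = np.array([
            elbo_linear(q, prior, X, y, n_mc_samples=1, antithetic=False,
                        rng=np.random.default_rng(k))
            for k in range(100)
        ])
        assert anti.var() < indep.var()

    def test_minibatch_sums_to_full_batch_exact(self, small_problem):
        X, y, prior, q = small_problem
        full = elbo_linear(q, prior, X, y, n_mc_samples=0)
        parts = sum(
            elbo_linear(q, prior, X[lo:lo + 20], y[lo:lo + 20],
                        n_mc_samples=0, n_total=len(y))
            for lo in range(0, len(y), 20)
        )
        assert abs(full - parts) < 1e-8


class TestElboLogistic:
    def test_near_null_balanced_is_coin_flip(self, rng):
        N, M = 60, 5
        X = rng.standard_normal((N, M))
        y = np.tile([0.0, 1.0], N // 2)
        prior = PriorSpec(0.1, 0.2)
        q = VariationalPosterior(np.full(M, 1e-6), np.zeros(M), np.full(M, 0.2))
        elbo = elbo_logistic(q, prior, X, y, n_mc_samples=64,
                             rng=np.random.default_rng(0))
        kl = float(np.sum(kl_spike_slab(q, prior)))
        assert abs((elbo + kl) - N * np.log(0.5)) < 0.5

    def test_directional_likelihood_monotonicity(self):
        x = np.full(30, 2.0)
        X = x[:, None]
        y = np.ones(30)
        prior = PriorSpec(0.5, 4.0)
        rng_ = np.random.default_rng(3)
        strong = VariationalPosterior(np.array([0.999]), np.array([2.0]),
                                      np.array([0.01]))
        null = VariationalPosterior(np.array([0.999]), np.array([0.0]),
                                    np.array([0.01]))
        e_strong = elbo_logistic(strong, prior, X, y, n_mc_samples=128, rng=rng_)
        e_null = elbo_logistic(null, prior, X, y, n_mc_samples=128, rng=rng_)
        assert e_strong > e_null


class TestGradients:
    @pytest.mark.parametrize("model", ["linear", "logistic"])
    def test_matches_central_differences(self, model, rng):
        """Analytic gradients equal finite differences under common noise."""
        N, M = 50, 5
        X = rng.standard_normal((N, M))
        X2 = X * X
        y = (
            rng.standard_normal(N)
            if model == "linear"
            else (rng.random(N) < 0.5).astype(float)
        )[:, None]
        a = rng.normal(0, 0.5, (M, 1))
        mu = rng.normal(0, 0.3, (M, 1))
        b = rng.normal(-1, 0.3, (M, 1))
        z = rng.standard_normal((4, N, 1))
        prior = PriorSpec(0.2, 0.3, 0.8)
        se2 = np.array([0.8])

        def f(a_, mu_, b_):
            return batch_loss_and_grads(
                a_, mu_, b_, X, X2, y, prior, model, 1.0, z, se2
            )[0]

        _, ga, gmu, gb = batch_loss_and_grads(
            a, mu, b, X, X2, y, prior, model, 1.0, z, se2
        )
        h = 1e-5
        for arr, g, which in ((a, ga, 0), (mu, gmu, 1), (b, gb, 2)):
            num = np.zeros(M)
            for j in range(M):
                d = np.zeros((M, 1))
                d[j] = h
                args_p = [a, mu, b]
                args_m = [a, mu, b]
                args_p[which] = arr + d
                args_m[which] = arr - d
                num[j] = (f(*args_p) - f(*args_m)) / (2 * h)
            np.testing.assert_allclose(g[:, 0], num, rtol=1e-5, atol=1e-7)


class TestFit:
    def test_bit_reproducible(self, rng):
        X = rng.standard_normal((100, 30)).astype(np.float32)
        y = rng.standard_normal(100).astype(np.float32)
        prior = PriorSpec(0.1, 0.05, 0.9)
        cfg = OptimizerConfig(max_epochs=10)
        q1, _ = fit_svi(X, y, prior, cfg, seed=42)
        q2, _ = fit_svi(X, y, prior, cfg, seed=42)
        assert np.array_equal(q1.slab_prob, q2.slab_prob)
        assert np.array_equal(q1.mu, q2.mu)
        assert np.array_equal(q1.var, q2.var)

    def test_smoothed_trace_nondecreasing_at_convergence(self, rng):
        X = rng.standard_normal((150, 40)).astype(np.float32)
        y = (X[:, 0] * 0.5 + rng.standard_normal(150)).astype(np.float32)
        y = y / y.std()
        prior = PriorSpec(0.1, 0.05, 0.8)
        # full-batch exact mode: a deterministic ascent whose smoothed trace
        # must be flat or rising once convergence is accepted
        cfg = OptimizerConfig(max_epochs=400, n_mc_samples=0, tol=1e-4,
                              batch_size=256, learning_rate=0.05)
        _, rep = fit_svi(X, y, prior, cfg, seed=0)
        assert rep.converged
        sm = rep.smoothed_trace()
        # the accepted tail of the smoothed trace is flat or rising
        tail = sm[-5:]
        assert np.all(np.diff(tail) > -1e-4 * np.abs(tail[:-1]))

    def test_causal_enrichment_of_slab_probabilities(self):
        """Posterior inclusion concentrates on true causal variants."""
        rng = np.random.default_rng(5)
        N, M, k = 1500, 1200, 12
        X = rng.standard_normal((N, M)).astype(np.float32)
        X = (X - X.mean(0)) / X.std(0)
        causal = rng.choice(M, k, replace=False)
        beta = np.zeros(M)
        beta[causal] = rng.normal(0, np.sqrt(0.4 / k), k)
        y = X @ beta.astype(np.float32) + rng.normal(
            0, np.sqrt(0.6), N
        ).astype(np.float32)
        y = y / y.std()
        prior = PriorSpec.from_h2(0.4, M, 0.01)
        q, _ = fit_svi(X, y, prior, OptimizerConfig(max_epochs=40), seed=1)
        mask = np.zeros(M, bool)
        mask[causal] = True
        assert q.slab_prob[mask].mean() > 3 * q.slab_prob[~mask].mean()

    def test_warm_start_loco_speedup(self):
        """Warm-started LOCO reaches the cold-start ELBO in <= 25% of epochs."""
        rng = np.random.default_rng(6)
        N, M = 800, 2000
        X = rng.standard_normal((N, M)).astype(np.float32)
        X = (X - X.mean(0)) / X.std(0)
        chroms = np.repeat([str(c) for c in range(1, 5)], M // 4)
        beta = np.zeros(M)
        causal = rng.choice(M, 20, replace=False)
        beta[causal] = rng.normal(0, np.sqrt(0.4 / 20), 20)
        y = (X @ beta.astype(np.float32)
             + rng.normal(0, np.sqrt(0.6), N).astype(np.float32))
        y = y / y.std()
        prior = PriorSpec.from_h2(0.4, M, 0.01)
        whole, _ = fit_svi(X, y, prior, OptimizerConfig(max_epochs=40), seed=2)

        cold_cfg = OptimizerConfig(max_epochs=40, tol=0)
        _, cold_rep = fit_svi(X, y, prior, cold_cfg, exclude_chromosome="2",
                              chromosomes=chroms, seed=3)
        warm_cfg = OptimizerConfig(max_epochs=10, tol=0)
        _, warm_rep = fit_svi(X, y, prior, warm_cfg, init=whole,
                              exclude_chromosome="2", chromosomes=chroms, seed=3)
        cold_best = max(cold_rep.elbo_trace)
        warm_best = max(warm_rep.elbo_trace)
        assert warm_best >= cold_best - 0.001 * abs(cold_best)


class TestLoco:
    def _posteriors(self, M, chroms, psi=None, mu=None):
        out = {}
        for c in dict.fromkeys(chroms):
            p = np.full(M, 1e-6) if psi is None else psi
            m_ = np.zeros(M) if mu is None else mu.copy()
            m_[np.asarray(chroms) == c] = 0.0
            out[c] = VariationalPosterior(p, m_, np.full(M, 0.1))
        return out

    def test_null_posterior_returns_y(self, rng):
        X = rng.standard_normal((50, 8))
        y = rng.standard_normal(50)
        chroms = np.array(["1"] * 4 + ["2"] * 4)
        res = loco_residuals(X, y, self._posteriors(8, chroms), "linear",
                             chromosomes=chroms)
        for c in ("1", "2"):
            np.testing.assert_allclose(res.residuals[c][:, 0], y, atol=1e-4)

    def test_single_chromosome_degenerate(self, rng):
        X = rng.standard_normal((30, 5))
        y = rng.standard_normal(30)
        chroms = np.array(["1"] * 5)
        mu = rng.normal(0, 1, 5)
        post = {"1": VariationalPosterior(np.full(5, 0.9), np.zeros(5),
                                          np.full(5, 0.1))}
        res = loco_residuals(X, y, post, "linear", chromosomes=chroms)
        np.testing.assert_allclose(res.residuals["1"][:, 0], y, atol=1e-12)

    def test_missing_posterior_rejected(self, rng):
        X = rng.standard_normal((30, 6))
        chroms = np.array(["1"] * 3 + ["2"] * 3)
        with pytest.raises(ValueError, match="missing LOCO"):
            loco_residuals(X, rng.standard_normal(30),
                           {"1": None}, "linear", chromosomes=chroms)

    def test_variance_reduction_follows_causal_chromosome(self):
        """Leaving out the causal chromosome keeps the full trait variance."""
        rng = np.random.default_rng(9)
        N, M = 1200, 600
        X = rng.standard_normal((N, M)).astype(np.float32)
        X = (X - X.mean(0)) / X.std(0)
        chroms = np.array(["1"] * (M // 2) + ["2"] * (M // 2))
        beta = np.zeros(M)
        causal = rng.choice(M // 2, 10, replace=False)  # all on chr 1
        beta[causal] = rng.normal(0, np.sqrt(0.5 / 10), 10)
        y = X @ beta.astype(np.float32) + rng.normal(0, np.sqrt(0.5), N).astype(
            np.float32
        )
        y = (y / y.std()).astype(np.float32)
        prior = PriorSpec.from_h2(0.5, M, 0.02)
        posts = {}
        for c in ("1", "2"):
            posts[c], _ = fit_svi(X, y, prior, OptimizerConfig(max_epochs=30),
                                  exclude_chromosome=c, chromosomes=chroms,
                                  seed=4)
        res = loco_residuals(X, y.astype(float), posts, "linear",
                             chromosomes=chroms)
        v1 = res.residuals["1"].var()
        v2 = res.residuals["2"].var()
        assert v1 > 0.9  # causal chromosome left out: signal stays
        assert v2 < v1 - 0.2  # predictor built on chr 1 explains variance

    def test_binary_weights_are_bernoulli_variance(self, rng):
        X = rng.standard_normal((40, 4))
        y = (rng.random(40) < 0.3).astype(float)
        chroms = np.array(["1"] * 4)
        post = {"1": VariationalPosterior(np.full(4, 1e-6), np.zeros(4),
                                          np.full(4, 0.1))}
        off = np.full(40, -0.8)
        res = loco_residuals(X, y, post, "logistic", chromosomes=chroms,
                             offset=off)
        p = res.phat["1"]
        assert np.all((p > 0) & (p < 1))
        np.testing.assert_allclose(res.weights["1"], p * (1 - p), atol=1e-12)
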