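"""MCMC engines: likelihood primitives, pCN chain, lumpy chain, estimator."""

import numpy as np
import pytest
from scipy.stats import chisquare, poisson

from iomcmc import (
    ChainConfig,
    GaussianPRFSpec,
    LumpyModelSpec,
    LumpyParams,
    LumpyMoveConfig,
    NoiseModel,
    estimate_log_lr,
    image_lumpy_background,
    log_gaussian_likelihood,
    log_lr_bke,
    lumpy_propose,
    make_constant_generator,
    make_linear_gaussian_generator,
    pcn_accept_prob,
    pcn_propose,
    run_latent_chain,
    run_lumpy_chain,
)

NOISE = NoiseModel("real", 2.0)


class TestLikelihoodPrimitives:
    def test_log_likelihood_zero_at_mean(self):
        g = np.arange(5.0)
        assert log_gaussian_likelihood(g, g, NOISE) == 0.0

    def test_log_likelihood_single_sigma_offset(self):
        assert log_gaussian_likelihood(
            np.array([2.0]), np.array([0.0]), NOISE
        ) == pytest.approx(-0.5)

    def test_log_likelihood_matches_elementwise_sum(self):
        rng = np.random.default_rng(0)
        g, mean = rng.standard_normal(10), rng.standard_normal(10)
        brute = sum(-(gi - mi) ** 2 / (2 * NOISE.sigma**2) for gi, mi in zip(g, mean))
        assert log_gaussian_likelihood(g, mean, NOISE) == pytest.approx(brute)

    def test_log_likelihood_complex_stacks_components(self):
        g = np.array([1 + 2j, 3 - 1j])
        mean = np.array([0 + 0j, 0 + 0j])
        expected = -(1 + 4 + 9 + 1) / (2 * NOISE.sigma**2)
        assert log_gaussian_likelihood(g, mean, NoiseModel("complex", NOISE.sigma)) == pytest.approx(expected)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            log_gaussian_likelihood(np.zeros(3), np.zeros(4), NOISE)

    def test_bke_zero_signal(self):
        rng = np.random.default_rng(1)
        g, b = rng.standard_normal(6), rng.standard_normal(6)
        assert log_lr_bke(g, b, np.zeros(6), NOISE) == 0.0

    def test_bke_decision_boundary(self):
        rng = np.random.default_rng(2)
        b, s = rng.standard_normal(6), rng.standard_normal(6)
        assert log_lr_bke(b + s / 2, b, s, NOISE) == pytest.approx(0.0, abs=1e-12)

    def test_bke_equals_likelihood_difference(self):
        rng = np.random.default_rng(3)
        g, b, s = (rng.standard_normal(8) for _ in range(3))
        direct = log_lr_bke(g, b, s, NOISE)
        diff = log_gaussian_likelihood(g, b + s, NOISE) - log_gaussian_likelihood(g, b, NOISE)
        assert direct == pytest.approx(diff, rel=1e-12, abs=1e-12)


class TestPcnProposal:
    def test_beta_bounds(self):
        rng = np.random.default_rng(4)
        with pytest.raises(ValueError):
            pcn_propose(np.zeros(2), 0.0, rng)
        with pytest.raises(ValueError):
            pcn_propose(np.zeros(2), 1.5, rng)

    def test_small_beta_stays_near_current(self):
        rng = np.random.default_rng(5)
        z = np.ones(4)
        z_new = pcn_propose(z, 1e-8, rng)
        np.testing.assert_allclose(z_new, z, atol=1e-6)

    def test_beta_one_is_prior_draw(self):
        z = np.full(3, 100.0)
        z_new = pcn_propose(z, 1.0, np.random.default_rng(6))
        assert np.all(np.abs(z_new) < 10)  # no memory of the current state

    def test_prior_invariance_moments(self):
        """If z ~ N(0, I) then the pCN proposal is N(0, I) too."""
        rng = np.random.default_rng(7)
        Z = rng.standard_normal((100_000, 2))
        P = np.sqrt(1 - 0.6**2) * Z + 0.6 * rng.standard_normal(Z.shape)
        assert np.abs(P.mean(axis=0)).max() < 3 / np.sqrt(len(P))
        np.testing.assert_allclose(np.cov(P, rowvar=False), np.eye(2), atol=0.02)

    def test_accept_prob_identical_state(self):
        rng = np.random.default_rng(8)
        g, b = rng.standard_normal(5), rng.standard_normal(5)
        assert pcn_accept_prob(g, b, b, NOISE) == 1.0

    def test_accept_prob_better_fit_clips_to_one(self):
        g = np.zeros(5)
        assert pcn_accept_prob(g, np.ones(5), np.zeros(5), NOISE) == 1.0

    def test_accept_prob_matches_direct_ratio(self):
        rng = np.random.default_rng(9)
        g, b1, b2 = (rng.standard_normal(6) for _ in range(3))
        direct = min(
            1.0,
            np.exp(log_gaussian_likelihood(g, b2, NOISE))
            / np.exp(log_gaussian_likelihood(g, b1, NOISE)),
        )
        assert pcn_accept_prob(g, b1, b2, NOISE) == pytest.approx(direct)


class TestLatentChain:
    def test_constant_generator_accepts_everything(self):
        gen = make_constant_generator(np.zeros(16), latent_dim=3)
        g = np.random.default_rng(10).standard_normal(16)
        cfg = ChainConfig(n_iterations=2_000, burn_in=200, beta_adapt=False, pcn_beta=0.8, thin=1)
        chain = run_latent_chain(g, gen, np.zeros(16), NOISE, cfg, z0=np.zeros(3))
        assert chain.acceptance_rate == 1.0

    def test_fixed_seed_bit_identical(self):
        gen = make_constant_generator(np.zeros(9), latent_dim=2)
        g = np.random.default_rng(11).standard_normal(9)
        cfg = ChainConfig(n_iterations=1_000, burn_in=100, seed=123)
        a = run_latent_chain(g, gen, np.zeros(9), NOISE, cfg, z0=np.zeros(2))
        b = run_latent_chain(g, gen, np.zeros(9), NOISE, cfg, z0=np.zeros(2))
        np.testing.assert_array_equal(a.log_lr_bke, b.log_lr_bke)
        np.testing.assert_array_equal(a.accepted, b.accepted)
        np.testing.assert_array_equal(np.asarray(a.states), np.asarray(b.states))

    def test_linear_gaussian_posterior_moments(self):
        """Post-burn-in latent samples match the conjugate Gaussian posterior.

        For b(z) = b0 + A z and g = b(z*) + noise, the posterior over z
        under H0 is N(mu, S) with S = (I + A^T A / sigma^2)^{-1} and
        mu = S A^T (g - b0) / sigma^2.
        """
        rng = np.random.default_rng(12)
        A = rng.standard_normal((25, 2))
        b0 = rng.standard_normal(25)
        gen = make_linear_gaussian_generator(b0, A)
        noise = NoiseModel("real", 1.5)
        z_true = rng.standard_normal(2)
        g = gen(z_true) + noise.sigma * rng.standard_normal(25)
        S = np.linalg.inv(np.eye(2) + A.T @ A / noise.sigma**2)
        mu = S @ A.T @ (g - b0) / noise.sigma**2
        cfg = ChainConfig(n_iterations=60_000, burn_in=5_000, seed=13, thin=10)
        chain = run_latent_chain(g, gen, np.zeros(25), noise, cfg, z0=z_true)
        Z = np.asarray(chain.states)[cfg.burn_in // cfg.thin :]
        n_eff = len(Z) / 10.0  # conservative correlation allowance
        np.testing.assert_allclose(
            Z.mean(axis=0), mu, atol=4 * np.sqrt(np.diag(S).max() / n_eff)
        )
        np.testing.assert_allclose(np.cov(Z, rowvar=False), S, atol=0.1)

    def test_object_domain_requires_imaging_op(self):
        gen = make_constant_generator(np.zeros(4), latent_dim=2)
        object_gen = type(gen)(
            latent_dim=2, output_size=4, fn=gen.fn, output_domain="object"
        )
        with pytest.raises(ValueError, match="imaging operator"):
            run_latent_chain(
                np.zeros(4), object_gen, np.zeros(4), NOISE,
                ChainConfig(n_iterations=10, burn_in=1), z0=np.zeros(2),
            )

    def test_true_latent_init_requires_z0(self):
        gen = make_constant_generator(np.zeros(4), latent_dim=2)
        with pytest.raises(ValueError, match="z0"):
            run_latent_chain(
                np.zeros(4), gen, np.zeros(4), NOISE,
                ChainConfig(n_iterations=10, burn_in=1),
            )

    def test_fit_latent_initialization_recovers_latent(self):
        """Least-squares init lands near the truth for an identifiable map."""
        rng = np.random.default_rng(14)
        A = rng.standard_normal((30, 2)) * 3
        gen = make_linear_gaussian_generator(np.zeros(30), A)
        noise = NoiseModel("real", 0.1)
        z_true = np.array([0.7, -0.4])
        g = gen(z_true) + noise.sigma * rng.standard_normal(30)
        cfg = ChainConfig(n_iterations=500, burn_in=100, init="fit-latent", seed=15, thin=1)
        chain = run_latent_chain(g, gen, np.zeros(30), noise, cfg)
        z_init = np.asarray(chain.states)[0]
        assert np.linalg.norm(z_init - z_true) < 0.2


class TestLumpyProposal:
    spec = LumpyModelSpec(mean_lumps=6.0, fov_size=64)
    move = LumpyMoveConfig()

    def _propose_kind(self, params, kind, seed=0):
        rng = np.random.default_rng(seed)
        for _ in range(500):
            prop, lq, lp, mv = lumpy_propose(params, self.move, self.spec, rng)
            if mv.kind == kind:
                return prop, lq, lp, mv
        raise AssertionError(f"never drew a {kind} move")

    def test_center_move_ratios_zero(self):
        params = LumpyParams(np.array([[30.0, 30.0], [10.0, 50.0]]))
        _, lq, lp, mv = self._propose_kind(params, "move")
        assert lq == 0.0 and lp == 0.0

    def test_birth_prior_count_ratio(self):
        """Birth n -> n+1 carries Poisson pmf ratio mean/(n+1) plus the
        uniform position density."""
        params = LumpyParams(np.array([[30.0, 30.0], [10.0, 50.0]]))
        _, lq, lp, mv = self._propose_kind(params, "birth")
        assert lp == pytest.approx(np.log(6.0 / 3.0) - 2 * np.log(64.0))
        assert lq == pytest.approx(np.log(1.0) + 2 * np.log(64.0))

    def test_death_ratios_inverse_of_birth(self):
        params = LumpyParams(np.array([[30.0, 30.0], [10.0, 50.0], [5.0, 5.0]]))
        _, lq, lp, mv = self._propose_kind(params, "death")
        assert lp + lq == pytest.approx(np.log(3.0 / 6.0))

    def test_death_with_zero_lumps_auto_rejects(self):
        params = LumpyParams(np.empty((0, 2)))
        rng = np.random.default_rng(16)
        saw_reject = False
        for _ in range(200):
            prop, lq, lp, mv = lumpy_propose(params, self.move, self.spec, rng)
            if mv.kind == "reject":
                saw_reject = True
                assert np.isneginf(lq)
        assert saw_reject

    def test_prior_only_chain_reproduces_poisson_counts(self):
        """With a flat data term the chain's count distribution is the
        Poisson prior (empirical detailed-balance check)."""
        prf = GaussianPRFSpec(fov_size=64)
        flat_noise = NoiseModel("real", 1e9)  # likelihood ratio ~ 1 for any state
        g = np.zeros(64 * 64)
        s = np.zeros(64 * 64)
        cfg = ChainConfig(n_iterations=60_000, burn_in=5_000, seed=17, thin=5000)
        chain = run_lumpy_chain(g, self.spec, prf, s, flat_noise, cfg,
                                theta0=LumpyParams(np.empty((0, 2))))
        counts = chain.extras["n_lumps"][cfg.burn_in :: 25]
        kmax = counts.max()
        observed = np.bincount(counts, minlength=kmax + 1)
        expected = poisson.pmf(np.arange(kmax + 1), 6.0) * counts.size
        keep = expected >= 5
        obs = np.append(observed[keep], observed[~keep].sum())
        exp = np.append(expected[keep], expected[~keep].sum())
        _, p = chisquare(obs, exp * obs.sum() / exp.sum())
        assert p > 0.001


class TestLumpyChain:
    spec = LumpyModelSpec()
    prf = GaussianPRFSpec()
    noise = NoiseModel("real", 20.0)

    def test_incremental_equals_full_recomputation(self):
        rng = np.random.default_rng(18)
        theta = LumpyParams(rng.uniform(0, 64, (6, 2)))
        b = image_lumpy_background(theta, self.spec, self.prf)
        g = b + self.noise.sigma * rng.standard_normal(b.size)
        s = np.zeros_like(b)
        cfg = ChainConfig(n_iterations=3_000, burn_in=300, seed=19, thin=100)
        chain = run_lumpy_chain(g, self.spec, self.prf, s, self.noise, cfg, theta0=theta)
        recomputed = image_lumpy_background(
            LumpyParams(chain.extras["final_centers"]), self.spec, self.prf
        )
        np.testing.assert_allclose(
            chain.extras["final_background"], recomputed, atol=1e-9
        )

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(20)
        theta = LumpyParams(rng.uniform(0, 64, (5, 2)))
        b = image_lumpy_background(theta, self.spec, self.prf)
        g = b + self.noise.sigma * rng.standard_normal(b.size)
        s = np.zeros_like(b)
        cfg = ChainConfig(n_iterations=1_000, burn_in=100, seed=21)
        a = run_lumpy_chain(g, self.spec, self.prf, s, self.noise, cfg, theta0=theta)
        c = run_lumpy_chain(g, self.spec, self.prf, s, self.noise, cfg, theta0=theta)
        np.testing.assert_array_equal(a.log_lr_bke, c.log_lr_bke)
        np.testing.assert_array_equal(a.extras["n_lumps"], c.extras["n_lumps"])

    def test_posterior_mean_image_correlates_with_truth(self):
        """On signal-free data from a known configuration, the posterior
        mean background resembles the true noiseless background."""
        rng = np.random.default_rng(22)
        theta = LumpyParams(rng.uniform(8, 56, (6, 2)))
        b_true = image_lumpy_background(theta, self.spec, self.prf)
        g = b_true + self.noise.sigma * rng.standard_normal(b_true.size)
        s = np.zeros_like(b_true)
        cfg = ChainConfig(n_iterations=8_000, burn_in=1_000, seed=23, thin=50)
        chain = run_lumpy_chain(g, self.spec, self.prf, s, self.noise, cfg, theta0=theta)
        post_mean = np.mean(
            [
                image_lumpy_background(p, self.spec, self.prf)
                for p in chain.states[cfg.burn_in // cfg.thin :]
            ],
            axis=0,
        )
        corr = np.corrcoef(post_mean, b_true)[0, 1]
        assert corr > 0.9


class TestEstimator:
    def test_constant_series(self):
        series = np.full(100, 2.5)
        assert estimate_log_lr(series) == pytest.approx(2.5)

    def test_mean_of_one_and_three(self):
        series = np.array([np.log(1.0), np.log(3.0)])
        assert estimate_log_lr(series) == pytest.approx(np.log(2.0))

    def test_matches_naive_mean_of_exponentials(self):
        rng = np.random.default_rng(24)
        series = rng.uniform(-1, 1, 500)
        naive = np.log(np.mean(np.exp(series)))
        assert estimate_log_lr(series) == pytest.approx(naive, rel=1e-12)

    def test_all_neginf_raises(self):
        with pytest.raises(ValueError):
            estimate_log_lr(np.full(10, -np.inf))

    def test_no_overflow_for_large_exponents(self):
        """Log-domain averaging survives exponents of order 10^3."""
        series = np.array([1000.0, 999.0, 998.0])
        val = estimate_log_lr(series)
        assert np.isfinite(val) and 998.0 < val < 1000.0

    def test_standard_error_reported(self):
        rng = np.random.default_rng(25)
        series = rng.normal(0, 0.1, 10_000)
        val, se = estimate_log_lr(series, return_se=True)
        assert se > 0 and abs(val) < 10 * se + 0.1


def test_chain_config_validation():
    with pytest.raises(ValueError):
        ChainConfig(n_iterations=100, burn_in=100)
    with pytest.raises(ValueError):
        ChainConfig(pcn_beta=0.0)
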