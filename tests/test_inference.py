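"""Every Gibbs full conditional is exact, so each one is checked against an
independent oracle: conjugate closed forms, brute-force enumeration of
discrete conditionals, and fine-grid CDF inversion for the truncated rate."""

import numpy as np
import pytest
from scipy import integrate, stats

from mncount.inference import (
    MCMCConfig,
    PosteriorSamples,
    PriorSpec,
    lambda_full_conditional,
    n_full_conditional,
    psi_full_conditional,
    q_full_conditional,
    run_mcmc,
    x0_conditional_pmf,
    x0_update,
)
from mncount.synthetic import PlotObservation, SiteParams, Study, simulate_site


class TestPsiConditional:
    @pytest.mark.parametrize(
        "n_plots, n_used, expected, mean",
        [
            (6, 6, (7, 1), 0.875),  # all six plots used
            (0, 0, (1, 1), 0.5),    # no data: the prior
            (3, 0, (1, 4), 0.2),    # three empty plots
        ],
    )
    def test_conjugate_update(self, n_plots, n_used, expected, mean):
        a, b = psi_full_conditional(n_plots, n_used)
        assert (a, b) == expected
        assert a / (a + b) == pytest.approx(mean)

    def test_rejects_inconsistent_counts(self):
        with pytest.raises(ValueError):
            psi_full_conditional(3, 4)
        with pytest.raises(ValueError):
            psi_full_conditional(-1, 0)


class TestLambdaConditional:
    def test_truncated_gamma_mean_with_no_nests(self):
        dist = lambda_full_conditional([0, 0], [4.0, 6.0], lambda_max=4.0)
        assert dist.shape == 1.0 and dist.rate == 10.0
        # Gamma(1, 10) barely notices the [0, 4] truncation
        assert dist.mean() == pytest.approx(0.1000, abs=1e-3)

    def test_empty_exposure_falls_back_to_prior(self, rng):
        dist = lambda_full_conditional([], [], lambda_max=4.0)
        draws = dist.rvs(rng, size=20_000)
        assert stats.kstest(draws, stats.uniform(0, 4).cdf).pvalue > 0.01
        assert dist.mean() == pytest.approx(2.0)

    def test_draws_match_grid_cdf_inversion(self, rng):
        # density proportional to lambda^8 exp(-2 lambda) on [0, 4]
        dist = lambda_full_conditional([8], [2.0], lambda_max=4.0)
        grid = np.linspace(0.0, 4.0, 20_001)
        dens = grid**8 * np.exp(-2.0 * grid)
        cdf = integrate.cumulative_trapezoid(dens, grid, initial=0.0)
        cdf /= cdf[-1]

        def oracle_cdf(x):
            return np.interp(x, grid, cdf)

        draws = dist.rvs(rng, size=100_000)
        assert draws.max() <= 4.0
        assert stats.ks_1samp(draws, oracle_cdf).pvalue > 0.01

    def test_rejects_nonpositive_exposure(self):
        with pytest.raises(ValueError):
            lambda_full_conditional([1], [0.0])


class TestNConditional:
    def test_perfect_detection_pins_n_to_y(self, rng):
        dist = n_full_conditional(y=5, lam=2.0, q=1.0, a=0.15, t=40.0)
        assert dist.rate == 0.0
        assert np.all(dist.rvs(rng, size=100) == 5)

    def test_zero_rate_pins_n_to_y(self, rng):
        dist = n_full_conditional(y=3, lam=0.0, q=0.5, a=0.15, t=40.0)
        assert np.all(dist.rvs(rng, size=100) == 3)

    def test_matches_enumeration_oracle(self):
        # brute force: P(n) propto Poisson(n; lam*a*t) * Binomial(y; n, q)
        y, rate, q = 3, 2.0, 0.8
        dist = n_full_conditional(y=y, lam=1.0, q=q, a=1.0, t=2.0)
        support = np.arange(y, 200)
        brute = stats.poisson.pmf(support, rate) * stats.binom.pmf(y, support, q)
        brute /= brute.sum()
        tv = 0.5 * np.abs(dist.pmf(support) - brute).sum()
        assert tv < 1e-9

    def test_impossible_data_rejected(self):
        with pytest.raises(ValueError, match="impossible"):
            n_full_conditional(y=2, lam=1.0, q=0.0, a=1.0, t=1.0)


class TestQConditional:
    def test_no_data_returns_prior(self):
        assert q_full_conditional(0, 0) == (1.0, 1.0)

    def test_all_revisit_nests_detected(self):
        # 93 recorded revisit nests with no latent misses
        assert q_full_conditional(93, 0) == (94.0, 1.0)

    def test_posterior_mean_identity(self):
        alpha, beta = q_full_conditional(
            10, 4, x_both=6, x_t1_only=2, x_t2_only=1, x0=12
        )
        s = 10 + 2 * 6 + 2 + 1
        f = 4 + 2 + 1 + 2 * (12 - 9)
        assert (alpha, beta) == (1 + s, 1 + f)
        assert alpha / (alpha + beta) == pytest.approx((1 + s) / (2 + s + f))

    def test_x0_below_found_rejected(self):
        with pytest.raises(ValueError):
            q_full_conditional(0, 0, x_both=5, x0=3)


class TestX0Update:
    def test_perfect_detection_gives_exactly_the_found_count(self, rng):
        assert all(x0_update(40, 1.0, 400, rng) == 40 for _ in range(20))

    def test_mean_matches_truncated_negative_binomial(self, rng):
        m, q = 40, 0.81
        support, pmf = x0_conditional_pmf(m, q, x0_max=400)
        exact_mean = float((support * pmf).sum())
        draws = np.array([x0_update(m, q, 400, rng) for _ in range(20_000)])
        se = draws.std() / np.sqrt(draws.size)
        assert abs(draws.mean() - exact_mean) < 4 * se
        assert draws.max() <= 400

    def test_pmf_matches_enumeration(self):
        # brute force over the truncated support: with m found out of x0 and
        # per-nest find probability s = 1 - (1-q)^2, flat prior on x0:
        # P(x0) propto C(x0, m) s^m (1-s)^(x0-m)
        for m, q, cap in [(0, 0.6, 30), (5, 0.3, 120)]:
            s = 1 - (1 - q) ** 2
            support = np.arange(m, cap + 1)
            brute = stats.binom.pmf(m, support, s)
            brute /= brute.sum()
            _, pmf = x0_conditional_pmf(m, q, cap)
            assert 0.5 * np.abs(pmf - brute).sum() < 1e-9


def _all_used_study(n_plots=6, seed=11):
    params = SiteParams(
        site_id="S", site_area=140.0, n_plots=n_plots,
        psi_true=1.0, lambda_true=0.8, q_true=0.81,
    )
    return Study(plots=simulate_site(params, seed=seed))


class TestRunMcmc:
    def test_psi_marginal_matches_conjugate_oracle(self, six_plot_used_study):
        samples = run_mcmc(
            six_plot_used_study,
            config=MCMCConfig(n_iter=6000, burn_in=1000, n_chains=2, seed=2),
        )
        psi = samples.flat("psi", "USM")
        # z is observed, so the psi chain is i.i.d. Beta(7, 1)
        assert abs(psi.mean() - 0.875) < 0.005
        assert stats.kstest(psi, stats.beta(7, 1).cdf).pvalue > 0.01

    def test_all_zero_site_keeps_prior_for_lambda(self):
        plots = [
            PlotObservation("Z", f"Z-p{i}", 0.1471, 0.0, 0, 0, 0, 0, 0, False)
            for i in range(3)
        ]
        samples = run_mcmc(
            Study(plots=plots),
            config=MCMCConfig(n_iter=4000, burn_in=500, n_chains=1, seed=9),
        )
        psi = samples.flat("psi", "Z")
        lam = samples.flat("lam", "Z")
        assert abs(psi.mean() - 0.2) < 0.02          # Beta(1, 4)
        assert stats.kstest(lam, stats.uniform(0, 4).cdf).pvalue > 0.01
        assert samples.na_eligible("Z")

    def test_identical_seeds_reproduce_identical_draws(self, six_plot_used_study):
        cfg = MCMCConfig(n_iter=600, burn_in=100, n_chains=2, seed=13)
        a = run_mcmc(six_plot_used_study, config=cfg)
        b = run_mcmc(six_plot_used_study, config=cfg)
        assert np.array_equal(a.q, b.q)
        assert np.array_equal(a.psi["USM"], b.psi["USM"])
        assert np.array_equal(a.lam["USM"], b.lam["USM"])
        assert np.array_equal(a.x0, b.x0)

    def test_plot_relabeling_leaves_draws_unchanged(self):
        study = _all_used_study(n_plots=8, seed=21)
        shuffled = Study(plots=list(reversed(study.plots)))
        cfg = MCMCConfig(n_iter=500, burn_in=100, n_chains=1, seed=3)
        a = run_mcmc(study, config=cfg)
        b = run_mcmc(shuffled, config=cfg)
        assert np.array_equal(a.lam["S"], b.lam["S"])
        assert np.array_equal(a.q, b.q)

    def test_draws_respect_prior_support(self, small_fit):
        for site in small_fit.site_ids:
            assert small_fit.lam[site].max() <= small_fit.priors.lambda_max
            assert small_fit.psi[site].min() >= 0
            assert small_fit.psi[site].max() <= 1
        assert small_fit.q.min() > 0 and small_fit.q.max() < 1
        m = 0  # x0 never drops below the distinct nests found
        assert small_fit.x0.min() >= m

    def test_draw_count_honors_config(self, small_fit):
        cfg = small_fit.config
        assert small_fit.q.shape == (cfg.n_chains, cfg.n_draws)
        assert small_fit.n_draws_total == cfg.n_chains * cfg.n_draws

    def test_plugin_mode_holds_q_fixed(self, six_plot_used_study):
        samples = run_mcmc(
            six_plot_used_study,
            config=MCMCConfig(n_iter=800, burn_in=100, n_chains=1, seed=4),
            q_mode="plugin",
        )
        assert np.ptp(samples.q) == 0.0
        assert 0.0 < samples.q.flat[0] < 1.0

    def test_empty_study_rejected(self):
        with pytest.raises(ValueError):
            run_mcmc(Study(plots=[]), config=MCMCConfig(n_iter=10, burn_in=1))

    def test_save_load_round_trip(self, small_fit, tmp_path):
        prefix = tmp_path / "fit"
        small_fit.save(prefix)
        loaded = PosteriorSamples.load(prefix)
        assert loaded.site_ids == small_fit.site_ids
        np.testing.assert_allclose(loaded.q, small_fit.q)
        for s in small_fit.site_ids:
            np.testing.assert_allclose(loaded.psi[s], small_fit.psi[s])
        assert loaded.n_used == small_fit.n_used


@pytest.mark.parametrize(
    "cfg",
    [
        dict(n_iter=100, burn_in=100),
        dict(n_chains=0),
        dict(thin=0),
    ],
)
def test_config_validation(cfg):
    with pytest.raises(ValueError):
        MCMCConfig(**{"n_iter": 1000, "burn_in": 10, **cfg}).validate()


def test_prior_spec_validation():
    with pytest.raises(ValueError):
        PriorSpec(lambda_max=0.0).validate()
    with pytest.raises(ValueError):
        PriorSpec(x0_max=5).resolve_x0_max(10)
    assert PriorSpec().resolve_x0_max(40) == 400
    assert PriorSpec().resolve_x0_max(0) == 20
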