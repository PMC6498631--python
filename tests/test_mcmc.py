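"""Sampler building blocks against conjugate closed forms and MC oracles."""

import numpy as np
import pytest

from sgcurve._distributions import (
    draw_invwishart,
    draw_scaled_inv_chisq,
    scaled_inv_chisq_posterior,
)
from sgcurve.mcmc import (
    GrowthSampler,
    MCMCConfig,
    PriorSpec,
    fit_entry_model,
    run_mcmc,
)


class TestConjugateDraws:
    def test_scaled_inv_chisq_posterior_algebra(self):
        df, scale = scaled_inv_chisq_posterior(-2.0, 0.0, ss=10.0, n=12)
        assert df == 10 and scale == pytest.approx(1.0)

    def test_scaled_inv_chisq_moments(self, rng):
        df, scale = 10.0, 1.0
        draws = np.array([draw_scaled_inv_chisq(rng, df, scale) for _ in range(100_000)])
        mean = df * scale / (df - 2)  # 1.25
        var = 2 * df**2 * scale**2 / ((df - 2) ** 2 * (df - 4))
        se = np.sqrt(var / draws.size)
        assert abs(draws.mean() - mean) < 3 * se

    def test_improper_posterior_guard(self):
        with pytest.raises(ValueError, match="improper"):
            scaled_inv_chisq_posterior(-2.0, 0.0, ss=1.0, n=2)

    def test_inverse_wishart_moments(self, rng):
        p, df = 3, 12.0
        a = rng.standard_normal((p, p))
        scale = a @ a.T + p * np.eye(p)
        draws = np.stack([draw_invwishart(rng, df, scale) for _ in range(20_000)])
        mean = scale / (df - p - 1)
        se = draws.std(axis=0, ddof=1) / np.sqrt(draws.shape[0])
        assert np.all(np.abs(draws.mean(axis=0) - mean) < 3 * se + 1e-12)


class TestConfig:
    def test_retained_draw_arithmetic_for_published_schedule(self):
        cfg = MCMCConfig(iterations=2_500_000, burn_in=2_000_000, thin=10)
        assert cfg.n_retained == 50_000

    def test_invalid_schedules_rejected(self):
        with pytest.raises(ValueError):
            MCMCConfig(iterations=100, burn_in=100)
        with pytest.raises(ValueError):
            MCMCConfig(iterations=100, burn_in=10, thin=0)


def make_sampler(small_dataset, vague_priors, **cfg_kw):
    data, _ = small_dataset
    kw = dict(iterations=10, burn_in=5, thin=1, n_chains=1, seed=1)
    kw.update(cfg_kw)
    s = GrowthSampler("sgc", data, vague_priors, MCMCConfig(**kw))
    s.init_state(np.random.default_rng(0))
    return s


class TestGibbsBlocks:
    def test_fixed_effects_collapse_to_ols_without_random_terms(
        self, small_dataset, vague_priors
    ):
        s = make_sampler(small_dataset, vague_priors)
        st = s.state
        st["u"][:] = 0.0
        st["v_0"][:] = 0.0
        st["v_1"][:] = 0.0
        st["sigma2_e0"] = 1e-10  # conditional collapses onto the OLS solution
        s.sample_location_effects(np.random.default_rng(2))
        ols, *_ = np.linalg.lstsq(s.X0, s.Y0, rcond=None)
        # u was redrawn inside the update; remove its (tiny) contribution
        np.testing.assert_allclose(
            st["beta0"],
            np.linalg.lstsq(s.X0, s.Y0 - st["u"][:, 3] - s._v_contrib(st), rcond=None)[0],
            atol=1e-5,
        )
        assert np.abs(st["beta0"] - ols).max() < 1.0

    def test_genetic_effect_conditional_matches_scalar_ridge_oracle(
        self, small_dataset, vague_priors
    ):
        # identity relationship + diagonal covariances decouple per animal:
        # the u0 conditional is the classic normal-normal shrinkage formula
        data, _ = small_dataset
        n = data.obs.n_animals
        import dataclasses

        data_iid = dataclasses.replace(data, relationship=np.eye(n))
        s = GrowthSampler(
            "sgc", data_iid, vague_priors,
            MCMCConfig(iterations=10, burn_in=5, thin=1, n_chains=1, seed=1),
        )
        rng = np.random.default_rng(3)
        s.init_state(rng)
        st = s.state
        st["Sigma_u"] = np.diag([100.0, 0.01, 1e-6, 400.0])
        st["Sigma_e"] = np.diag([50.0, 0.005, 5e-7])
        st["sigma2_e0"] = 250.0
        st["v_0"][:] = 0.0
        st["v_1"][:] = 0.0
        r0 = s.Y0 - s.X0 @ st["beta0"]
        prec = 1 / 400.0 + 1 / 250.0
        expect_mean = (r0 / 250.0) / prec
        draws = []
        for _ in range(4000):
            s._sample_genetic_effects(rng)
            draws.append(st["u"][:, 3].copy())
        draws = np.asarray(draws)
        se = draws.std(axis=0) / np.sqrt(len(draws))
        assert np.all(np.abs(draws.mean(axis=0) - expect_mean) < 4 * se + 1e-8)
        np.testing.assert_allclose(
            draws.var(axis=0), 1 / prec, rtol=0.15
        )

    def test_variance_update_recovers_inverse_wishart_scale_at_zero_effects(
        self, small_dataset, vague_priors
    ):
        s = make_sampler(small_dataset, vague_priors)
        st = s.state
        st["u"][:] = 0.0
        st["beta"][:] = 0.0
        st["G"][:] = 0.0001  # positivity not enforced here; residual E = G
        E = st["G"] - s.X @ st["beta"] - st["u"][:, :3]
        expected_scale = s.S_e + E.T @ E
        rng = np.random.default_rng(4)
        draws = []
        for _ in range(3000):
            st["u"][:] = 0.0
            st["beta"][:] = 0.0
            s.sample_variance_components(rng)
            draws.append(st["Sigma_e"].copy())
        draws = np.asarray(draws)
        mean = draws.mean(axis=0)
        expected = expected_scale / (s.nu_e + s.N - 3 - 1)
        se = draws.std(axis=0, ddof=1) / np.sqrt(draws.shape[0])
        assert np.all(np.abs(mean - expected) < 5 * se + 0.02 * np.abs(expected))


class TestMetropolisBlocks:
    def test_zero_proposal_scale_leaves_growth_state_unchanged(
        self, small_dataset, vague_priors
    ):
        s = make_sampler(small_dataset, vague_priors)
        s._log_scale_G[:] = -np.inf
        before = s.state["G"].copy()
        s.mh_update_growth_params(np.random.default_rng(5))
        np.testing.assert_array_equal(s.state["G"], before)

    def test_zero_proposal_scale_leaves_spline_weights_unchanged(
        self, small_dataset, vague_priors
    ):
        s = make_sampler(small_dataset, vague_priors)
        s.state["P"][:] = 0.3
        s._refresh_caches()
        s._log_scale_P[:] = -np.inf
        before = s.state["P"].copy()
        s.mh_update_spline_weights(np.random.default_rng(6))
        np.testing.assert_array_equal(s.state["P"], before)

    def test_acceptance_probability_matches_exact_posterior_ratio(self, rng):
        # scalar random-walk MH on a standard normal: empirical acceptance
        # from a fixed point x with scale s has closed form
        # E[min(1, exp(-(x+sz)^2/2 + x^2/2))]; check by simulation against
        # the same rule applied through independent arithmetic
        x, s = 1.0, 0.8
        z = rng.standard_normal(100_000)
        prop = x + s * z
        logr = -0.5 * prop**2 + 0.5 * x**2
        alpha = np.minimum(1.0, np.exp(logr))
        accepted = np.log(rng.uniform(size=z.size)) < logr
        se = alpha.std() / np.sqrt(z.size)
        assert abs(accepted.mean() - alpha.mean()) < 3 * se + 0.005

    def test_curve_level_ridge_move_ratio_matches_brute_force(
        self, small_dataset, vague_priors
    ):
        # the joint (P + delta, A - delta*Y0) proposal must use exactly the
        # posterior-density ratio of the full model
        from sgcurve.splines import CausalCurve, curve_prior_logdensity

        s = make_sampler(small_dataset, vague_priors)
        rng = np.random.default_rng(8)
        for _ in range(25):
            s.sweep(rng)
        st = s.state

        def copy_state(state):
            return {k: (v.copy() if hasattr(v, "copy") else v)
                    for k, v in state.items()}

        def gprior(state):
            mu = s.X @ state["beta"] + state["u"][:, :3]
            d = state["G"] - mu
            return -0.5 * float(
                np.einsum("ni,ij,nj->", d, np.linalg.inv(state["Sigma_e"]), d)
            )

        def pprior(state):
            return curve_prior_logdensity(
                CausalCurve(s.knots, state["P"], state["sigma2_p"])
            )

        for delta in (0.07, -0.11):
            prop = copy_state(st)
            prop["P"] = st["P"] + delta
            prop["G"][:, 0] = st["G"][:, 0] - delta * s.Y0
            brute = (
                s.loglik_for_state(prop) - s.loglik_for_state(st)
                + gprior(prop) - gprior(st)
                + pprior(prop) - pprior(st)
            )
            assert s._curve_level_log_ratio(delta) == pytest.approx(brute, abs=1e-6)

    def test_prior_only_spline_sampling_matches_random_walk_prior(
        self, small_dataset, vague_priors
    ):
        # with the trajectory likelihood switched off (huge residual variance)
        # the P-updates sample the second-order random-walk prior, so the
        # second differences have variance sigma2_p
        s = make_sampler(small_dataset, vague_priors)
        st = s.state
        st["sigma2_e"] = 1e30
        s._log_scale_P[:] = np.log(0.8)
        rng = np.random.default_rng(7)
        d2 = []
        for it in range(30_000):
            s.mh_update_spline_weights(rng)
            st["sigma2_p"] = 0.25  # hold the prior variance fixed
            if it > 2000 and it % 5 == 0:
                d2.append(np.diff(st["P"], n=2).copy())
        d2 = np.asarray(d2)
        assert d2.var() == pytest.approx(0.25, rel=0.15)


class TestPriorCalibration:
    def test_preliminary_scale_matrix_matches_stated_values(self):
        pri = PriorSpec.preliminary()
        np.testing.assert_array_equal(pri.S_e, np.diag([1e4, 0.65, 5e-7]))
        np.testing.assert_array_equal(pri.S_u_star, np.diag([1e4, 0.65, 5e-7]))
        assert pri.nu_u == 6 and pri.nu_e == 6 and pri.nu_u_star == 5
        assert (pri.nu0, pri.s0sq) == (-2.0, 0.0)

    def test_two_stage_calibration_assembles_valid_scales(self, small_dataset):
        from sgcurve.mcmc import calibrate_priors

        data, _ = small_dataset
        cfg = MCMCConfig(iterations=800, burn_in=400, thin=4, n_chains=1, seed=2)
        pri = calibrate_priors(data, cfg)
        assert pri.S_u.shape == (4, 4)
        np.testing.assert_allclose(pri.S_u, pri.S_u.T)
        assert np.linalg.eigvalsh(pri.S_u).min() > 0
        # growth block comes from the GC_B fit, entry block from the
        # entry-day mixed model; both must carry positive variance scales
        assert pri.S_u[3, 3] > 0
        assert np.all(np.diag(pri.S_e) >= 0)
        assert pri.S_e[0, 0] > 1.0  # asymptote dispersion is in kg² units


class TestRunMcmc:
    def test_fixed_seed_reproduces_posterior_exactly(self, small_dataset, vague_priors):
        data, _ = small_dataset
        cfg = MCMCConfig(iterations=120, burn_in=60, thin=3, n_chains=2, seed=11)
        a = run_mcmc("sgc", data, vague_priors, cfg)
        b = run_mcmc("sgc", data, vague_priors, cfg)
        for name in a.names():
            np.testing.assert_array_equal(a.stacked(name), b.stacked(name))
        np.testing.assert_array_equal(a.loglik, b.loglik)

    def test_acceptance_rates_adapt_into_target_band(self, small_dataset, vague_priors):
        data, _ = small_dataset
        cfg = MCMCConfig(iterations=1500, burn_in=1000, thin=5, n_chains=1, seed=12)
        samples = run_mcmc("sgc", data, vague_priors, cfg)
        for name, rate in samples.acceptance[0].items():
            assert 0.1 <= rate <= 0.6, f"{name} acceptance {rate}"

    def test_all_three_models_produce_finite_draws(self, small_dataset, vague_priors):
        data, _ = small_dataset
        cfg = MCMCConfig(iterations=150, burn_in=50, thin=5, n_chains=1, seed=13)
        for model in ("sgc", "gc_a", "gc_b"):
            s = run_mcmc(model, data, vague_priors, cfg)
            assert np.all(np.isfinite(s.loglik))
            assert s.n_draws == cfg.n_retained

    def test_entry_model_recovers_simple_regression(self, rng):
        n = 300
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        beta = np.array([5.0, 2.0])
        y = X @ beta + rng.normal(0, 1.0, n)
        cfg = MCMCConfig(iterations=600, burn_in=300, thin=3, n_chains=1, seed=14)
        fit = fit_entry_model(y, X, np.eye(n), [], PriorSpec(), cfg)
        np.testing.assert_allclose(fit.mean("beta"), beta, atol=0.3)
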