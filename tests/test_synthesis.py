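"""Synthetic-data generator properties and the parametric-bootstrap check."""

import numpy as np
import pytest

from sgcurve.growth_model import gompertz
from sgcurve.mcmc import MCMCConfig
from sgcurve.pedigree import build_nrm
from sgcurve.synthesis import (
    SimulationConfig,
    default_sigma_u,
    fit_animal_model,
    piecewise_lambda,
    simulate_pedigree,
    simulate_sgc_dataset,
)


class TestLambdaCurve:
    def test_plateau_then_linear_decay(self):
        lam = piecewise_lambda(0.8, 200.0, 620.0)
        assert lam(0.0) == lam(200.0) == 0.8
        assert lam(410.0) == pytest.approx(0.4, abs=1e-12)
        assert lam(620.0) == 0.0 and lam(900.0) == 0.0

    def test_invalid_breakpoints_rejected(self):
        with pytest.raises(ValueError):
            piecewise_lambda(0.8, 620.0, 200.0)


class TestPedigreeSimulation:
    def test_final_generation_has_requested_size(self, rng):
        cfg = SimulationConfig(n_animals=120, n_generations=3, n_sires=8)
        ped, phen = simulate_pedigree(cfg, rng)
        assert len(phen) == 120
        assert ped.generation_depth == 3

    def test_phenotyped_animals_are_related(self, rng):
        cfg = SimulationConfig(n_animals=80, n_sires=5)
        ped, phen = simulate_pedigree(cfg, rng)
        a = build_nrm(ped).submatrix(phen).values
        off = a[np.triu_indices_from(a, k=1)]
        assert off.max() >= 0.25  # half or full sibs exist


class TestSimulateDataset:
    def test_degenerate_limit_reproduces_fixed_effect_gompertz(self, rng):
        tiny = 1e-30
        cfg = SimulationConfig(
            n_animals=25,
            sigma2_u0=0.0, sigma2_v1=0.0, sigma2_v2=0.0, sigma2_e0=0.0,
            sigma2_e=0.0,
            Sigma_u=np.eye(4) * tiny,
            Sigma_e=np.eye(3) * tiny,
            lambda_plateau=0.0, lambda_decay_start=10.0, lambda_extinction=11.0,
        )
        data, truth = simulate_sgc_dataset(cfg, rng)
        for i, (t, w) in enumerate(zip(data.obs.times, data.obs.weights)):
            f = gompertz(t, *truth["G"][i])
            np.testing.assert_allclose(w, f, atol=1e-4)

    def test_entry_weight_variance_decomposition(self):
        cfg = SimulationConfig(n_animals=2000, n_sires=60)
        data, truth = simulate_sgc_dataset(cfg, np.random.default_rng(77))
        random_part = data.obs.entry_weight - data.X0 @ truth["beta0"]
        total = cfg.sigma2_u0 + cfg.sigma2_v1 + cfg.sigma2_v2 + cfg.sigma2_e0
        assert np.var(random_part) == pytest.approx(total, rel=0.05)

    def test_defaults_match_reported_study_scale(self):
        cfg = SimulationConfig(n_animals=2000, n_sires=60)
        data, _ = simulate_sgc_dataset(cfg, np.random.default_rng(78))
        obs = data.obs
        assert obs.entry_weight.mean() == pytest.approx(236.0, abs=6.0)
        assert obs.n_records / obs.n_animals == pytest.approx(4.4, abs=0.35)
        slaughter = np.array([w[-1] for w in obs.weights])
        assert slaughter.mean() == pytest.approx(730.0, abs=40.0)

    def test_invalid_covariance_rejected(self):
        with pytest.raises(ValueError, match="positive definite"):
            SimulationConfig(Sigma_e=np.zeros((3, 3)))

    def test_maternal_plus_farm_share_configurable(self):
        # maternal+farm fraction of entry random variance: 268.6/1033 ≈ 0.26
        cfg = SimulationConfig(n_animals=5000, n_sires=150)
        data, truth = simulate_sgc_dataset(cfg, np.random.default_rng(79))
        dam_idx = data.random_effects[0].levels
        farm_idx = data.random_effects[1].levels
        contrib = (
            truth["maternal"][dam_idx].var() + truth["farm"][farm_idx].var()
        )
        random_part = data.obs.entry_weight - data.X0 @ truth["beta0"]
        share = contrib / np.var(random_part)
        expected = (cfg.sigma2_v1 + cfg.sigma2_v2) / (
            cfg.sigma2_u0 + cfg.sigma2_v1 + cfg.sigma2_v2 + cfg.sigma2_e0
        )
        assert share == pytest.approx(expected, abs=0.03)


def half_sib_relationship(n_sires, per_sire):
    n = n_sires * per_sire
    a = np.eye(n)
    for s in range(n_sires):
        blk = slice(s * per_sire, (s + 1) * per_sire)
        a[blk, blk] += 0.25 * (1 - np.eye(per_sire))
    return a


class TestAnimalModel:
    def test_recovers_half_sib_heritability(self):
        rng = np.random.default_rng(5)
        n_sires, per_sire = 200, 10
        n = n_sires * per_sire
        h2, vp = 0.4, 100.0
        sire_eff = rng.normal(0, np.sqrt(h2 * vp / 4), n_sires)
        mend = rng.normal(0, np.sqrt(0.75 * h2 * vp), n)
        e = rng.normal(0, np.sqrt((1 - h2) * vp), n)
        y = 50.0 + np.repeat(sire_eff, per_sire) + mend + e
        a = half_sib_relationship(n_sires, per_sire)
        cfg = MCMCConfig(iterations=1200, burn_in=600, thin=3, n_chains=1, seed=3)
        res = fit_animal_model(y, np.ones((n, 1)), a, cfg)
        assert res["h2_mean"] == pytest.approx(h2, abs=0.08)

    def test_near_perfect_heritability_at_vanishing_residual(self):
        rng = np.random.default_rng(6)
        n = 300
        a = half_sib_relationship(30, 10)
        u = np.linalg.cholesky(a + 1e-9 * np.eye(n)) @ rng.standard_normal(n) * 10
        y = 20.0 + u + rng.normal(0, 0.1, n)
        cfg = MCMCConfig(iterations=800, burn_in=400, thin=2, n_chains=1, seed=4)
        res = fit_animal_model(y, np.ones((n, 1)), a, cfg)
        assert res["h2_mean"] > 0.9

    def test_agrees_with_half_sib_anova_oracle(self):
        # independent route: classic balanced half-sib ANOVA estimates
        # sigma2_sire = (MS_between - MS_within)/per_sire = sigma2_a/4;
        # the animal-model Gibbs fit must land on the same heritability
        rng = np.random.default_rng(21)
        n_sires, per = 150, 12
        n = n_sires * per
        h2, vp = 0.45, 100.0
        sire_eff = rng.normal(0, np.sqrt(h2 * vp / 4), n_sires)
        y = (
            30.0
            + np.repeat(sire_eff, per)
            + rng.normal(0, np.sqrt(vp - h2 * vp / 4), n)
        )
        groups = y.reshape(n_sires, per)
        msb = per * np.var(groups.mean(axis=1), ddof=1)
        msw = np.mean(np.var(groups, axis=1, ddof=1))
        s2s = (msb - msw) / per
        h2_anova = 4 * s2s / (s2s + msw)
        cfg = MCMCConfig(iterations=1500, burn_in=750, thin=3, n_chains=1, seed=5)
        ours = fit_animal_model(
            y, np.ones((n, 1)), half_sib_relationship(n_sires, per), cfg
        )
        assert ours["h2_mean"] == pytest.approx(h2_anova, abs=0.1)

    def test_rank_deficient_design_rejected(self):
        with pytest.raises(ValueError, match="rank"):
            fit_animal_model(
                np.zeros(10), np.ones((10, 2)), np.eye(10),
                MCMCConfig(iterations=10, burn_in=5),
            )


class TestParametricBootstrap:
    def test_default_replicate_count_is_one_thousand(self):
        import inspect

        from sgcurve.synthesis import parametric_bootstrap

        sig = inspect.signature(parametric_bootstrap)
        assert sig.parameters["replicates"].default == 1000

    def test_zero_genetic_variance_truth_yields_null_heritability(self):
        from sgcurve.splines import CausalCurve, build_knots
        from sgcurve.synthesis import SGCParameters, parametric_bootstrap

        # a large, deep-family pedigree (≈30 offspring per sire) so the
        # heritability posterior can concentrate near the zero boundary
        rng = np.random.default_rng(9)
        cfg = SimulationConfig(n_animals=1200, n_sires=40)
        data, truth = simulate_sgc_dataset(cfg, rng)
        tiny = 1e-8
        est = SGCParameters(
            beta0=truth["beta0"],
            beta=truth["beta"],
            Sigma_u=np.diag([tiny, tiny * 1e-4, tiny * 1e-8, tiny]),
            Sigma_e=cfg.Sigma_e,
            sigma2_v=[cfg.sigma2_v1, cfg.sigma2_v2],
            sigma2_e0=cfg.sigma2_e0,
            sigma2_e=cfg.sigma2_e,
            curve=CausalCurve(build_knots(data.obs.T_L), np.zeros(8)),
        )
        slaughter = np.array([t[-1] for t in data.obs.times])
        mc = MCMCConfig(iterations=2500, burn_in=1250, thin=5, n_chains=1, seed=10)
        res = parametric_bootstrap(
            est, data, slaughter, mc, replicates=8, rng=rng
        )
        assert res.mean < 0.05
        assert res.heritabilities.size == 8
        assert np.all((res.heritabilities >= 0) & (res.heritabilities <= 1))

    def test_recovers_configured_heritability(self):
        from sgcurve.splines import CausalCurve, build_knots
        from sgcurve.synthesis import SGCParameters, parametric_bootstrap

        rng = np.random.default_rng(11)
        cfg = SimulationConfig(n_animals=200, n_sires=12)
        data, truth = simulate_sgc_dataset(cfg, rng)
        # truth at slaughter: weight ≈ A (asymptote), so h2 at slaughter is
        # driven by the genetic share of var(A): 6200 / (6200 + 200 + s2e)
        est = SGCParameters(
            beta0=truth["beta0"], beta=truth["beta"],
            Sigma_u=cfg.Sigma_u, Sigma_e=cfg.Sigma_e,
            sigma2_v=[cfg.sigma2_v1, cfg.sigma2_v2],
            sigma2_e0=cfg.sigma2_e0, sigma2_e=cfg.sigma2_e,
            curve=CausalCurve(build_knots(data.obs.T_L), np.zeros(8)),
        )
        slaughter = np.array([t[-1] for t in data.obs.times])
        mc = MCMCConfig(iterations=500, burn_in=250, thin=2, n_chains=1, seed=12)
        res = parametric_bootstrap(est, data, slaughter, mc, replicates=25, rng=rng)
        assert 0.5 < res.mean < 1.0
        assert res.q05 <= res.mean
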