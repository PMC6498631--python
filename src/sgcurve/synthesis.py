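"""Synthetic pedigreed longitudinal data and the parametric-bootstrap check.

The generator draws every component of the structural growth curve model in
the generative direction: a multi-generation pedigree; four correlated genetic
effect vectors N(0, Σ_u ⊗ A); maternal (pedigree-structured) and
reproduction-farm (iid) effects on the entry-day weight; per-animal Gompertz
parameters from their hierarchy; and weight trajectories observed on irregular
per-animal schedules with a configurable causal-effect curve added.

Default magnitudes emulate the Japanese Black progeny-testing data the model
was built for: entry at ≈ 251 d of age with mean entry weight ≈ 236 kg
(SD ≈ 39, decomposed into genetic 499.4, maternal 49.6, farm 219.0 and
residual 265.0 kg²), slaughter ≈ 635 d after entry at ≈ 730 kg, and 4.4 ± 0.7
weight records per animal (clamped to 1–6).  The default causal-effect curve
is a plateau at 0.8 up to day 200 followed by a linear decline reaching zero
(extinction) at day 620.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._distributions import nearest_pd
from .growth_model import gompertz
from .likelihood import ObservationSet
from .mcmc import (
    MCMCConfig,
    ModelData,
    PosteriorSamples,
    PriorSpec,
    RandomEffect,
    fit_entry_model,
)
from .pedigree import PedigreeTable, build_nrm
from .splines import CausalCurve

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "SGCParameters",
    "BootstrapResult",
    "simulate_pedigree",
    "simulate_sgc_dataset",
    "piecewise_lambda",
    "fit_animal_model",
    "parametric_bootstrap",
]


def _correlated_cov(sds, corr) -> np.ndarray:
    sds = np.asarray(sds, dtype=float)
    corr = np.asarray(corr, dtype=float)
    cov = corr * np.outer(sds, sds)
    cov, _ = nearest_pd(cov)
    return cov


def default_sigma_u(entry_growth_corr: tuple = (0.0, 0.0, 0.0)) -> np.ndarray:
    """Genetic covariance of (A, B, K, entry weight): high growth-parameter
    heritabilities with the estimated correlation signs (A–B +, A–K −, B–K −).

    By default the entry-weight genetic effect is uncorrelated with the growth
    parameters, i.e. all dependence of later weight on the entry weight flows
    through the causal path λ(t)·Y_0 — the clean generative regime of the
    structural model.  A residual genetic correlation can be injected through
    ``entry_growth_corr``; note that at small sample sizes such a correlation
    is nearly confounded with a level shift of λ(t) (see the methods note).
    """
    sds = [np.sqrt(6200.0), np.sqrt(0.082), np.sqrt(5.8e-7), np.sqrt(499.4)]
    ca, cb, ck = entry_growth_corr
    corr = np.array(
        [
            [1.0, 0.63, -0.69, ca],
            [0.63, 1.0, -0.67, cb],
            [-0.69, -0.67, 1.0, ck],
            [ca, cb, ck, 1.0],
        ]
    )
    return _correlated_cov(sds, corr)


def default_sigma_e() -> np.ndarray:
    """Growth-parameter residual covariance (small next to the genetic part)."""
    sds = [np.sqrt(200.0), np.sqrt(0.008), np.sqrt(6e-8)]
    corr = np.array(
        [[1.0, 0.34, -0.57], [0.34, 1.0, -0.30], [-0.57, -0.30, 1.0]]
    )
    return _correlated_cov(sds, corr)


def piecewise_lambda(plateau: float, decay_start: float, extinction: float):
    """Causal-effect curve: constant plateau, then linear decay to zero."""
    if not 0 <= decay_start < extinction:
        raise ValueError("require 0 <= decay_start < extinction")

    def lam(t):
        t = np.asarray(t, dtype=float)
        out = np.where(
            t <= decay_start,
            plateau,
            plateau * np.clip((extinction - t) / (extinction - decay_start), 0.0, None),
        )
        return float(out) if out.ndim == 0 else out

    return lam


@dataclass
class SimulationConfig:
    """True parameter values and population structure of a synthetic study."""

    n_animals: int = 400
    n_generations: int = 3
    #: sires per generation: progeny-testing populations use few sires with
    #: large paternal half-sib families, which is what identifies the genetic
    #: variances; dams are plentiful (one small maternal family each)
    n_sires: int = 15
    n_dams: int | None = None  # default: n_animals // 3
    animals_per_farm: int = 2
    n_stations: int = 3
    n_birth_years: int = 4
    # entry-day weight model (kg / kg²)
    beta0_intercept: float = 223.0
    beta0_sex: float = 25.0
    beta0_age: float = 15.0
    sigma2_u0: float = 499.4
    sigma2_v1: float = 49.6
    sigma2_v2: float = 219.0
    sigma2_e0: float = 265.0
    # growth curves
    beta_A: tuple = (780.0, 50.0)
    beta_B: tuple = (2.8, 0.05)
    beta_K: tuple = (5.4e-3, 2e-4)
    Sigma_u: np.ndarray = field(default_factory=default_sigma_u)
    Sigma_e: np.ndarray = field(default_factory=default_sigma_e)
    sigma2_e: float = 300.0
    # causal-effect curve
    lambda_plateau: float = 0.8
    lambda_decay_start: float = 200.0
    lambda_extinction: float = 620.0
    # measurement schedule
    records_per_animal: tuple = (4.4, 0.7)
    max_records: int = 6
    slaughter_day: tuple = (635.0, 46.7)
    entry_age: tuple = (251.5, 20.4)

    def __post_init__(self) -> None:
        for name in ("Sigma_u", "Sigma_e"):
            m = np.asarray(getattr(self, name), dtype=float)
            if np.linalg.eigvalsh(m).min() <= 0:
                raise ValueError(f"{name} must be positive definite")
            setattr(self, name, m)
        for name in ("sigma2_u0", "sigma2_v1", "sigma2_v2", "sigma2_e0", "sigma2_e"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    def lambda_true(self):
        return piecewise_lambda(
            self.lambda_plateau, self.lambda_decay_start, self.lambda_extinction
        )


def _spline_template_curve(config: SimulationConfig, T_L: float) -> CausalCurve:
    """Least-squares projection of the plateau/decay template onto the cubic
    B-spline basis with the model's knot rule for the realized T_L."""
    from .splines import basis_matrix, build_knots

    kv = build_knots(T_L)
    if config.lambda_plateau == 0.0:
        return CausalCurve(kv, np.zeros(kv.n_basis))
    template = piecewise_lambda(
        config.lambda_plateau, config.lambda_decay_start, config.lambda_extinction
    )
    grid = np.linspace(0.0, kv.domain[1] * (1 - 1e-9), 600)
    S = basis_matrix(grid, kv)
    w, *_ = np.linalg.lstsq(S, template(grid), rcond=None)
    return CausalCurve(kv, w)


def simulate_pedigree(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[PedigreeTable, list[str]]:
    """Discrete-generation random-mating pedigree.

    Returns the pedigree and the ids of the final (phenotyped) generation,
    which has exactly ``n_animals`` members.
    """
    n_dams = config.n_dams or max(config.n_animals // 3, 10)
    males = [f"M0_{i}" for i in range(config.n_sires)]
    females = [f"F0_{i}" for i in range(n_dams)]
    records = [(a, None, None) for a in males + females]
    # intermediate generations stay at breeding-population scale; only the
    # final (phenotyped) generation is expanded to n_animals
    for g in range(1, config.n_generations + 1):
        last = g == config.n_generations
        size = config.n_animals if last else config.n_sires + n_dams
        new_m, new_f = [], []
        for i in range(size):
            sire = males[rng.integers(len(males))]
            dam = females[rng.integers(len(females))]
            sex_m = (len(new_m) < config.n_sires) if not last else rng.random() < 0.5
            name = f"{'M' if sex_m else 'F'}{g}_{i}"
            records.append((name, sire, dam))
            (new_m if sex_m else new_f).append(name)
        if not last:
            males = new_m or males
            females = new_f or females
    ped = PedigreeTable(records)
    phen = [a for a, _, _ in records[-config.n_animals :]]
    return ped, phen


def _design_matrices(config: SimulationConfig, rng: np.random.Generator):
    n = config.n_animals
    sex = rng.integers(0, 2, size=n)  # 1 = steer
    year = rng.integers(0, config.n_birth_years, size=n)
    season = rng.integers(0, 4, size=n)
    station = rng.integers(0, config.n_stations, size=n)
    age = rng.normal(config.entry_age[0], config.entry_age[1], size=n)
    age_std = (age - age.mean()) / age.std()
    year_d = np.eye(config.n_birth_years)[year][:, 1:]
    season_d = np.eye(4)[season][:, 1:]
    X0 = np.column_stack([np.ones(n), sex, year_d, season_d, age_std])
    station_d = np.eye(config.n_stations)[station][:, 1:]
    X = np.column_stack([np.ones(n), sex, station_d])
    return X0, X, sex, station, age


def simulate_sgc_dataset(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[ModelData, dict]:
    """Draw a complete synthetic dataset; returns (data, truth).

    ``truth`` holds every simulated component (pedigree, genetic effects,
    growth parameters, the causal curve, slaughter times) for recovery tests.
    """
    n = config.n_animals
    ped, phen = simulate_pedigree(config, rng)
    nrm = build_nrm(ped)
    A_sub = nrm.submatrix(phen).values

    # genetic effects: chol(A) Z chol(Σ_u)ᵀ has covariance Σ_u ⊗ A
    La = np.linalg.cholesky(A_sub + 1e-10 * np.eye(n))
    Lu = np.linalg.cholesky(config.Sigma_u)
    u = La @ rng.standard_normal((n, 4)) @ Lu.T
    u = u[:, [0, 1, 2, 3]]

    # maternal effect: effect of each dam, pedigree covariance among dams
    dam_of = {a: d for a, _, d in ped.records}
    dams = sorted({dam_of[a] for a in phen if dam_of[a] is not None})
    dam_idx = np.array([dams.index(dam_of[a]) for a in phen])
    H1 = nrm.submatrix(dams).values
    m_eff = np.linalg.cholesky(H1 + 1e-10 * np.eye(len(dams))) @ rng.standard_normal(
        len(dams)
    ) * np.sqrt(config.sigma2_v1)

    # reproduction-farm effect: iid levels
    n_farms = max(1, n // config.animals_per_farm)
    farm_idx = rng.integers(0, n_farms, size=n)
    f_eff = rng.normal(0.0, np.sqrt(config.sigma2_v2), size=n_farms)

    X0, X, sex, station, age = _design_matrices(config, rng)
    beta0 = np.concatenate(
        [
            [config.beta0_intercept, config.beta0_sex],
            rng.normal(0, 4, size=config.n_birth_years - 1),
            rng.normal(0, 4, size=3),
            [config.beta0_age],
        ]
    )
    y0 = (
        X0 @ beta0
        + u[:, 3]
        + m_eff[dam_idx]
        + f_eff[farm_idx]
        + rng.normal(0, np.sqrt(config.sigma2_e0), size=n)
    )

    # growth parameters from the hierarchy
    beta = np.zeros((X.shape[1], 3))
    beta[0] = [config.beta_A[0], config.beta_B[0], config.beta_K[0]]
    beta[1] = [config.beta_A[1], config.beta_B[1], config.beta_K[1]]
    e_g = rng.standard_normal((n, 3)) @ np.linalg.cholesky(config.Sigma_e).T
    G = X @ beta + u[:, :3] + e_g
    G = np.clip(G, [1.0, 1e-3, 1e-6], None)

    # irregular measurement schedules ending at slaughter
    counts = np.clip(
        np.rint(rng.normal(*config.records_per_animal, size=n)).astype(int),
        1,
        config.max_records,
    )
    t_sl = np.clip(rng.normal(*config.slaughter_day, size=n), 120.0, None)
    times, weights = [], []
    schedule = []
    for i in range(n):
        k = counts[i]
        # station-by-year measurement calendars differ, so pooled record times
        # are dispersed over the whole fattening period; the final record is
        # the weight at slaughter
        t = np.sort(rng.uniform(10.0, t_sl[i], size=k - 1)) if k > 1 else np.empty(0)
        schedule.append(np.unique(np.round(np.append(t, t_sl[i]))))

    # the true causal-effect curve is realized as a cubic B-spline on the
    # same knot rule the model uses (the template fixes its plateau, decay
    # start and extinction); growth biology is smooth and this keeps the
    # simulated truth inside the model's curve class
    T_L = max(float(t[-1]) for t in schedule)
    lam = _spline_template_curve(config, T_L)

    for i in range(n):
        t = schedule[i]
        f = gompertz(t, G[i, 0], G[i, 1], G[i, 2])
        y = y0[i] * lam(t) + f + rng.normal(0, np.sqrt(config.sigma2_e), size=t.size)
        times.append(t)
        weights.append(y)

    obs = ObservationSet(y0, times, weights)
    data = ModelData(
        obs=obs,
        X0=X0,
        X=X,
        relationship=A_sub,
        random_effects=[
            RandomEffect("maternal", dam_idx, H1),
            RandomEffect("farm", farm_idx, None),
        ],
        entry_age=age,
    )
    truth = {
        "pedigree": ped,
        "phenotyped_ids": phen,
        "u": u,
        "maternal": m_eff,
        "farm": f_eff,
        "beta0": beta0,
        "beta": beta,
        "G": G,
        "lambda": lam,
        "sex": sex,
        "station": station,
        "slaughter_day": t_sl,
        "config": config,
    }
    return data, truth


# ---------------------------------------------------------------------------
# parametric bootstrap of heritability at slaughter
# ---------------------------------------------------------------------------


@dataclass
class SGCParameters:
    """Point estimates of the full SGC parameter state used to re-simulate data."""

    beta0: np.ndarray
    beta: np.ndarray
    Sigma_u: np.ndarray
    Sigma_e: np.ndarray
    sigma2_v: list[float]
    sigma2_e0: float
    sigma2_e: float
    curve: CausalCurve

    @classmethod
    def from_samples(cls, samples: PosteriorSamples) -> "SGCParameters":
        """Posterior-mean parameter state of an SGC fit."""
        if samples.model != "sgc":
            raise ValueError("expected an SGC fit")
        s2v = []
        j = 0
        while f"sigma2_v{j}" in samples.names():
            s2v.append(float(samples.mean(f"sigma2_v{j}")))
            j += 1
        return cls(
            beta0=samples.mean("beta0"),
            beta=samples.mean("beta"),
            Sigma_u=samples.mean("Sigma_u"),
            Sigma_e=samples.mean("Sigma_e"),
            sigma2_v=s2v,
            sigma2_e0=float(samples.mean("sigma2_e0")),
            sigma2_e=float(samples.mean("sigma2_e")),
            curve=CausalCurve(samples.knots, samples.mean("P")),
        )


@dataclass
class BootstrapResult:
    heritabilities: np.ndarray
    mean: float
    sd: float
    q05: float
    observed: float | None = None
    n_excluded: int = 0


def fit_animal_model(
    phenotypes: np.ndarray,
    fixed_design: np.ndarray,
    relationship: np.ndarray,
    config: MCMCConfig,
    rng: np.random.Generator | None = None,
    priors: PriorSpec | None = None,
) -> dict:
    """Single-trait animal model y = Xβ + u + e, u ~ N(0, A σ²_a), by Gibbs.

    Returns posterior summaries of the heritability σ²_a / (σ²_a + σ²_e).
    """
    X = np.asarray(fixed_design, dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed-effect design is rank deficient")
    priors = priors or PriorSpec()
    fit = fit_entry_model(
        np.asarray(phenotypes, dtype=float), X, relationship, [], priors, config, rng
    )
    s2u = fit.flat("sigma2_u")
    s2e = fit.flat("sigma2_e")
    h2 = s2u / (s2u + s2e)
    return {
        "h2_mean": float(h2.mean()),
        "h2_sd": float(h2.std(ddof=1)),
        "h2_draws": h2,
        "sigma2_a": float(s2u.mean()),
        "sigma2_e": float(s2e.mean()),
        "samples": fit,
    }


def simulate_slaughter_weights(
    estimates: SGCParameters,
    data: ModelData,
    slaughter_times: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """One parametric-bootstrap replicate of the weights at slaughter.

    All random components are redrawn from the estimated generative model:
    genetic effects from Σ̂_u ⊗ A, maternal/farm effects from their estimated
    variances, growth parameters from their hierarchy, and fresh residuals;
    the slaughter weight is Y_0 λ̂(T_i) + f(T_i; A_i, B_i, K_i) + e.
    """
    n = data.obs.n_animals
    La = np.linalg.cholesky(data.relationship + 1e-10 * np.eye(n))
    Lu = np.linalg.cholesky(estimates.Sigma_u)
    u = La @ rng.standard_normal((n, 4)) @ Lu.T
    y0 = data.X0 @ estimates.beta0 + u[:, 3]
    for re, s2 in zip(data.random_effects, estimates.sigma2_v):
        if re.H is not None:
            Lh = np.linalg.cholesky(re.H + 1e-10 * np.eye(re.n_levels))
            eff = Lh @ rng.standard_normal(re.n_levels) * np.sqrt(s2)
        else:
            eff = rng.normal(0, np.sqrt(s2), size=re.n_levels)
        y0 = y0 + eff[re.levels]
    y0 = y0 + rng.normal(0, np.sqrt(estimates.sigma2_e0), size=n)
    e_g = rng.standard_normal((n, 3)) @ np.linalg.cholesky(estimates.Sigma_e).T
    G = np.clip(data.X @ estimates.beta + u[:, :3] + e_g, [1.0, 1e-3, 1e-6], None)
    t = np.asarray(slaughter_times, dtype=float)
    lam = estimates.curve(np.clip(t, *_curve_span(estimates)))
    f = gompertz(t, G[:, 0], G[:, 1], G[:, 2])
    return y0 * lam + f + rng.normal(0, np.sqrt(estimates.sigma2_e), size=n)


def _curve_span(estimates: SGCParameters) -> tuple[float, float]:
    lo, hi = estimates.curve.knots.domain
    return lo, np.nextafter(hi, lo)


def parametric_bootstrap(
    estimates: SGCParameters,
    data: ModelData,
    slaughter_times: np.ndarray,
    config: MCMCConfig,
    replicates: int = 1000,
    rng: np.random.Generator | None = None,
    observed_h2: float | None = None,
    animal_model_design: np.ndarray | None = None,
) -> BootstrapResult:
    """Repeatedly simulate slaughter weights and refit the animal model.

    ``config`` controls the per-replicate Gibbs fit.  The animal-model design
    defaults to the growth-curve fixed effects (sex, station) plus the
    standardized slaughter age, when entry ages are available.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if animal_model_design is None:
        cols = [data.X]
        if data.entry_age is not None:
            sl_age = data.entry_age + np.asarray(slaughter_times, dtype=float)
            cols.append(((sl_age - sl_age.mean()) / sl_age.std())[:, None])
        Xb = np.column_stack(cols)
    else:
        Xb = np.asarray(animal_model_design, dtype=float)
    h2 = []
    excluded = 0
    for b in range(replicates):
        y = simulate_slaughter_weights(estimates, data, slaughter_times, rng)
        try:
            res = fit_animal_model(y, Xb, data.relationship, config, rng=rng)
        except (np.linalg.LinAlgError, ValueError) as exc:
            excluded += 1
            logger.warning("bootstrap replicate %d excluded: %s", b, exc)
            continue
        h2.append(res["h2_mean"])
    h2 = np.asarray(h2)
    if h2.size == 0:
        raise RuntimeError("all bootstrap replicates failed")
    return BootstrapResult(
        heritabilities=h2,
        mean=float(h2.mean()),
        sd=float(h2.std(ddof=1)) if h2.size > 1 else 0.0,
        q05=float(np.quantile(h2, 0.05)),
        observed=observed_h2,
        n_excluded=excluded,
    )
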