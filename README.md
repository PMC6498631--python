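# sgcurve — structural growth curve models for pedigreed longitudinal weights

`sgcurve` is a Bayesian toolkit for a question that ordinary growth-curve
models cannot ask: *how strongly, and for how long, does an animal's initial
weight causally influence its later growth?*  The motivating setting is beef
cattle production, where calves are raised on reproduction farms and moved to
fattening stations at around nine months of age; the weight at entry carries
maternal, farm and genetic influences, and its imprint on the fattening-phase
trajectory decays with time.

## The model

For animal *i*, with time *t* in days since entry to the station:

```
Y_i0 = x_i0 β0 + u_i0 + v_mat,i + v_farm,i + e_i0          (entry day)
Y_it = Y_i0 λ(t) + f(t; A_i, B_i, K_i) + e_it              (fattening)
```

* `f(t) = A·exp{−B·exp(−K t)}` is the Gompertz curve: asymptotic weight A
  (kg), time shift B, maturing rate K (1/day).
* `λ(t)` is the time-varying **causal effect** of the entry weight, a cubic
  B-spline with 8 basis functions (12 knots: four at 0, interior at T_L/4,
  T_L/2, 3T_L/4, T_L, four at 5T_L/4).  `100·λ(t)²` is the percentage of
  phenotypic variance at day *t* explained by the entry weight.
* Per-animal growth parameters have an animal-model hierarchy; the four
  genetic effect vectors (u_A, u_B, u_K, u_0) are jointly
  N(0, Σ_u ⊗ A) with A the pedigree numerator relationship matrix.
* Writing the system as Λ·Y with Λ unit lower triangular (−λ(t) in the first
  column), |Λ| = 1 exactly, so the likelihood factorizes into simple normal
  densities.

Estimation is by MCMC — Gibbs updates for every conjugate block (including an
exact O(N) joint draw of the genetic effects through an eigendecomposition of
A) and random-walk Metropolis–Hastings for the Gompertz parameters — with a
two-stage empirical calibration of the covariance prior scales, ordinary
growth-curve baselines (entry-day and birth-day time origins), DIC/WAIC/mean
log-likelihood comparison, Gelman–Rubin convergence checks, and a
parametric-bootstrap check of the heritability at slaughter.  A synthetic
data generator draws complete pedigreed studies from the generative model.
See `docs/methods.md` for the full statistical account.

## Worked example

Simulate a progeny-tested herd of 200 animals whose true causal effect
plateaus at 0.8 and dies out around day 620, calibrate the priors on the
preliminary fits, and fit the structural (SGC) and ordinary (GC_A) models:

```python
import numpy as np
from sgcurve import (MCMCConfig, SimulationConfig, calibrate_priors,
                     compare_models, run_mcmc, simulate_sgc_dataset,
                     summarize_fit)
from sgcurve.splines import basis_matrix, decline_extinction_time

cfg = SimulationConfig(n_animals=200)
data, truth = simulate_sgc_dataset(cfg, np.random.default_rng(7))

cal = MCMCConfig(iterations=10_000, burn_in=5_000, thin=10, n_chains=1, seed=2)
priors = calibrate_priors(data, cal)

mcmc = MCMCConfig(iterations=30_000, burn_in=15_000, thin=15, n_chains=2, seed=1)
sgc = run_mcmc("sgc", data, priors, mcmc)
gca = run_mcmc("gc_a", data, priors, mcmc)
for row in compare_models([summarize_fit(sgc), summarize_fit(gca)]):
    print(f"{row['model']:5s}  mean loglik {row['mean_loglik']:10.1f}  "
          f"DIC {row['dic']:10.1f}  WAIC {row['waic']:10.1f}")
```

```
sgc    mean loglik    -4677.8  DIC     9825.4  WAIC     9844.7
gc_a   mean loglik    -4977.4  DIC    10362.0  WAIC    10384.9
```

The structural model wins on every criterion — the data carry a real causal
effect, and the ordinary curve has to absorb it into residual noise.  The
posterior causal-effect curve with its 95% band:

```
day     0: lambda =  0.84  [ 0.77,  0.89]  truth  0.80
day   187: lambda =  0.98  [ 0.86,  1.08]  truth  0.78
day   374: lambda =  0.65  [ 0.49,  0.77]  truth  0.47
day   560: lambda =  0.21  [ 0.01,  0.36]  truth  0.11
day   747: lambda =  0.05  [-0.23,  0.26]  truth -0.01
estimated extinction of the causal effect: day 639 (simulated truth: day 601)
```

Reading: just after entry, each extra kilogram at entry still shows up as
≈0.84 kg (so the entry weight explains ≈ 70% of phenotypic variance); by day
560 the effect has decayed to 0.21 and the zero crossing of its declining
flank — the day the effect disappears — is estimated within ≈ 6% of the
simulated truth.

The same pipeline is scriptable from the shell:

```sh
sgcurve simulate --n-animals 200 --seed 7 --out herd/
sgcurve fit --model sgc --data herd/ --iterations 30000 --burn-in 15000 --out fit_sgc/
sgcurve fit --model gc_a --data herd/ --iterations 30000 --burn-in 15000 --out fit_gca/
sgcurve compare fit_sgc/manifest.json fit_gca/manifest.json
sgcurve curve --fit fit_sgc/ --out lambda.tsv        # posterior curve + 95% HPD band
sgcurve bootstrap --data herd/ --fit fit_sgc/ --replicates 200 --out boot.json
sgcurve nrm --pedigree ped.txt --invert --out ainv.txt
```

Readers and writers cover the study's supplementary-data dialects: dense
weight tables with the 999,999 missing code, fixed-effect design matrices,
1-based sparse triplet relationship-matrix inverses, farm-code and
row-mapping files.

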