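# Methods

## The structural growth curve model

`sgcurve` models longitudinal weights of animals that move from birth farms to
fattening stations.  Time is measured in days since entry to the station; the
entry-day weight is `Y_{i,0}` and later records are `Y_{i,t}`.  The model is a
two-equation structural system:

```
Y_{i,0} = x_{i,0} β₀ + u_{i,0} + v_{1,i} + v_{2,i} + e_{i,0}
Y_{i,t} = Y_{i,0} λ(t) + f(t; A_i, B_i, K_i) + e_{i,t}
```

The first equation is a linear mixed model for the entry weight with fixed
effects (sex, birth year, birth season, standardized entry age), an additive
genetic effect `u₀`, a maternal effect `v₁` (pedigree covariance among dams),
and a reproduction-farm effect `v₂` (iid).  The second equation is a Gompertz
growth curve `f(t) = A·exp{−B·exp(−K t)}` plus a *time-varying causal effect*
of the entry weight, λ(t), realized as a cubic B-spline with N_p = 8 basis
functions on a clamped knot vector: four knots at 0, interior knots at T_L/4,
T_L/2, 3T_L/4 and T_L, four at 5T_L/4 (T_L = last measurement day in the
data).  λ(t)² is the fraction of phenotypic variance at day t attributable to
the entry weight, which is how the curve is interpreted downstream
(`variance_explained` returns 100·λ²).

The per-animal Gompertz parameters carry an animal-model hierarchy: each of
A, B, K is fixed effects (sex, station) + additive genetic effect + residual.
The four genetic vectors (u_A, u_B, u_K, u₀) are jointly N(0, Σ_u ⊗ A) with A
the pedigree numerator relationship matrix; the three growth residual vectors
are N(0, Σ_e ⊗ I).

Writing the system as Λ·Y per animal, with Λ unit lower triangular carrying
−λ(t) in its first column, the Jacobian determinant is exactly 1, so the joint
likelihood is the product of the entry-day normal density and per-record
normal densities of `Y_{i,t} − λ(t)Y_{i,0} − f(t)`.  Full normalizing
constants are kept so likelihood values are comparable across models.

Two ordinary growth-curve baselines share the machinery: GC_A (entry-day time
origin; the entry weight is the t = 0 record) and GC_B (birth-day origin;
record times are shifted by the entry age).  Both drop λ and the entry-day
mixed model, and use a 3×3 genetic covariance.

## Priors and the two-stage calibration

Fixed effects: flat (optionally proper normal for prior-predictive checks).
Scalar variances (maternal, farm, entry residual, trajectory residual, spline
smoothing σ²_p): scaled inverse-χ²(−2, 0), i.e. flat in σ².  Σ_u ~ IW(6, S_u),
Σ_e ~ IW(6, S_e), and the 3×3 GC covariance ~ IW(5, S*_u).  Spline weights:
P₀, P₁ ~ N(0, 1000σ²_p) and P_j ~ N(2P_{j−1} − P_{j−2}, σ²_p) for j ≥ 2 — a
second-order random walk shrinking λ toward straight lines with a vague level.

`calibrate_priors` determines the scale matrices empirically in two stages:
(1) a GC_B fit with the fixed preliminary scales diag(1e4, 0.65, 5e-7) and an
entry-day mixed-model fit (by Gibbs, with the same machinery); (2) S*_u and
S_e are set to the stage-1 posterior means, and the 4×4 S_u is assembled from
the growth-parameter block, the entry-weight genetic variance, and the
empirical covariances between the stage-1 posterior-mean genetic effects
(projected to the nearest positive-definite matrix if needed).  At small N
these empirical covariances are strongly shrinkage-attenuated and their signs
are noisy; they serve as prior scales with only ν ≈ 6 pseudo-observations of
weight, not as estimates.

## Posterior computation

A systematic-scan sampler cycles:

1. **Location effects** (Gibbs): fixed effects from their normal conditionals
   (multivariate regression form for the growth block), maternal/farm level
   effects from MVN conditionals, and the genetic-effect block jointly.  The
   joint 4N genetic draw uses a one-time eigendecomposition A = V D Vᵀ: with a
   residual precision shared across animals, the conditional precision
   Σ_u⁻¹ ⊗ A⁻¹ + R⁻¹ ⊗ I block-diagonalizes in the rotated basis into one 4×4
   problem per eigencomponent — an exact draw in O(N) small solves.
2. **Variance components** (Gibbs): inverse-Wishart conditionals for Σ_u and
   Σ_e, scaled inverse-χ² for the scalar variances.
3. **Growth parameters** (Metropolis–Hastings): univariate Gaussian random
   walks on A_i, B_i, K_i, proposed for all animals simultaneously (animals
   are conditionally independent), with proposals outside the positive
   support rejected.
4. **Spline weights**: by default the whole P block is drawn from its *exact*
   multivariate normal conditional — given the growth parameters the
   trajectory equation is linear in P (regressor S_j(t)·Y_{i,0}) and the
   random-walk prior is Gaussian.  A per-weight random-walk MH update is also
   provided (`MCMCConfig.spline_update="mh"`); it targets the same
   distribution but mixes far more slowly, because the growth parameters
   adapt to the current curve and pin it.
5. **Curve-level ridge move** (MH): the level of λ trades off against the
   per-animal asymptotes (a level shift δ changes predictions by δ·Y_{i,0},
   which A_i absorbs at late times).  A joint symmetric proposal
   (P + δ, A − δ·Y₀) with unit Jacobian traverses this ridge in O(1) moves;
   its acceptance ratio is the exact posterior ratio (verified against a
   brute-force density evaluation in the tests).
6. **σ²_p** from its exact scaled inverse-χ² conditional.

Metropolis scales adapt toward 30% acceptance by a Robbins–Monro recursion
during burn-in only.  Chains are seeded from a deterministic seed sequence;
chain 0 starts from a moment-based initialization (coarse-grid per-animal
Gompertz fits, residual-split genetic effects so no covariance starts in the
absorbing zero state), later chains from overdispersed jitters.  Fixed seeds
reproduce posterior files bit for bit.

Model comparison uses the mean log-likelihood, DIC (deviance at the
observation level, conditional on the latent growth parameters, with the
posterior mean taken per parameter including latents) and WAIC (pointwise
unit = one weight record, variance form of the penalty).  Convergence is
monitored with the classic two-moment Gelman–Rubin R̂ without chain
splitting; values below 1.1 are taken as converged.  Because the DIC focus is
a convention, absolute DIC values are comparable within this package only.

## Synthetic data

`simulate_sgc_dataset` draws every component in the generative direction.
Defaults emulate a Japanese Black progeny-testing population: entry at
251.5 ± 20.4 d of age with mean entry weight 236 kg (random components
499.4 genetic + 49.6 maternal + 219.0 farm + 265.0 residual kg²), slaughter
at 635 ± 47 d after entry near 730 kg, 4.4 ± 0.7 records per animal (clamped
to 1–6) dispersed over the fattening period with the final record at
slaughter, three stations, two sexes, and ~2 animals per reproduction farm.
The pedigree is a discrete-generation progeny-testing design: few sires
(default 15) with large paternal half-sib families and many dams.  Growth
parameters use high heritabilities with the estimated correlation pattern
(A–B positive, A–K and B–K negative).

The true causal-effect curve is parameterized as a plateau (0.8) to day 200,
linear decline, extinction at day 620 — and realized as the least-squares
projection of that template onto the model's own spline basis, since a kinked
curve is not representable by an 8-basis cubic spline and growth biology is
smooth.  By default the entry-weight genetic effect is uncorrelated with the
growth-parameter genetic effects, i.e. all dependence of later weight on the
entry weight flows through the causal path; a residual genetic correlation
can be injected (`default_sigma_u(entry_growth_corr=...)`), with the caveat
below.

What the generator does *not* emulate: station-year measurement calendars
(records are uniform over the fattening period rather than clustered),
selection (matings are random), heterogeneous residual variance over age,
and missing-record informativeness.  Passing recovery tests therefore show
that the estimation machinery inverts its own generative model at the stated
scale — not that every feature of field data is handled.

## The parametric bootstrap

`parametric_bootstrap` re-simulates the weight at slaughter from a fitted
parameter state (all random components redrawn: genetic effects from
Σ̂_u ⊗ A, maternal/farm effects, growth parameters from their hierarchy,
fresh residuals; λ̂ evaluated at each animal's slaughter day), refits a
single-trait animal model (sex and station as fixed effects, standardized
slaughter age as a covariate) by Gibbs, and collects the heritability
posterior means — 1000 replicates by default, with mean, SD and the lower 5%
quantile reported against the observed-data heritability.

## Numerical choices and scaled-down study sizes

- Relationship matrices are built by the tabular method and inverted densely;
  inverses are emitted (and read) as 1-based sparse triplets.
- Genetic effects are sampled only for phenotyped animals using the NRM
  submatrix — the exact marginal of N(0, Σ ⊗ A) on a subset.
- B-spline evaluation is half-open on [0, 5T_L/4); evaluation at the right
  boundary is an error.
- The improper χ⁻²(−2, 0) prior requires n > 2 observations per variance;
  this is checked and raised, never silently patched.
- Negative effective-parameter counts (pD, pWAIC) are warned about, never
  clipped.
- Test-suite study sizes are chosen to exercise the full pipeline within a
  package-test budget: the λ-recovery experiments run N = 300 animals with a
  20k-sweep calibration stage and 2–3 chains × 60k sweeps; the model-ordering
  experiment runs 12 replicates at N = 60; the bootstrap null check runs
  N = 1200 with 8 replicates.  The offline `scripts/full_analysis.py` runs
  the published schedule (2.5M/1M iterations, 3 chains) on the real
  supplementary data files.

## Known limitations

- **λ-level vs genetic-covariance ridge.**  A level shift of λ(t) is nearly
  exchangeable with a covariance between the entry-weight and asymptote
  genetic effects; the contrast that separates them (non-genetic components
  of Y₀ propagate only through λ) grows with pedigree information.  At
  N ≈ 300 the posterior resolves the ridge but a residual level uncertainty
  of a few hundredths remains; with an injected u₀–growth genetic
  correlation and a weak pedigree, λ is close to unidentified.
- **Direct–maternal confounding.**  The entry-day decomposition into direct
  genetic, maternal, farm and residual variance is weakly identified at
  desk-scale N (dams are related to the phenotyped animals); posterior means
  of σ²_u0 are strongly attenuated.  Tables of entry-weight variance
  proportions should only be interpreted from full-scale fits.
- **Near-saturated trajectories.**  With ~4.4 records per animal and three
  Gompertz parameters, individual curves are almost saturated; all
  identification of λ flows through the hierarchy, which makes the posterior
  sensitive to the covariance priors — the motivation for the two-stage
  calibration.
- DIC/WAIC absolute values depend on the latent-conditional likelihood focus
  and are not comparable to implementations with a different focus.
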