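# Methods

## The model

`starpanel` fits structured additive regression (STAR) models to complete
county × year panels of standardized health-indicator rates. Counties
c = 1, …, C are linked by an adjacency graph; years t = 1, …, T are
consecutive. The observed rate per 100,000 is transformed to

    y_ct = log((rate_ct + offset) / 100,000),

with a small positive `offset` (default 0.5 per 100,000) keeping zero
county-year rates finite. The likelihood is Gaussian,
y_ct ~ N(η_ct, σ²_e). Effects on η are therefore log relative risks: a
coefficient β multiplying a covariate x means a multiplicative rate change
exp(β·Δx). The Gaussian-log-rate family is a package design choice —
directly standardized rates are continuous and their county-level effects
are naturally read on the log-RR scale; a count likelihood with a
population offset would be the alternative for raw case counts and is out
of scope.

Two model kinds share one backbone:

* **Varying-coefficient model (VCM)**

      η_ct = α + x1_ct·β1_t + x2_ct·β2_t + f(t) + s_c + u_c

  β1, β2 are T-vectors of time-varying effects with second-order
  random-walk (RW2) smoothness priors: the penalty K = D2′D2 charges
  squared second differences, leaving the level and the linear trend of
  the trajectory unpenalized (diffuse start values — a partially improper
  prior of rank T−2).

* **Random-effects model (REM)**

      η_ct = α + x1_ct·b1_c + x2_ct·b2_c + f(t) + s_c + u_c

  b1, b2 are C-vectors of county-specific slopes with exchangeable normal
  priors N(0, τ²); reduced variants drop either or both slope blocks for
  model comparison.

Shared blocks: f(t) is a P-spline time smoother (cubic B-spline basis on
the year grid with an RW2 penalty on its coefficients); its role is to
absorb serial correlation in the panel. The spatial effect is split
Besag-York-Mollié-style into a *structured* term s_c with an intrinsic CAR
prior — conditional on its neighbours, s_c is normal with mean the
neighbour average and variance σ²_str/N_c — and an *unstructured*
exchangeable term u_c ~ N(0, σ²_unstr). Every variance component gets an
inverse-gamma (a, b) = (0.001, 0.001) hyperprior (including σ²_e, for
uniform treatment); the intercept is flat.

## Identifiability

Partially improper priors leave the predictor aliased; sum-to-zero
constraints restore a unique decomposition: Σ_t f(t) = 0, Σ_c u_c = 0, and
Σ s_c = 0 within every connected component of the graph. Islands (no
neighbours) have an undefined CAR full conditional; their s_c is fixed at
0 and the county relies on u_c (a warning is logged). Constraints are
enforced by centering each Gibbs draw — valid in coefficient space for the
spline because a partition-of-unity basis shifts its fitted values by the
same constant — and the intercept absorbs the freed level at its next
update.

Two aliasing facts are worth knowing when reasoning about the *design*
rather than the posterior:

* s and u share the county-indicator design, so only s + u is
  likelihood-identified; the split is resolved by the priors (spatially
  smooth vs independent), as in any BYM-type model.
* if a covariate is time-constant per county (the default for the
  deprivation index), the *level* of its time-varying coefficient is
  likelihood-confounded with the county effects; the RW2 and spatial
  priors resolve it. With both covariates varying in time, the constrained
  design (county blocks merged) has full column rank.

## Sampling

A fixed-sweep block Gibbs sampler: intercept, each coefficient block,
each variance component, then σ²_e. Every Gaussian block has full
conditional N(P⁻¹X′r/σ²_e, P⁻¹) with P = K/v + X′X/σ²_e, drawn via a
dense Cholesky factorization (block dimensions are at most C ≤ 200, where
dense is faster than sparse). Variance components are conjugate
inverse-gamma with shape a + rank(K)/2 — the rank, not the dimension,
because RW2 and CAR penalties are rank-deficient — and rate
b + ½·θ′Kθ; σ²_e uses a + n/2 and the residual sum of squares. Draws are
floored at 1e−12 to guard numerical collapse (logged). Initial state:
α at the response mean, all blocks at zero, variances at 0.1. Each block
consumes its own RNG substream spawned from the chain seed, so runs are
bit-reproducible; a split-chain potential-scale-reduction helper is
provided for multi-seed checks but no threshold is asserted anywhere.

Default schedule: 22,000 iterations, 2,000 burn-in, every 20th draw kept —
1,000 retained draws.

## Reported quantities

* posterior means and equal-tailed 95% credible intervals per parameter;
* DIC = D(θ̄) + 2·p_d in the additive form D(θ) + p_d, with D(θ) the
  posterior mean deviance (−2 × Gaussian log-likelihood) and
  p_d = D(θ) − D at the posterior means (the plug-in variant; the additive
  identity holds by construction);
* ρ = σ²_str/(σ²_str + σ²_unstr), the structured share of spatial
  variance, reported to two decimals;
* the 80% posterior-probability rule: a county's spatial effect is
  significantly positive (negative) when ≥ 80% of its posterior mass is
  above (below) zero, with strict ≥ at the boundary, else nonsignificant;
* quintile map bins at the 20/40/60/80 percentiles, ties to the lower bin;
* relative-risk transforms: both the mean of exp(draws) (for county RR
  maps) and exp(mean) (for area summary tables) are reported, since the
  two differ under skew;
* percent change of a time-varying effect, 100·(start − end)/start, and
  flagged-county shares, both to one decimal.

## Upstream steps

**Direct standardization.** Stratum-specific rates (cases/population in
age-group × race cells; default scheme 5-year age groups 40–85+ crossed
with race) are combined with fixed standard-population weights and scaled
to per-100,000. Zero-population strata are dropped with renormalization of
the remaining weights (sparse rural county-years make this routine) and a
warning. When the standard weights equal the county-year's own population
shares the standardized rate equals the crude rate — an algebraic identity
used as a test oracle.

**Deprivation index.** One common factor is extracted from a county ×
variable census table (default six items: no high-school education,
unemployment, crowded housing, no car, no telephone, below poverty) by
iterated principal-axis factoring on the correlation matrix (delegated to
statsmodels; `method="ml"` available). Loadings are sign-oriented so
deprivation items load positively; counties are scored by the regression
method and standardized to mean 0, sd 1 (higher = more deprived).
Reliability is Cronbach's alpha on the raw items; stability across census
periods is the Pearson correlation of the two score vectors. The choice of
items is editorial and accepted as given; scoring by regression weights is
a package decision (a plain weighted sum is a close cousin).

## Synthetic data

The generators draw from exactly the models the samplers fit, with known
truth, sized to the study setting the package targets: ~200 counties in 9
mutually disconnected areas (rook-adjacency lattice bands, a small island
fraction), T = 21 years; x1 log-normal with median ≈ 60 per 100,000 and
mild yearly variation, divided by 1,000 before fitting; x2 a standardized
time-constant score generated independently of x1 (their empirical
correlation is near zero); β1 declining linearly 3.72 → 2.45 and β2 rising
−0.25 → 0 across the period; a small centered sinusoidal f(t);
σ²_str = 2.26, σ²_unstr = 0.56 (structured clustering dominant), and
σ²_e = 0.05 (log-scale residual sd ≈ 0.22, a realistic roughness for
adjusted county rates; no reference value exists for this one).
The CAR field is drawn from the intrinsic prior restricted to its row
space, centered per component.

What the generators do *not* emulate: registry case-listing artifacts,
age-race composition drift, covariate measurement error, missing
county-years, and any space-time interaction (the model family itself has
none). Passing recovery tests therefore demonstrate correctness of the
machinery under the model's own assumptions, not robustness to real-data
violations of them.

## Problem sizes and numerical choices

Test and validation runs use deliberately scaled problems chosen as good
statistical practice for repeated-fit experiments: recovery experiments
use a 36-county lattice (two components, ~5% islands), T = 21, chains of
4,400 iterations (400 burn-in, thin 4), 50 replicate fits; the
end-to-end ρ-signature check uses 8 replicates at 1,100 iterations.
Coverage of the 95% CIs for the β1 trajectory across the 50 replicates
falls in the high-90s — wide intervals are expected because a covariate
whose variation is mostly cross-sectional competes with the county
effects, so the effect is informed mainly by within-county temporal
variation.

Other numerics: spline default degree 3 with 18 knot intervals on [1, T]
(basis dimension 21 at T = 21; ≈ one knot per year), exposed in config;
percentile intervals use linear interpolation; quintile ties go down;
variance floor 1e−12; Cholesky solves use LAPACK via scipy with
`check_finite` off. Degenerate inputs (negative rates, incomplete panels,
asymmetric adjacency, burn-in ≥ iterations, both spatial variances zero)
raise errors naming the offending object rather than propagating NaNs.

## Known limitations

* No space-time interaction terms; geographic variation of *temporal*
  trends is out of reach by construction.
* Gaussian likelihood only; no count model for small-population counties.
* DIC is the only model-comparison criterion (no WAIC/LOO).
* Single-chain fits by default; convergence assessment is left to the
  user via replicate seeds and the provided R-hat helper.
* The factor model extracts exactly one factor; no rotation or
  multi-factor structure.
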