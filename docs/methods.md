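# Methods

This note records the models, estimation procedures, numerical choices and
limitations behind `twinstable`. It is written for users who want to know
exactly what is computed and what the simulation-based tests do and do not
demonstrate about real cohort data.

## Study design emulated by the generator

The synthetic cohort reproduces a semilongitudinal classic twin design:
44 monozygotic (MZ) and 20 dizygotic (DZ) same-sex pairs — 128 individuals
— each measured at 3 visits over two months, with 400 analyzed 0.02-ppm
spectral bins per sample. Covariates: age in years (truncated normal,
mean 35, SD 13, range 18–65, shared exactly within a pair), sex (balanced
Bernoulli, shared within a pair), fat-free mass in kg (normal, mean 52,
SD 8 — consistent with a cohort of mean body mass 70.4 kg and ~26% body
fat) and HEI-2015 diet-quality score (normal, mean 60, SD 12, on the 0–100
scale). FFM and HEI are drawn per individual with within-pair correlation
0.5 (MZ) / 0.25 (DZ); the source cohort does not report these correlations,
so they are a configurable stand-in chosen to make familial confounding of
the covariate-adjustment stage realistic.

### Per-bin forward model

Each bin follows a longitudinal ACE model: lower-triangular path matrices
`a`, `c`, `e` (visits × visits) load latent standard-normal factors, giving
within-person covariance `aaᵀ + ccᵀ + eeᵀ`, MZ cross-twin covariance
`A + C` and DZ cross-twin covariance `0.5·A + C` (A = aaᵀ, C = ccᵀ). Latent
draws are multivariate normal — defensible because the analyzed scale is
post-Johnson-transform, i.e. approximately Gaussian by construction. The
random stream is split hierarchically (cohort / bin / noise) so adding bins
never perturbs cohort draws, and every function takes an explicit seed.

The default 400-bin mixture draws each bin's true ICC from a normal
centred at 0.39 with SD 0.15 (clipped to [0.02, 0.9]); with estimation
noise at 128 individuals the *estimated* ICC distribution then matches the
reported urinary profile (median ≈ 0.39, SD ≈ 0.17, ≈ 20% of bins at or
above the 0.51 cutoff — a seed-1 run gives 78/400 = 19.5%). The stable
portion of each bin's variance is split between a persisting genetic
factor, a persisting shared-environment factor and persisting unique
environment (between-visit correlation 0.95 for A and C); the remainder is
visit-specific unique environment. Total variance is 1 per bin.

### Spectrum synthesis

`simulate_spectra` renders bin values as triangular peaks (half-width
0.008 ppm, fully contained in one 0.02-ppm window) on a 0.0005-ppm grid
whose nodes include all bin edges and peak vertices, so trapezoidal
re-integration recovers the inputs exactly at zero noise. Gaussian
intensity noise is added pointwise and clipped at zero. This is a fixture
generator: no Lorentzian lineshapes, chemical-shift drift, or baseline
artifacts.

## Preprocessing

Bins are labeled by center `c` and cover `[c − 0.01, c + 0.01)` ppm; the
0–10 ppm axis yields 500 bins, and the default excluded window
[4.50, 6.50) ppm (water/urea region) removes exactly 100, leaving the 400
analyzed bins. The exclusion window is fully configurable because the
precise excluded region is a processing choice, not a property of the
method. Each sample is normalized to its total retained spectral integral
(rows sum to 1), then each bin is transformed toward normality across
samples.

The Johnson transformation is fitted by the Slifker–Shapiro percentile
method: empirical quantiles at normal deviates ±z and ±3z with z = 0.524
select the family (S_U if mn/p² > 1, S_B if < 1, S_L at the boundary) and
give closed-form parameters. When the percentile fit is numerically
invalid, leaves |skewness| ≥ 0.5 or |excess kurtosis| ≥ 1, or the data are
heavily tied (fewer than half the values distinct), the transform falls
back to the rank-based inverse normal with Blom offsets, with a logged
warning. All variants are strictly monotone on distinct values; constant
input or fewer than 8 distinct values is an error.

## Variance decomposition

The two-level random-intercept model (individual within family) is fitted
by maximizing the Gaussian likelihood profiled over the fixed effects
(GLS), with analytic gradients in the three variance components and
non-negativity enforced by bounded L-BFGS-B — a boundary estimate is a
genuine constrained optimum, not a post-hoc truncation. Families are
grouped by identical block shape so the per-iteration algebra is batched;
unbalanced visit counts are handled per family (complete-case per bin,
individuals need ≥ 1 visit). Both REML (default for reported components
and ICC) and ML objectives are available; the REML estimates agree with
statsmodels' variance-components MixedLM to 3–4 decimals (cross-checked in
the test suite), and ML estimates agree with a brute-force likelihood grid
(step 0.01) on balanced 16-family instances to within 0.02 per component.

Covariate ANOVA uses likelihood-ratio tests of ML fits (full model vs
dropping one covariate, χ²₁); an F-test would be a reasonable alternative
but the LRT pairs naturally with the ML machinery. Benjamini–Hochberg
adjustment is applied across the joint bins × covariates family by default
(per-covariate families via config), significance at q < 0.05. For each
bin, significant covariates are retained as fixed effects and the reported
ICC comes from that refit's residual components.

The proportion of variance attributable to a covariate is defined as
var(β_c·x_c) / (var(full fixed-effect predictor) + σ_B² + σ_F² + σ_W²) × 100
— a marginal-R²-style ratio. The source description of this quantity is
incomplete, so this definition is a package choice; it reproduces the
intended behavior at both extremes (pure signal → 100%, independent
covariate → ≈ 0%).

## Stability classification

Bands partition [0, 1]: poor [0, 0.40), fair [0.40, 0.51),
good [0.51, 0.75), excellent [0.75, 1]. The printed band edges leave
[0.74, 0.75) formally unassigned; assigning it to "good" preserves the
partition. The stable set is every bin with ICC ≥ 0.51, ordered by
descending ICC with ties broken by bin label.

## Longitudinal Cholesky ACE model

The joint MZ + DZ multivariate-normal likelihood is maximized over the
three path matrices plus a mean model (per-visit intercepts; age and sex
as pair-level mean covariates only — they never enter the covariance
model). The likelihood is evaluated from per-zygosity sufficient
statistics, so its cost is independent of the number of pairs. Numerical
choices:

- L-BFGS-B with up to 5 restarts (data-driven start from moment estimates
  of A = 2(R_MZ − R_DZ), C = 2R_DZ − R_MZ, E = V − A − C, eigenvalue-floored
  and Cholesky-factored; subsequent starts are seeded perturbations).
- The DZ additive coefficient is fixed at 0.5 (classic twin assumption);
  no dominance pathway.
- Cholesky column signs are indeterminate; columns are flipped after
  fitting so diagonals are non-negative (AAᵀ etc. unchanged).
- Complete pairs only; families with a missing co-twin or visit are
  dropped with a logged count.

Standardization divides each path by the implied SD of its visit row and
squares it; the squared standardized A, C, E entries of each visit sum to
1 by construction (asserted to 1e-6).

Assumption checks are likelihood-ratio tests against the unstructured
saturated model: equality of means across twin order (free covariances),
equality of means across zygosity, and equality of per-visit SDs across
order and zygosity (correlations left free, means at sample means). With a
single zygosity group the zygosity tests are skipped with a warning.

**Confidence intervals** are profile-likelihood on the squared
standardized scale: the model is refitted under an equality constraint on
the target coefficient (SLSQP), and the bound solves LRT(t) = χ²₁(0.95) by
bracketing + Brent's method, clipped to [0, 1]; a coefficient estimated at
0 gets a one-sided interval with lower bound exactly 0. Simulated coverage
for the standardized A proportion at 500 + 500 pairs is ≈ 95–96%
(200-replicate check in the acceptance suite).

**Power simulation** generates univariate twin samples with specified
standardized (A, C, E) proportions, fits ACE and CE by ML, and tests A = 0
with the 50:50 χ²₀/χ²₁ boundary mixture (plain χ²₁ selectable). The
mixture reference is exact only asymptotically with C in the interior: at
small samples or with C on its own boundary the test is conservative
(empirical size ≈ 0.05 at 500+500 pairs with C = 0.3; below 0.05 at 64
pairs). At the design size of 44 MZ + 20 DZ pairs, a true additive
proportion of 0.77 with no shared environment is detected with ≈ 88–92%
power at α = 0.05 (500 replicates), consistent with the design being
powered at 80% for A ≥ 0.77.

## Conservation indices

Profile correlations are computed on the transformed bin scale, matching
the pipeline order. The weighted variant uses weighted means, variances
and covariance across bins inside the Pearson formula; weights are
covariate-adjusted longitudinal bin correlations (both time points
residualized on age, sex, FFM and HEI before correlating), clipped at
zero because a negative test–retest correlation carries no conservation
signal. Ranking uses average ranks on ties (ties have probability zero on
continuous data but occur in tests). Bands: "1.00" means index exactly 1,
then [0.90, 1), [0.70, 0.90), [0, 0.70) — a partition.

## What passing simulations do and do not show

The generator draws bins independently of one another. Real NMR profiles
have strong cross-bin dependence (several bins per metabolite, correlated
pathways, compositional coupling from total-integral normalization), which
makes interindividual profile correlations widely dispersed in real
cohorts. With independent bins, interindividual correlations concentrate
near zero, so nearly every simulated individual ranks first against their
own follow-up and conservation indices pile up at 1.00. Conservation
tests therefore verify the correlation, ranking, weighting and band logic
— not any particular cohort's band mix. Likewise the variance and SEM
recovery tests demonstrate estimator correctness under the generating
model, not robustness to non-Gaussian or drifting real spectra.

## Problem sizes in the test and acceptance runs

Simulation-based checks use sizes chosen to balance Monte-Carlo precision
against runtime: cross-twin covariance checks at 2000 pairs/group;
Cholesky recovery at 2000 + 2000 pairs; CI coverage with 200 replicates at
500 + 500 pairs; FDR calibration with 12 replicates of the full
400-bin × 4-covariate null; power at 500 replicates. The default pipeline
models the top 10 stable bins with the Cholesky ACE model (the headline
longitudinal table reports the ten most stable regions) and skips profile
CIs unless `sem_ci = profile` is set, since profiling all 18 coefficients
of a trivariate fit is an order of magnitude more expensive than the fit
itself.

## Known limitations

- No dominance (ADE), sex-limitation, or cross-bin multivariate models.
- The preprocessing stage consumes already-tabulated spectra; phasing,
  baseline correction and reference alignment are out of scope.
- The mixed model supports exactly one family level and random intercepts
  only (no random slopes), and Gaussian outcomes only.
- The SEM engine is n-visit generic but output formatting targets 3 visits.
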