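# Methods

This note documents the models, numerical choices and study conditions
behind `ibrkit`, and what its synthetic-data validation does and does not
establish about real data.

## Resistance-surface parameterization

A covariate raster enters the pipeline as a strictly positive resistance
surface. Covariates whose high values facilitate gene flow are reversed
first (`max − value + 0.1`); the 0.1 floor guarantees no zero-resistance
cells, which the circuit solver requires.

Two exponential transformations shape the response to resistance:

* **high**: `f(R) = exp(α · R / R_max)`. Convex and rank-preserving:
  low-resistance cells are compressed toward 1, differences among
  high-resistance cells are amplified, the maximum maps to `exp(α)`.
  Normalizing by the surface maximum makes the transform invariant to the
  covariate's native scale.
* **low**: reverse, apply the same exponential, reverse back, add 0.1.
  Monotone increasing but concave: variation among favourable cells is
  amplified instead. A constant input is defined to map to the constant 0.1.

α controls steepness; the standard family uses α ∈ {5, 10}. The exponential
form itself was fixed from its documented properties (exponential in R,
α-steepness, R_max normalization, low-value homogenization); for the low
transformation, the inner maximum is taken over the reversed surface.

Each transformed surface is then averaged over a circular focal window
(radius 1.5, 6.44 or 17.33 km — short-range habitat-selection scales and a
dispersal-distance scale), giving 5 × 3 = 15 variants per covariate. The
window sizes are treated as radii and are configurable. Transformation
precedes windowing. Near edges and nodata cells the focal mean uses the
available cells only. Road-style covariates use the distance decay
`exp(−d/α)` with α = 0.564 km and no windows (5 variants).

## Circuit-theory effective resistance

The raster is a resistor network: unmasked cells are nodes; 8-connected
neighbours (4-connectivity available) are joined by a resistor of
`(r_a + r_b)/2`, scaled by √2 for diagonals. Pairwise effective resistance
solves the Kirchhoff system with one node grounded, one sparse LU
factorization shared across all pairs; the batched result equals per-pair
solves by linearity. Focal groups are represented by the single cell at
their coordinates; coincident cells are an error naming the groups, and
focal nodes in different graph components raise a connectivity error rather
than returning infinities. For sensitivity analysis of the point-vs-region
choice, `focal_buffer` short-circuits every cell within a radius of each
group into one region node (internal resistance zero, parallel conductances
summed); by Rayleigh monotonicity this can only lower pairwise resistances.
A dense pseudoinverse route
(`effective_resistance_dense`) exists purely as a test oracle; it uses a
symmetric eigendecomposition with an explicit 1e-12 relative cutoff because
the default singular-value threshold can drop small physical eigenvalues of
heterogeneous networks.

## Genetic differentiation

Estimators are frequency plug-ins (no small-sample correction by default;
a Nei-1987 unbiased H_S/H_T correction is available via `unbiased=True`), so
worked examples are exact. Missing genotypes are excluded per locus
(pairwise-available); no imputation. Multilocus aggregation:

* **G_ST**: per pair and locus, H_S is the mean within-group expected
  heterozygosity and H_T the expected heterozygosity of the mean allele
  frequencies; the multilocus value is `(mean H_T − mean H_S)/mean H_T`
  with unweighted means across loci.
* **Jost's D**: per locus `D = (H_T − H_S)/(1 − H_S) · 2` (two groups);
  across loci the default is the arithmetic mean, the convention of the
  standard differentiation packages. The harmonic mean (Jost's own
  suggestion) is available via `aggregation="harmonic"` but is dominated by
  the noisiest near-zero locus on short panels — on a 14-locus synthetic
  panel it destroys the otherwise strong G_ST–D_est agreement (r ≈ 0.94
  arithmetic vs ≈ 0.59 harmonic), which is why it is not the default.

Allelic richness is rarefied by repeatedly subsampling individuals (default
10 individuals, 1000 replicates, seeded), counting distinct alleles per
locus and averaging across loci; mean and SD over replicates are reported.
Subsampling whole individuals (not gene copies) keeps the unit consistent
with the group definition.

## The MLPE mixed model

`y = Xβ + Zu + ε` over (i<j) pairs, with Z carrying a 1 for each of a row's
two member groups (plain multiple membership), `u ~ N(0, σ_u² I_G)`,
`ε ~ N(0, σ_e² I)`. Predictors are standardized by centering and dividing by
2 SD (Gelman's convention, making slopes comparable with binary predictors;
`n_sd=1` gives classical z-scores). Constant predictors are an error naming
the column.

**REML.** β is profiled by GLS and σ_e² analytically, leaving a bounded 1-D
search over `log γ`, `γ = σ_u²/σ_e²` (γ ∈ [e⁻¹⁵, e¹⁰], Brent-style bounded
minimization, xatol 1e-10), with the γ = 0 boundary checked explicitly. All
solves use the Woodbury identity on the G×G scale, so a fit costs a few
dozen small Cholesky factorizations. At γ = 0 the fit reproduces OLS
exactly (REML residual divisor); `fix_gamma` pins the ratio for oracle
tests. Non-convergence of the scalar search is flagged on the fit, never
silent. The REML criterion matches lme4's (verified against an independent
mixed-model implementation to ~1e-6).

**MCMC.** A Gibbs sampler on the conjugate parameterization: (β, u) drawn
as one joint Gaussian block (this removes the intercept–group-mean random
walk that plagues separate updates), then inverse-gamma draws for both
variances. Priors: flat on β, IG(0.001, 0.001) on σ_u² and σ_e² (weakly
informative; with no group variance in the data the σ_u² posterior
collapses toward 0). At least two chains are enforced, started from
jittered OLS states; their posterior means are compared against 3× the
combined autocorrelation-adjusted Monte-Carlo SE, and disagreement sets a
flag and warns. Credible intervals default to quantile; HPD is available
(`method="hpd"`).

**Criteria.**

* `AICc = −2ℓ_R + 2k + 2k(k+1)/(n−k−1)`, k counting intercept, slopes and
  both variance components. REML information criteria across different
  fixed structures are statistically contested; they are computed because
  the workflow uses them, and the consensus rank dilutes any one criterion.
* `DIC = D̄ + pD`, conditional (on u) Gaussian deviance over pooled
  post-burnin draws, `pD = D̄ − D(posterior means)`; negative pD — a known
  pathology — is reported with a warning.
* `R²_β = (q/ν)F / (1 + (q/ν)F)` with the Wald F for all slopes.
  Denominator df: Satterthwaite by default (per-eigencontrast df from the
  REML-information covariance of the variance components, combined as in
  lmerTest), or `residual` (n − p). A true Kenward–Roger small-sample
  covariance correction is not implemented — its correction terms are
  second order for this balanced pairwise design, and the σ_u² = 0 identity
  with OLS R² pins the implementation; requesting it raises with a pointer
  to Satterthwaite.
* `R²_m = σ_f²/(σ_f² + σ_u² + σ_e²)` with σ_f² the variance of the
  fixed-effect fitted values (variance-ratio marginal R²; σ_u² enters once,
  matching how the component is reported by the fitting software the
  workflow emulates).

## Model selection

Models are ranked per criterion (ascending for AICc/DIC, descending for
both R²; ties get average ranks); the consensus value is the mean of the
four ranks and the agreement estimate their SD. A model with a missing
criterion keeps NaN ranks and an `incomplete` flag rather than being
dropped. Winners are the lowest mean rank, ties broken by lower AICc, then
fewer predictors. The undifferentiated null (UNDIF) is the intercept-plus-
random-effects model — no slope enters the design. The default multivariate
set is the 22-model dispersal-hypothesis set over three seasonal habitat
indices and five landscape components; custom sets are declarative lists of
predictor tuples. Variants whose resistance network is disconnected are
dropped from the univariate screen with a warning. Resistance matrices are
computed once per variant and passed as a cache between stages.

## Combined surfaces

For a multivariate winner with same-sign standardized slopes, each
variable's weight is `β_i / Σβ_j` (intercept excluded) and the combined
surface is the cellwise weighted sum of component surfaces of one
transformation family; mixed-sign or zero coefficients are an error, since
the recipe is undefined there, rather than an absolute-value convention.
Combination operates on transformed pre-window surfaces, with the winning
window applied afterwards (configurable); surfaces from different
transformation families (e.g. high5 with high10) cannot be mixed.
Validation closes the loop: circuit distances on the combined surface are
fitted univariately and the criteria row is rank-compatible with the model
tables.

## Synthetic data: what it emulates, and what it does not

* **Landscapes** are stationary Gaussian random fields with exponential
  covariance `exp(−d/range)`, generated by circulant embedding (exact up to
  clipping of negative spectral mass) and rescaled linearly to a value
  range. Defaults: 300-m cells, 5-km correlation range — a
  percent-cover-like layer. Real covariates are non-Gaussian, anisotropic
  and patchy (roads especially); none of that is emulated.
* **Genotypes** follow a Balding–Nichols Dirichlet drift model: flat
  Dirichlet ancestral frequencies per locus, group frequencies Dirichlet
  with concentration `p̄(1−F)/F`, genotypes as two independent draws,
  calls masked completely at random (default 2%). Expected F_ST ≈ F, so
  differentiation is tunable; there is no spatial pedigree, linkage or
  mutation model. Defaults emulate a 14-locus microsatellite panel over 37
  groups.
* **Pairwise responses** are drawn directly from the MLPE generative model
  on standardized resistances. This is the assumed covariance structure, so
  recovery tests validate the estimator, not the biological claim that
  genetic distance is linear in resistance.

Because the source study's rasters and genotypes are not deposited,
validation is property- and simulation-based: passing tests show the
estimators are correct and the selection machinery recovers known truths
under the assumed model at desk scale — not that any particular landscape
drives gene flow.

## Study conditions of the validation experiments

Fixed in `ibrkit.experiments` and used by both the test suite and
`scripts/acceptance.py`:

* **Circuit oracle**: 50 random lognormal rasters up to 20×20, alternating
  4/8-connectivity, 3 node pairs each, sparse vs dense to 1e-8 relative.
* **MLPE recovery**: one 40×40 (1-km cells) landscape, 30 groups, true
  slope 0.5, σ_u = 0.2, σ_e = 0.1; 500 response replicates; mean slope
  bias and 95%-interval coverage.
* **REML/MCMC agreement**: same conditions, 10⁴ post-burnin draws × 2
  chains, DIC compared across two independently seeded runs.
* **End-to-end selection recovery**: 20 replicates of two 40×40 landscapes
  (1-km cells — chosen so the fixed window radii remain distinguishable on
  a 40-km extent; the generator default stays at 300 m), 15 groups,
  generative variant high-10/1.5-km, univariate slope 1.0 and multivariate
  slopes (0.7, 0.7) with σ_u = σ_e = 0.1. These effect sizes are invented —
  no empirical generative model links differentiation to resistance — and
  were fixed once as "strong-signal" conditions. Screen and model-set fits
  use shortened Gibbs chains (1500 iterations, 500 burnin, 2 chains), which
  is ample for DIC *ranking* at 105 pairs.

## Known limitations

* GeoTIFF I/O is not provided; rasters are ESRI ASCII grids (any GIS
  converts losslessly).
* Gaussian responses only; no least-cost paths, current maps or corridor
  products.
* REML-based AICc comparisons across fixed structures inherit the known
  conceptual objection; the consensus rank is the mitigation, not a fix.
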