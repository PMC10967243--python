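# Methods

This note documents the models, the synthetic-data assumptions, the
numerical choices and the known limitations of `stemtherm`.

## Growth-curve smoothing and QMER phenology

Plot height series are smoothed with penalized B-splines: cubic basis on a
uniformly extended knot grid (one interior knot per ~3 days of span, capped
near the number of observations), a second-order difference penalty on the
coefficients, and monotonicity enforced by a large asymmetric quadratic
penalty (weight 1e6, at most 50 reweighting iterations) on negative
coefficient first-differences — non-decreasing coefficients are sufficient
for a non-decreasing cubic B-spline.  The uniform (not clamped) knot
extension matters: it keeps straight lines exactly in the penalty's null
space, so linear growth is reproduced without boundary shrinkage.  The
smoothing parameter is selected by generalized cross-validation over a
log-spaced grid (1e-3..1e5), with the monotonicity penalty active during
selection.

Phenology uses the quarter-of-maximum-elongation-rate (QMER) rule on an
hourly evaluation grid: `tPHstart` is the first grid time at which the
spline derivative reaches 1/4 of its peak, `tPHstop` the last.  If the
criterion is already met at the first (last) grid point, the event precedes
(follows) the observation window and is reported as undetermined with a
reason code — reporting the window edge would masquerade as a biological
event; in practice this is what happens in seasons without pre-jointing
measurements.  `PH_max` is the median of the top 24 post-`tPHstop` grid
predictions; on the hourly grid those are one day's worth of predictions.
The grid resolution and edge rules are conventions of this package.

## Asymptotic temperature dose-response

The hourly elongation rate is an asymptotic-regression curve,
`r(T) = r_max (1 - exp(-exp(lrc)(T - T_min)))` for `T > T_min` and 0
otherwise (continuous at `T_min`).  Height accumulates over whole hours:
hour h covers [h, h+1) in days since sowing and is credited at its recorded
temperature; the single mm-to-m conversion happens in the accumulation.
Parameters and units: `T_min` degC (bounds [-5, 15]), `r_max` mm/h
((0, 3]), `lrc` log rate constant ([0, 6]), `H0` m (height at window
start, bounded to the minimum observed height +-0.30 m).  The likelihood is
i.i.d. Gaussian on the observed heights with the residual SD profiled
analytically.

Numerically, the model is linear in `(H0, r_max)` once `(T_min, lrc)` is
fixed, so those two are profiled by least squares and the optimizer works
on the 2-D `(T_min, lrc)` surface only: a 25 x 13 deterministic grid scan,
Nelder-Mead refinement from the best grid points plus seeded
Latin-hypercube starts (8 by default), and simplex restarts from the
incumbent.  On noise-free data this recovers the generating parameters to
numerical precision.  The objective is evaluated in mm^2 to keep it well
scaled.

Weak-identifiability diagnostics follow the temperature distribution in the
fitting window: `T_min` is flagged when fewer than 5% of in-window hours
fall below `T_min + 1` degC, `lrc` when fewer than 5% of hours sit in the
curved region (rate between 10% and 90% of `r_max`).

An important, measured limitation: when the true response is steep
(`lrc ~ 3`, i.e. a rate constant of ~20 /degC), the rate curve is nearly a
step function of temperature and the profiled likelihood is flat in `lrc`
over roughly [2, 6].  Single-plot `lrc` estimates are then unstable —
typically piling at the bounds — regardless of the optimizer, because
almost no hours fall inside the ~0.15 degC transition band that carries
information about the curvature.  `T_min` and `r_max` remain well
determined.  This mirrors the general difficulty of quantifying temperature
response parameters precisely from field data and is the reason the
pipeline leans on multi-year aggregation for `lrc`-like traits.

The fit window in the pipeline is `[tPHstart - 3 d, tPHstop + 3 d]` from
the QMER step, with `H0` estimated and accumulation starting at the window
start.  A window wider than the true phase makes the model accrue growth
during hours the plant was not elongating; the 3-day pad keeps that bias
small while tolerating QMER error.  Recovery benchmarks fit with the window
equal to the true phase so that they measure estimator error, not window
error.  The linear benchmark (`lm_slope`) regresses interval growth rates
(mm/h) on interval mean hourly temperatures by OLS.

## Stage-wise mixed models

The REML solver handles arbitrary fixed designs, random terms with optional
known relationship matrices, per-row "diagonal" random terms (one
independent effect per data row with a separate variance per group — used
for year-specific genotype-by-year variances at one observation per cell),
and per-row weights (`Var(e_i) = sigma^2 / w_i`, with `sigma^2` estimated
rather than fixed to 1).  The residual scale is profiled; the restricted
likelihood is maximized over log variance ratios (L-BFGS-B, bounds
e^-14..e^14, Nelder-Mead fallback) through a Woodbury identity, so a fit
costs O(n q^2) per likelihood evaluation.  BIC is
`-2 logLik_REML + k log n` with k counting variance parameters plus fixed
effects; it is used only for the weighting decision.

Stage 2 models one year's plot values as genotype + random row + random
range (a deliberate simplification of 2-D spline spatial models: it is
identifiable on synthetic data and plays the same adjustment role).  The
BLUE run uses cell-means coding so coefficients are adjusted genotype-year
means; weights are 1/SE^2.  The BLUP run (genotype random) yields the
within-year repeatability via the difference-based heritability formula.

Stage 3 combines genotype-year means with year fixed, genotype fixed
(BLUEs) or random with the IBS kinship (BLUPs), year-specific
genotype-by-year variances, and stage-2 weights on the residual.  Year is
fixed in both modes — with only a few year levels a random year variance is
poorly estimable.  Weighting is kept only when it lowers BIC; ties go to
unweighted.  The same difference-based heritability,
`H2 = 1 - vbar_Delta / (2 sigma_g^2)` with `vbar_Delta` the mean pairwise
prediction-error variance of genotype BLUP differences, is used within and
across years.  A variance ratio driven to the optimizer's lower bound is
treated as a zero component (H2 = 0, flagged): otherwise the PEV/variance
ratio converges to a kinship-dependent constant as the variance vanishes.
On balanced complete data without spatial effects, the two-stage genotype
BLUEs equal a one-stage fit of the combined model exactly; this equivalence
is the central correctness check of the stage-wise decomposition.

## Quantitative genetics

Marker QC removes unmapped, monomorphic, high-missing (> 0.05) and rare
(MAF < 0.05) markers; missing dosages are mean-imputed for matrix
operations only.  The MAF rule keeps common markers — the keep-direction is
the only reading under which a panel survives filtering.  Kinship is mean
identity-by-state, `(2 - |g_i - g_j|)/2` averaged over shared loci,
min-max rescaled to [0, 1] (recorded in metadata) with nearest-PSD repair
by eigenvalue clipping at 1e-8 if needed.  LD-decay thresholds smooth
squared dosage correlations of sampled intra-chromosomal pairs with a
non-increasing isotonic (PAVA) fit and report the smallest distance whose
fitted r^2 drops below the cutoff; isotonic is the default because it
assumes nothing about the decay form.

GBLUP (`y = mu + g + e`, `g ~ N(0, sigma_g^2 K)`, optional weighted
residuals) is re-estimated by REML on every training fold (scalar search
over the variance ratio); held-out genotypes are predicted through the
kinship.  Accuracy is Pearson's r per fold, averaged over all k x repeats
folds; fold assignment is deterministic given the seed.

The bivariate genetic correlation fits trait-wise intercepts and year
effects as fixed, genotype effects with a 2 x 2 genetic covariance
Kronecker the kinship, and one pooled 2 x 2 residual covariance across
traits (genotype-by-year and residual are confounded at one observation
per trait-cell, so they are pooled).  Both covariances use log-Cholesky
parameterization; the REML likelihood is computed exactly after rotating
the genotype axis by the kinship eigenvectors, which block-diagonalizes the
problem into per-genotype (years x traits) cells, with moment-based
starting values.  The implementation requires complete genotype x year x
trait cells and drops incomplete genotypes; unbalanced bivariate REML is
out of scope.

GWAS uses the single-locus mixed linear model: variance components are
estimated once under the no-marker null (intercept + 3 marker PCs +
kinship random effect) via the spectral decomposition of the kinship, then
every marker is tested by generalized least squares with those components
fixed — the "population parameters previously determined" scheme.  P-values
are two-sided t with residual df = n - rank(covariates) - 1; markers
collinear with the covariates get p = 1 and a flag.  With an identity
kinship and zero PCs this reduces exactly to per-marker OLS.  The
significance threshold is Bonferroni, `-log10(alpha / m)`.  Compression
and multi-locus models are out of scope.

Group summaries aggregate genotype values by country-of-registration group
(seven groups; groups with n < 10 excluded) with Tukey-HSD all-pairs
comparisons and a compact letter display (insert-and-absorb; ties broken
alphabetically), plus mean trajectories over five registration-era groups.

## The synthetic-trial generator

The generator defines the study conditions for every test and benchmark.
Defaults: ~345 genotypes plus 3 checks, 2 replicates per year, 4 seasons,
augmented design with checks recurring in a 3 x 3 block arrangement;
110-day seasons with hourly temperature = linear ramp + 5 degC diurnal
cosine (peak 14:00) + AR(1) noise (sd 1.5 degC, autocorrelation 0.7);
measurements every 3 d with +-1 d jitter; 5 mm measurement noise; additive
row/range spatial effects (sd 10 mm each) plus a smooth cosine surface
(amplitude 10 mm); height truncated at 0 and `H0 = 0.15` m.

True genotype parameters are built from 40 shared QTL with effect vectors
drawn with the requested cross-trait correlation, plus a non-genetic
genotype-level deviation tuned so the genotype-mean heritability matches
the request.  Natural scales: `T_min` 5.5 +- 0.5 degC, `r_max` 0.8 +- 0.10
mm/h, `lrc` 3.0 +- 0.35, elongation start 35 +- 2.5 d and stop 80 +- 2.5 d
(the 45-day phase mirrors jointing-to-end-of-elongation spanning roughly
April to June), with per-year shifts (sd 2 d) creating year effects.

The marker panel threshold-samples latent Gaussian AR(1) processes along
each chromosome (correlation `exp(-d / 5 Mb)`), with Balding-Nichols
subpopulation divergence (3 subpopulations, Fst 0.1) and — crucially —
founder-mosaic relatedness: each individual's haplotypes are recombinant
mosaics of a small founder pool (5 founders per subpopulation, ~1 crossover
per chromosome).  The founder pool was calibrated so the panel reproduces
the genomic-prediction regime reported for well-heritable traits in this
trial system (GBLUP r around 0.6-0.8); a panel of unrelated individuals
yields r around 0.3 because the family structure of real variety panels is
missing.  The unstructured mode (`founders_per_subpop=None`) is used where
independence is wanted, e.g. GWAS calibration.

What the generator does **not** emulate: lodging, missing plots, platform
changes mid-season, supra-optimal temperature decline, pedigree-accurate
families, ascertainment-biased marker panels, or weather beyond
ramp+diurnal+AR(1).  Passing tests therefore demonstrate correctness of the
estimators under the stated generating model, not robustness to every
artifact of real field data.

## Benchmark problem sizes

The validation benchmarks (shared by the test suite and
`scripts/acceptance.py`) use: 100 plots for dose-response recovery; a
noise-free daily-sampled logistic (K = 1 m, k = 0.2 /d, midpoint 50 d) for
the QMER analytic check; 200 genotypes x 2 reps x 2 years for the
two-stage/one-stage equivalence; 200 genotypes x 2 reps x 4 years x 10
seeds per h2 level for heritability ordering; 300 genotypes with 10 x
10-fold CV for GBLUP bounds; 300 genotypes x 4 years x 20 seeds for
genetic-correlation recovery; and 300 genotypes x 2000 markers for GWAS
calibration, with 20 seeds for power.  Genetic values in the heritability
and correlation benchmarks are drawn model-consistently from
`N(0, Sigma_g (x) K)` so that those benchmarks measure estimator error
rather than kinship misspecification.

## Known limitations

* Single-plot `lrc` is weakly identified at steep true responses (see
  above); its recovery is reported honestly by the acceptance script.
* The spatial stage-2 model is additive row/range, not a full 2-D spline
  decomposition.
* The bivariate REML requires complete cells.
* The pipeline's QMER-derived fit window biases dose-response estimates
  slightly when QMER misses the true phase boundaries.
* BIC counts parameters simply (variance parameters + fixed effects);
  it is used only to choose between weighted and unweighted stage-3 fits.
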