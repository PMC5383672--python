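# Methods

This note documents the models implemented in `stsroi`, the assumptions of
the synthetic-data generators, and the numerical conventions chosen where
the underlying analysis recipe leaves the choice open. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Study design emulated

A block-design audiovisual-speech experiment: five conditions (A, V, AV, R,
G) presented in 12-s blocks separated by 0.5-s intervals, three blocks per
condition per run, ten runs of 109 volumes at TR = 2.5 s (1090 EPI volumes
in total), with an oddball vigilance task (30 oddball and 150 standard
blocks per session). The stimulus content of each condition is coded by
three binary parameters: auditory AP = 1 for A, AV, R; visual VP = 1 for V,
AV, G; speech SP = 1 for A, V, AV. `DesignSpec` carries the layout;
`blocks_per_condition_per_run` is an explicit parameter (default 3, giving
30 blocks per condition over ten runs) because the source protocol can also
be read as providing 15 blocks per condition to the MVPA stage — dataset
sizes are never hard-coded.

## Synthetic data: what it emulates, what it does not

`gen_block_psc` draws block-level percent signal change (PSC) from the
additive model

    psc = β₀ + b₀ₛ + AP·(β_AP + b_APₛ) + VP·(β_VP + b_VPₛ) + SP·(β_SP + b_SPₛ) + ε,

with per-subject random effects b ~ N(0, Σ) (Σ = D·R·D from user-supplied
standard deviations and a correlation matrix, factored by eigendecomposition
so zero-variance terms stay exactly zero), Gaussian noise ε, and optional
outlier contamination (an additive ±magnitude shift at a given rate, chosen
to be detectable by the median/MAD rule). Random effects are drawn
independently per subregion. Defaults mirror the study scale: 18 subjects,
10 runs, 3 blocks/condition/run.

`gen_bold_timeseries` builds per-run series as Σ amplitude × (boxcar ⊛ HRF)
plus polynomial drift and white noise, sampled at the TR, together with
synthetic censoring metrics (|N(0, 0.05)| motion-derivative norms,
Exp(0.02) outlier-voxel fractions). The HRF is a double-gamma with unit
peak (gamma shapes 6 and 16, scales 1 s, undershoot ratio 1/6 — peak near
5 s, undershoot near 15 s); all parameters are configurable. Convolution
runs on a 0.1-s grid before TR sampling to control discretization error,
and regressors are rescaled so an isolated block of the scheduled duration
has unit peak (amplitudes are then in PSC units). Rest and oddball blocks
are not generated as modeled conditions; the scheduler places the 15
modeled blocks consecutively at the start of each run, which leaves a rest
tail — adequate for testing estimation, not a physiological simulation.

`gen_pattern_dataset` produces blocks × voxels patterns as condition mean +
isotropic Gaussian noise with run labels; `gen_frames` renders moving
Gaussian blobs, rectangles, or full-field smooth periodic textures with
recorded ground-truth displacement; `gen_oddball_outcomes` draws binomial
hit/false-alarm counts with the 30/150 denominators.

None of the generators model vascular or physiological noise, spatial
autocorrelation between voxels, scanner drift nonstationarity, or face-like
image structure. Passing tests therefore demonstrate the statistical
machinery's correctness and calibration under its own assumptions, not
robustness to real-data violations of them.

## Behavior

d' = Φ⁻¹(H) − Φ⁻¹(F). Extreme rates (H or F exactly 0 or 1) raise a
structured error by default, because the recorded worked examples never
need correction and silent alteration would be misleading; an opt-in
loglinear policy substitutes (x + 0.5)/(n + 1). The exclusion rule flags
d' < mean − 1.5·SD, computed over all subjects including candidates, with
the sample (n−1) standard deviation; both k and the ddof are configurable
since the recipe does not pin them down.

## LS-S estimation

For each block, an OLS model with: the block's own HRF-convolved regressor;
one nuisance regressor summing the remaining blocks of its condition; one
per other condition (so five condition nuisances for a five-condition
design); a run baseline; Legendre drift (default order 2); and optional
user confound columns (the 12 motion-parameter regressors of a real
pipeline enter here — the synthetic data supplies none because the
censoring metrics, not raw motion parameters, drive testable behavior).
Censored volumes (outlier fraction > 0.10, strictly, or motion-derivative
norm > 0.4) are dropped from every fit; rank deficiency after censoring is
an error naming the block. Because blocks in different runs share no
volumes and drift is per-run, per-run estimation is equivalent to a joint
multi-run fit.

Two identifiability facts shape the tests. With condition-level amplitudes
the generating signal lies in every block design's column span, so recovery
is exact (< 1e−8, noiseless). With heterogeneous per-block amplitudes the
condition-sum nuisance cannot represent the signal and LS-S is a deliberate
bias/variance compromise — it does not coincide with an all-blocks GLM even
for temporally separated blocks, except when the two designs are literally
the same set of columns (one block per condition), which is the regime the
equivalence test uses.

## Mixed model and permutation FWER

Per subregion: psc ~ AP + VP + SP with by-subject random intercept and
slopes, REML via statsmodels MixedLM; Wald t = estimate / SE (no
Satterthwaite correction — the permutation makes the reference distribution
empirical). Predictors are standardized to mean 0, SD 1 within each
subject × subregion stratum (sample SD). Before fitting, each subject's
blocks pass the robust outlier rule: drop x with |x − median| >
Φ⁻¹(1 − 0.001/N) · (π/2) · MAD. The rule is implemented as printed: the
π/2 multiplier (not the usual √(π/2) ≈ 1.2533 or the 1.4826 MAD consistency
constant) is the default and configurable; deviations are measured from the
median. Because the quantile is N-adjusted, the expected number of false
flags per Gaussian subject sample is ≈ 0.002 — a Bonferroni-style rule
whose false-flag *fraction* is of order 1e−5, which the tests assert.

Non-convergence falls back stepwise, each step logged: free-correlation
random effects → independent variance components → drop the SP, then VP,
then AP slope → intercept only → OLS.

The permutation test reshuffles condition labels within subject — subjects
are the exchangeability blocks under the random-effects model — with the
identical shuffle applied to AP/VP/SP and to every subregion; the response
is never reordered. Per permutation the per-subregion t-scores are refit
and their max and min across subregions recorded. One-tailed p-values
compare positive observed t to the max-t distribution and negative t to the
min-t distribution, with the add-one convention (b+1)/(n+1) for sampled
permutations; exhaustive enumeration (available when the within-subject
permutation space is small) includes the identity and returns exact
proportions. Null values within 1e−8 of the observed statistic count toward
the exceedance, so mathematically exact ties resolve independently of
floating-point evaluation order.

Two refit paths exist. The default refits the full mixed model per
permutation. The `subject_ols` path computes, per subregion, each subject's
OLS coefficients on (1, AP, VP, SP) and forms a one-sample t across
subjects — the classic summary-statistics shortcut, exact to permute (only
the predictor order changes, so the per-subject projection matrix is fixed)
and orders of magnitude faster. Its rank agreement with the mixed-model t
is validated in the suite (Spearman ρ > 0.9 over a 20-fit validation set);
dense permutation schedules and the null-calibration study use it.

**What "FWER < 0.05" means here.** Each directional family test — any
subregion exceeding the max-t threshold (activation), or any below the
min-t threshold (deactivation) — controls family-wise error across
subregions at the nominal 0.05 per fixed effect. Declaring significance in
*either* direction, as the sign-dependent p-value does, is the union of the
two directional tests and rejects under a global null at ≈ 2α (~0.10,
reproduced empirically). The calibration study and the acceptance script
therefore measure the directional (max-t) family rejection rate, which is
the quantity the procedure controls at the nominal level; its global-null
generator uses a random intercept but zero random slopes, since
condition-linked slope variance would itself violate within-subject label
exchangeability. `min_t_conjunction` additionally exposes the voxelwise
minimum of two statistic maps for conjunction-null testing; thresholding is
left to the caller.

## PCA of condition × voxel activation

Voxels are variables, the five conditions observations. Columns are
centered per voxel across conditions and not variance-scaled (all values
share PSC units); the SVD of the centered matrix yields condition scores
U·S, orthonormal voxel coefficients V, and percent variance s²/Σs². Signs
are fixed by orienting each component so the condition with the largest
|score| is positive. Biplot data scales condition scores into the voxel
coefficient range (default 0.8 of the axis range, a display-only choice)
and shares axis limits across subregion panels.

## MVPA

Patterns are z-scored across voxels per block (population SD), removing
mean-amplitude differences so classification reflects pattern shape.
Pairwise decoding uses a linear soft-margin SVM (C = 1, no further feature
scaling) with leave-one-run-out folds; every run must contain both
conditions. Fold-level d' designates one condition "signal" (hit = correct
prediction on a signal block; false alarm = incorrect prediction on a noise
block) and applies the loglinear rate correction *by default*: with ~3
blocks per class per fold, perfect folds are common and would otherwise
give infinite d'. This caps the per-fold d' at Φ⁻¹((n+0.5)/(n+1)) −
Φ⁻¹(0.5/(n+1)) — about 2.30 for 3+3 folds — so group means are conservative
relative to an uncapped statistic. Subject d' is the mean over folds.

The bootstrap-T group test reshuffles the two conditions' labels within
subject and run, re-runs the full cross-validated classification per
repetition, and compares the observed one-sample t of subject d' (against
chance 0) to the null t distribution, p = P(t_null > t_obs) with the
add-one convention. The repetition count is a parameter: the full-scale
10,000 default is appropriate for production use, while the suite and
examples run reduced schedules (tens to hundreds) because each repetition
refits runs × subjects SVMs.

## ROI partition

Probabilistic-map thresholding is inclusive (value ≥ threshold) and never
admits zero-probability voxels, so threshold 0 returns the support.
Equal-length partition divides the mask's extent along a world-coordinate
axis (default the y/anterior–posterior axis, in millimeters — not sulcal
arc length, and not voxel index space unless no affine is given) into K
intervals of equal length, half-open on the posterior side with the final
interval closed; labels run 1 (anterior-most) to K. Centers of mass are
unweighted means of member-voxel world coordinates.

## Problem sizes and known limitations

The suite and acceptance script run desk-scale versions of the heavy
studies: the null-calibration uses 100 cohorts × 200 permutations with the
subject-OLS path (8 subjects, 4 subregions, 6 blocks/condition), mixed-model
recovery uses 200 cohorts at the full 18-subject design, and MVPA
calibration uses 18 subjects × 50 voxels. These sizes were chosen so each
check completes in seconds to a couple of minutes while keeping Monte-Carlo
error within the asserted tolerances.

Known limitations: Horn–Schunck is solved by the classic Jacobi iteration,
which converges slowly — with the default 100 iterations a 1 px/frame
translation is heavily damped, so displacement-recovery checks run the
solver to ~5000 iterations (ratios between clips are much less sensitive to
truncation than absolute magnitudes); the RMS "motion energy" pools the u
and v components by default (per-pixel speed RMS is available as
`method="magnitude"`); the mixed model assumes Gaussian errors and a single
residual variance across conditions; MVPA offers no searchlight or feature
selection; the ROI tools do not bundle an atlas or perform registration.
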