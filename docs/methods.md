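# Methods

This note documents the models implemented in `lcstress`, the synthetic
cohort they are validated on, the numerical choices that matter, and what
the passing tests do and do not establish.

## Task structure and behavioral models

Trials of the emotional Stroop task are congruent (C) or incongruent (I);
the trial-sequence label combines the previous and current trial (CC, CI,
IC, II; the run-initial trial is labelled `first`). The CI > II contrast is
the conflict-upregulation response: both conditions present an incongruent
stimulus, but only CI requires fresh upregulation of control.

Behavioral fits regress z-scored RT (linear) or accuracy (logistic) on
current congruency, previous congruency, their interaction, and emotional
valence. Binary predictors are effect-coded ±0.5, so linear coefficients
read as condition differences in RT standard deviations. Error trials and
run-initial trials are excluded from RT fits (common practice; the coding
and exclusion rules are package choices, surfaced as defaults). The CSE
score used as a predictor downstream is the raw mean RT(CI) − RT(II) over
accurate trials, in ms; for balanced designs it equals the negated
interaction-implied contrast.

## First-level GLM

The design holds HRF-convolved indicators for CC/CI/IC/II (plus a
throw-away `first` column), unconvolved nuisance series (6 motion, blink,
and the first 5 principal components of the demeaned CSF voxel-by-time
matrix), a discrete-cosine high-pass basis (128 s cutoff by default), and
an intercept. The HRF is the double-gamma (response shape 6/scale 1 s,
undershoot shape 16, ratio 1/6), built on a `TR/oversampling` grid and
normalized to unit peak. Condition regressors are additionally scaled so
one isolated event of the typical duration peaks at 1; condition betas
therefore read as peak evoked amplitudes in raw signal units.

Temporal autocorrelation is an AR(1) process whose coefficient is estimated
once from OLS residuals pooled over all voxels; data and design are
whitened with the exact AR(1) Cholesky factor (first row scaled by
√(1−φ²), then yₜ − φyₜ₋₁) and refit. This equals explicit GLS with the
AR(1) covariance, which the tests assert to 1e-8 on toy problems. The
pooled residual estimate of φ carries an O(k/n) downward bias (≈0.016 at
380 scans, 6 regressors); whitening with a slightly biased φ does not bias
the contrast estimates, only marginally their efficiency. Contrast t maps
use t = cᵀβ / √(cᵀ(XᵀX)⁻¹c·σ̂²) on the whitened design with df = n − k.
Contrasts touching an all-zero design column (an unrealised condition) are
refused.

PPI designs append the mean-centred seed time course and its element-wise
products with the convolved CI and II regressors (no deconvolution; the
interaction is formed on the BOLD-level regressors as stated in the
construction we mirror). Coupling is the weighted-ROI average of the
seed×CI − seed×II effect.

## ROI extraction and tSNR

Small brainstem nuclei are summarised by probability-weighted averages
Σwᵥxᵥ/Σwᵥ over voxels with wᵥ > 0 — linear in the map and invariant to
uniform weight rescaling. tSNR is mean/sd per voxel (sample sd, ddof=1);
zero-variance voxels become NaN sentinels and are excluded from ROI
summaries. LOSO sphere extraction computes, for each subject, the group
mean map of all other subjects, takes the arg-max voxel within a search
mask (ties: lowest linear index), and averages the held-out subject's map
in a 5 mm sphere (voxel centre within radius, inclusive; spheres are
clipped at grid edges with a flag).

## Pupillometry

Preprocessing per run: linear interpolation across blink gaps, zero-phase
3rd-order Butterworth high-pass at 0.05 Hz then low-pass at 4 Hz, z-score.
Epochs span ±5 s (2501 samples at 250 Hz); trials too close to run edges
are dropped and counted. Group inference on per-subject difference
waveforms uses pointwise one-sample t, two-sided cluster-forming threshold
at α = 0.05, cluster mass Σ|t|, and a max-mass null from whole-subject sign
flips with the add-one p estimator — an exact FWER control for symmetric
errors. PDD = mean CI−II difference over 1530–4862 ms minus the same over
−3044 to −1222 ms, windows snapped outward to the 4 ms grid, endpoints
inclusive, no baseline subtraction (z-scoring only).

## Prediction machinery

Change scores are Δt1 = t1 − t0, Δt2 = t2 − t0, mean change = (Δt1+Δt2)/2,
per instrument (STAI anxiety, PHQ depression). Associations use Spearman
rank correlation (mid-rank ties; exact permutation p for n ≤ 9, otherwise
the t-approximation) and robust bisquare regression (tuning 4.685,
coefficient tolerance 1e-8). Median-split tests compare a marker between
subjects above vs at-or-below the outcome median (ties to the lower group)
with a pooled-variance t, df = n − 2.

LTSO enumerates all N·(N−1) ordered pairs; each fold's linear model on the
remaining N−2 subjects is obtained exactly from the full-sample normal
equations by a rank-2 downdate (Sherman–Morrison–Woodbury), verified
against brute-force refits. A pair scores 1 when sign(ŷᵢ−ŷⱼ) =
sign(yᵢ−yⱼ), 0.5 on ties; the symmetric rule makes ordered and unordered
counting identical, which the tests assert to machine precision. The
permutation null shuffles the change scores once per permutation (reused
across folds); because the pair operators depend only on the predictors,
the 1000-permutation null is a single matrix product. The literal
per-left-out-pair shuffle is available (`per_pair_shuffle=True`) but is not
the default: it collapses the null to a degenerate distribution tightly
concentrated at 50% and rejects almost always under independence, whereas
the global shuffle is an exact test (type-I ≈ 5%, asserted). A consequence
worth knowing: under the global null the accuracy distribution is folded
(≈50 + 50·|Kendall τ| of the shuffle), so at a true marker–outcome Spearman
of 0.35 and N = 48 the expected accuracy is ≈62% and the power of the test
at α = 0.05 is ≈0.65, not higher — accuracy bands and power should be read
against this folded null.

LOSO predictions under independence are *negatively* correlated with the
outcome (the usual cross-validation artifact); the null check therefore
tests for absence of spurious positive skill rather than a symmetric band.

## Model comparison

Gaussian linear models report R², adjusted R² = 1 − (1−R²)(n−1)/(n−k−1),
and AIC/BIC from the Gaussian ML log-likelihood (parameter count =
regression coefficients, variance not counted — the statsmodels OLS
convention). Stepwise selection starts from the constant model, adds the
candidate with the smallest deviance-difference p (Gaussian deviance
n·log(RSS/n), χ² on the parameter-count difference) while p < 0.05, with
removal passes; scan order is the table's column order, making the result
deterministic. Note the family-wise behavior: with m pure-noise candidates
the constant model survives at roughly (1−α_eff)^m ≈ 0.70 for m = 5 (the
deviance χ² is mildly anticonservative at n = 48), not at 1−α. ROC labels
binarise the continuous change at the cohort median (an explicit cutoff is
accepted); AUC is the trapezoid area and equals Mann–Whitney concordance
with ties counted half.

## Synthetic cohort: what it emulates, and calibration

Defaults describe the study conditions: 48 subjects, 160 trials at SOA
4 s + 0–1 s jitter, TR 2 s, 380 scans, a 2.5 mm voxel grid with Gaussian
probabilistic ROI profiles, LC CI−II amplitude ~N(0.6, 0.3²) signal units
on a baseline of 100, AR(1) noise (marginal sd 2.3, φ = 0.3), three shared
sinusoid+AR physiological components injected into CSF at amplitude 3 and
leaking into brainstem nuclei at fraction 0.15, motion-correlated drift,
and an LC–symptom-change Spearman coupling of 0.35 via a Gaussian copula
(Pearson latent r = 2·sin(πρ/6), rank-normal scores of the true
amplitudes). These values put the measured LC tSNR near 40 (comfortably
above the >30 quality cut-off) and the measured brain–symptom correlations
in the 0.30–0.38 range reported for cohorts of this kind. Trial counts,
TR and run structure are configuration values, not claims about any
particular acquisition.

Symptom panels are built so the derived change scores recompute exactly
from raw t0/t1/t2 integers: a shared latent drives both instruments, the
t1/t2 split is antisymmetric (cancelling in the mean change), and
instrument-specific offsets are small, so the configured rank coupling
carries through to the STAI mean change up to rounding (calibration test:
mean sample ρ within ±0.03 of target over 200 cohorts).

Two pupil-generator choices deserve emphasis. First, the I−C conflict
surplus lives on a short (0.9 s) early kernel: CI trials are always
preceded by C and II by I, so any slow conflict-locked component of the
*previous* trial would systematically contaminate the pre-trial window of
the CI−II contrast. Second, configured effect sizes are defined as
post-pipeline z-unit values: the 0.05 Hz high-pass removes 30–50% of
sustained multi-second responses in situ (with strong cross-window
leakage), so the generator measures a 2×2 response matrix on a
deterministic noiseless reference schedule pushed through the exact filter
cascade and solves it for the injected (CI−II surplus, pre-trial
carry-over) amplitudes. The band-limited noise floor is calibrated so the
post-filter trace has ≈unit variance, making z-scoring nearly scale-free.

All randomness flows from one root seed: a `SeedSequence` spawns one child
per subject (split into trials/behavior/bold/pupil streams) plus
cohort-level streams for the amplitudes and symptoms, so identical
(config, seed) reproduce identical cohorts; on-disk manifests carry
checksums of all text outputs.

## Problem sizes and numerical choices

Validation experiments run at desk scale on one CPU: a compact voxel grid
(16×20×13) that still contains every ROI (only background voxels are
trimmed, so ROI statistics are unchanged), 100-cohort batteries for power
and specificity, 500 replicates for cluster-test FWER, 2000 null voxels for
GLM calibration, and 200–1000 permutations per test. The specificity
harness fits the massively univariate GLM on the union of ROI supports —
per-voxel estimates identical to a whole-grid fit, with the AR coefficient
pooled over those voxels.

Degenerate inputs are errors, not warnings: all-zero masks, grid
mismatches, constant PPI seeds, rank-deficient designs, zero-variance
one-sample tests, fully blinked runs. Ties are resolved deterministically
(peak selection by lowest linear index, pairwise scoring by the 0.5 rule,
median splits to the lower group).

## What passing tests do not show

The synthetic cohort has no anatomy, no realistic spatial correlation
structure, no scanner drift beyond AR(1)+low-rank physiology, no slice
timing or motion *estimation* (series are generated, not estimated), no
luminance confound in the pupil model, and symptom trajectories with a
single shared latent rather than heterogeneous growth classes. Recovery of
planted effects therefore validates the estimators and their calibration,
not the biological claim; on real data, registration quality, partial
voluming around the fourth ventricle, and pulsatile artifacts are the
dominant risks and are out of scope here.
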