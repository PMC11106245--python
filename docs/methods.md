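# Methods

This note documents the statistical model behind `mspanel`, the defaults and
why they are what they are, what the synthetic cohorts do and do not emulate,
and the numerical and design choices made where the procedure left room.

## Endpoint derivation

A sample's lesion annotation is only trusted when the blood draw lies within
a symmetric ±30-day window of the MRI (`mri_offset_days` is signed, draw −
MRI, compared at day resolution).  Out-of-window samples keep their rows but
lose the lesion annotation, so they remain usable for the clinical endpoints.
Binary contrasts: GDA (0 vs ≥ 1 lesion), SDA (0 vs exactly 1; ≥ 2 excluded),
EDA (0 vs ≥ 3; 1–2 excluded), CRS (quiescence vs exacerbation), ARR
(≤ 0.2 low vs ≥ 1.0 high relapses/year, inclusive bounds; intermediate rates
excluded).  Missing annotations always mean *excluded*, never imputation.
Lesion counts entering regression are clipped at five: higher counts are too
rare for the model's behavior there to be reliable.

## Synthetic cohorts

The generator draws, per sample, latent standardized protein scores
z_ij ~ N(0,1) and an NPX-scale measurement

    NPX_ij = baseline_j + batch_offset[b(i),j] + γ_age age_i + γ_sex sex01_i
             + γ_dd duration_i + s·z_ij + ε_ij,      ε ~ N(0, noise_sd²).

Endpoints are driven by the same latents through sparse coefficient vectors
β: lesion counts are Poisson(exp(α + βᵀz)); relapse status is
Bernoulli(logistic(c + βᵀz)); ARR class membership is logistic in the same
latent (high positively, low negatively loaded), with the numeric rate drawn
inside the class band.  Class intercepts are calibrated by root-finding on
the realized latents so requested prevalences hold in expectation.  ARR and
CRS share their causal set by default, making the clinical endpoints
correlated as they are in real cohorts; the joint endpoint distribution is
otherwise an assumption of this generator, not an observed fact.

Defaults are the emulated study conditions: cohorts of 326 / 180 / 124
samples (lesions + ARR, lesions only, relapse status only), age ~ N(39, 9)
years, disease duration ~ |N(7, 6)| years, 73 % female; 3 batches with
offsets ~ N(0, 0.5²) NPX and 8 bridge aliquots re-measured per batch;
measurement noise sd 0.4 NPX; covariate effects 0.01 NPX/year (age),
0.2 NPX (sex), 0.02 NPX/year (duration); Poisson intercept −0.7 (mean
lesion count ≈ 1.3, roughly a quarter of samples lesion-free); anchor β 0.9
on the lesion latent and 0.72 on the clinical latent, plus nine secondary
causal proteins per endpoint at β 0.35 / 0.30; ARR high-class prevalence
8 %.  Everything is reproducible bit-for-bit from one seed through fixed
substreams (per cohort, batch structure, bridges).

What the generator does **not** emulate: assay chemistry, detection limits
and censoring, plate-layout artifacts beyond additive batch offsets,
longitudinal correlation within patients, and non-Gaussian abundance tails.
A passing recovery test therefore shows the *pipeline* is sound under its
stated model, not that any particular real panel would be recovered.

## Preprocessing

Bridge normalization shifts every batch, per protein, by
(median of its bridge measurements − pooled median of all bridge
measurements); medians resist single outlying bridge wells, and after the
shift every per-batch bridge median equals the grand median exactly (the
test tolerance, 1e−9, is pure float headroom).  The transform is a per-batch
constant, so within-batch sample ranks never change.  A batch with no bridge
aliquot is an error, not a silent pass-through.

Covariate correction fits, per protein, OLS of bridge-normalized NPX on
(1, age, sex01, duration) using only the reference class — lesion-free
samples where a lesion endpoint exists, endpoint-negative samples otherwise
— and subtracts the prediction from **all** samples.  The reference class
must have at least covariates + 2 = 5 members and a full-rank design; a
constant covariate is reported by name.  Bridge aliquots carry no
demographics and are dropped after normalization.  Missing values are never
imputed; proteins above a configurable missingness fraction (default 20 %)
are dropped with a warning.  Univariate statistics consume normalized
values; all multivariate modeling consumes the residuals.

## Univariate statistics

Spearman's ρ uses average ranks (count ties are the norm) with the
large-sample t approximation for the two-sided p-value.  The class
comparison is a pooled-variance Student's t (Welch is available behind
`equal_var`-style code paths but pooled is the default, matching the
screen's convention); the sign is positive when the positive class has the
higher mean.  The AUROC is computed through mid-ranks and equals the
Mann–Whitney pair fraction exactly — the identity
auroc(v) + auroc(−v) = 1 holds to machine precision.  Significance is
flagged at α = 0.05 unadjusted, as in the original screen; a
Benjamini–Hochberg column is available (`add_bh=True`) but not used by
default.  Box-plot summaries use linear interpolation of order statistics;
whiskers are the central 90 % and outliers everything outside [p5, p95].

## Randomized-subset screen

Subset sizes 3–21 in steps of three; architectures logistic regression,
linear-kernel SVC, random forest; every subset contains the anchor plus
uniformly drawn others.  Models are fit on the entire labeled set and scored
by *training* AUROC — a deliberately optimistic protocol whose bias is
shared by every candidate and so cancels in the ranking (a held-out variant
exists behind `held_out_fraction`).  Importance rules: |coef|·sd for
logistic ("variance-normalized" coefficient magnitude — on a log-like scale
per-protein spreads are similar, so this mostly removes units; the
alternative |coef|/variance is selectable), |coef| for the linear SVC, and
impurity importances for the forest.  Vectors are normalized to unit sum
per model (an all-zero vector is recorded as degenerate and excluded),
weighted by model AUROC, and averaged per protein over the models containing
it.  Hyperparameters are fixed and echoed in the run manifest: C = 1 for
both linear models, and a 25-tree depth-6 forest — shallow forests are ample
for ≤ 21-feature subsets and keep the desk-scale screen (2,000 repeats per
size × architecture, 42,000 models) on one CPU in minutes.  Full-scale runs
use 100,000 repeats via the `paper` mode preset.

Panel integration is by summed rank over all univariate and multivariate
lists (a protein absent from a list contributes that list's length + 1),
stable-sorted so ties break lexicographically; the default budget is 20
proteins plus an optionally appended reserved analyte, which is a
configuration entry, never a computed result.

## Bootstrap ensemble, GFS, and sizing

All multivariate evaluation runs over one plan of stratified
two-thirds/one-third splits (1000 in paper mode, 200 desk); stratification
guarantees both classes in every train and test fold, which plain random
splits violate for rare classes like high-ARR.  Re-using a single plan
across feature sets makes comparisons paired.  Greedy forward selection
seeds with the feature maximizing the mean univariate test metric over the
plan, then adds whichever feature maximizes the grown set's mean test
metric, to pool exhaustion; ties break toward the smaller protein id.
Candidates losing a rep (single-class restricted fold, failed fit) lose
only that rep, and the drop count is recorded.

The plateau rule concretizes "no longer significantly improved": the
working size is the smallest k with mean(k+1) − mean(k) < z·sd(k)/√reps,
z = 1 (a one-standard-error rule; z is configurable).  A never-improving
curve returns size 1 with a warning.

## Endpoint models

Binary endpoints use L2 logistic regression (C = 1); lesion counts use
log-link Poisson regression (alpha ≈ 0) on counts clipped at five, with
continuous expected-count predictions — R² is the square of Pearson's
correlation between actual and predicted test counts, and the pooled
actual-vs-predicted cloud yields the best-fit line and RMSE.  Features are
standardized with train-fold parameters inside every fit (leakage control),
which also makes classifier scores invariant to affine feature rescaling.
ROC bands vertically average per-rep curves at 101 evenly spaced FPR points
(mean ± 1 sd); the trapezoid area under the mean curve agrees with the mean
per-rep AUROC to grid resolution (< 0.005).  The GDA-trained ensemble is
additionally scored on the SDA and EDA contrasts by restricting each test
fold to those contrasts' classes.  Permutation importance shuffles one
feature's column within the test fold (one shuffle per rep by default,
configurable upward) and reports the mean ± sd metric decrease.

## Numerical and statistical caveats

Bootstrap reps resample one dataset, so per-rep values are correlated and
sd/√reps understates the uncertainty of dataset-level means; null-behavior
tests therefore average over independent replicate datasets and use the
across-dataset spread, or use small absolute floors where a single dataset
is the point.  Degenerate inputs have defined behavior throughout: constant
score vectors give AUROC 0.5 via mid-ranks; constant features survive
standardization (sd forced to 1); all-zero importance vectors and
non-convergent fits are counted and skipped, never silently averaged.

## Scale defaults

Desk scale — 200 bootstrap reps, 2,000 screen repeats — is the package's
working configuration for iteration and testing and the scale the test
suite and the acceptance script run at; `paper` mode (1000 / 100,000) is a
preset away.  Both are named presets of `RunConfig`, and `bootstrap_reps` /
`screen_repeats` override either preset for still smaller smoke runs.
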