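# Methods

## Scope

`mbopls` implements a complete screening workflow for designed multiblock
LC-MS metabolomics: construction and diagnosis of a mixed-level orthogonal
array, simulation of multiblock peak tables with known effects, feature-level
filtering and Pareto scaling, consensus OPLS-DA over fused linear kernels with
LOOCV/DQ² and permutation validation, and S-plot-based biomarker selection
with metabolite-level clustering. This note records the model, its
assumptions, the defaults, and the choices made where the design was open.

## Experimental design

The target class is the 2^12 · 3 · 4 screen in 96 runs: every factor balanced,
every factor pair level-combination balanced (orthogonal array), so all main
effects are estimated orthogonally. The builder constructs the array from the
full factorial over the multi-level factors and `log2(runs / Π levels)`
two-level carrier columns; a four-level factor is decomposed into two ±1
pseudo-bits, and each two-level factor is assigned to a ±1 product column of
the base. Any distinct product column is automatically balanced against every
factor and every other product column, so the orthogonal-array property holds
by construction and is re-verified exactly (integer contingency tables) before
a design is returned. Among the admissible columns, assignment is greedy:
each factor takes the unused column creating the fewest new confounding
triples, ties broken toward lower-order products. This reproduces the design
class and diagnostics of catalogue-based generators while staying
self-contained; the exact column allocation of any particular catalogued
96-run array is not unique, so confounding triples are validated against brute
force, not against a specific catalogue.

Confounding is diagnosed per factor triple {A, B, C} by canonical correlations
between A's centered main-effect contrast space and the span of the pairwise
products of B's and C's centered contrasts (and the two rotations). A squared
canonical correlation ≥ 1 − 1e−8 counts as complete aliasing; the explicit
cutoff makes the numeric rank decision reproducible. Two calibration facts
worth recording: a full factorial has zero aliased triples; the resolution-III
half fraction I=ABC has all three directed checks equal to 1, whereas the
resolution-IV fraction I=ABCD has none (main effects there alias only
three-factor interactions) — both verified by brute force in the tests.

Power for a two-level factor uses the two-sided two-sample t-test with pooled
variance, runs/2 observations per level, df = runs − 2, evaluated through the
noncentral t distribution (statsmodels). At 96 runs and α = 0.05 this gives
0.998 / 0.679 / 0.953 for standardized effects of 1.0 / 0.5 / 0.75 SD, and
power equals α at zero effect. The one-factor-at-a-time comparison counts
(1 + Σ_f (levels_f − 1)) · replicates runs; the 14-factor screen needs
18 · 24 = 432 OFAT runs versus 96.

Indicator columns drive all supervised models: one column per two-level factor
(high = 1) and one per hormone of a multi-level factor (present = 1), 19 in
total for the default screen. A k-level factor's k columns sum to the all-ones
vector; the hormones are therefore modelled one-vs-rest, and reports always
print the majority-class baseline (75% for the four auxins, 66.7% for the
three cytokinins) next to the prediction accuracy.

## Simulator

Intensities are log-normal: each latent feature draws a baseline
log-intensity ~ N(8, 1.5²) (arbitrary units), experiment run values add the
factor effects and N(0, noise_sd²) on the log scale, and intensities are the
exponential (hence non-negative). Effects are additive log shifts of
`magnitude × noise_sd` applied through an indicator column, so magnitudes are
in residual-SD units. Defaults: noise_sd = 0.4; blocks of 1500/1366/1368
features (RPPOS/RPNEG/HILIC) with a 0.15 shared-feature fraction (shared
latents materialise in several blocks with independent noise); m/z uniform in
100–1200 Da and retention time in 1.6–24.6 min to match a typical acquisition
window. Hormone-derivative features exist only in runs containing the hormone
and otherwise sit at a noise floor (default 10 intensity units) with a small
log jitter of 0.5 × noise_sd — not exact zero, which would create
zero-variance columns that Pareto scaling must reject. Blank runs contain only
designated background features; one pure-additive run per hormone contains
only that additive's features; QC injections are the pooled experiment mean
times exp(N(0, σ²)) with σ = sqrt(log(1 + CV²)) so the per-feature CV matches
`qc_cv_target` (default 0.15) exactly in expectation.

The bundled screen configuration mirrors the qualitative outcome structure of
the tobacco-cell screen it emulates: strong effects (2.5 SD, 18 features) for
KNO3, NH4NO3, CaCl2, MeJA, salicylic acid, cyclanilide, ABA and light; weak
effects (1.5 SD, 10 features) for GA3 and ethephon, calibrated so those models
come out statistically significant but with visibly lower prediction accuracy;
no effects at all for KH2PO4 and MgSO4, the screen's null factors; and
per-hormone derivative features named after 45 identified-metabolite fixtures
(glycosides, ribosides, hormone metabolites), which double as the rows of the
metabolite loading matrix. No effect-size information exists for the real
data, so these magnitudes are calibrated only to reproduce that
significant/non-significant split, and were fixed before any acceptance
checking of downstream statistics.

What the simulator does **not** model: chromatographic peak shape, isotope
patterns and adducts, ionisation suppression, retention-time drift,
batch/injection-order effects, or heavy-tailed contamination. Passing tests
therefore demonstrate that the statistical machinery recovers known structure
under a faithful intensity model, not that any particular instrument's
artefacts are handled.

## Preprocessing

Background removal drops a feature if its intensity exceeds an explicit
detection threshold in at least one blank or pure-additive run (presence, not
fold change); a feature detected in both kinds of run is counted once, under
blank. The default threshold of 30 equals three times the simulator's noise
floor; for real tables it is instrument-specific configuration. QC dispersion
is reported as a per-feature coefficient of variation over pooled-sample
injections with a 40% flag threshold; the flag is diagnostic only — filtering
on it is off by default since reporting a CV and filtering on one are
different policies, and only the former is unambiguous. CVs use raw
intensities (a CV after centering is meaningless). Pareto scaling
(mean-center, divide by sqrt of the sample SD, ddof = 1) is the modelling
normalisation; it is deliberately *not* baked into stored datasets because
cross-validation must refit it per training fold.

## Consensus OPLS-DA

Per block, the linear kernel X_i X_i^T is double-centered (equivalent to
column-centering X_i in feature space) and scaled to unit Frobenius norm, so
blocks of very different dimensionality and intensity scale start with equal
leverage. Block weights are modified RV coefficients — both kernel diagonals
zeroed before the normalised Frobenius inner product, removing the
sample-size bias of the classic RV — computed against the response kernel
y_c y_c^T, clipped at zero and normalised to sum to one. If every RV is
non-positive (pathological anti-structure), weights fall back to uniform with
a warning. A single block always gets weight 1.

The kernel OPLS fit works entirely in the dual. With y_c the centered
indicator: the predictive score is t_p = K y_c / sqrt(y_c^T K y_c)
(unit-norm weights in feature space); each orthogonal component is the
structured Y-orthogonal direction t_o ∝ (K − t_p t_p^T) t_p, unit-normalised;
the kernel is deflated on both sides, K ← (I − t_o t_o^T) K (I − t_o t_o^T),
and the final predictive component is extracted from the fully deflated
kernel, which makes t_p exactly orthogonal to every t_o. For linear kernels
this reproduces the primal OPLS sequence (weights, orthogonal weights as the
loading component orthogonal to w, row-space deflation); the tests verify
held-out-prediction agreement with an explicit primal implementation to 1e−8
and agreement with single-component PLS when no orthogonal component is
requested. Prediction deflates new cross-kernel rows with the stored per-stage
quantities — algebraically identical to deflating the new sample in feature
space — then projects onto the predictive direction: ŷ = t_p,new q_p + ȳ.

Rank guards: fitting raises once y_c^T K y_c or the orthogonal-score norm
falls below 1e−12 × trace(K), rather than returning numerically meaningless
components.

## Validation

LOOCV leaves out one run at a time and refits *everything* on the training
fold: Pareto parameters, kernel centering, Frobenius scaling and RV weights;
the held-out sample is transformed with the fold's parameters. This is the
leakage-free reading of cross-validation for a pipeline whose scaling is
data-dependent. DQ² = 1 − PRESS/TSS with class-side truncation (residuals of
predictions beyond their own class label set to zero) scores each candidate
number of orthogonal components, 0..max (default cap 3, reduced runs use 2),
stopping early once DQ² decreases and choosing the first maximum — small
models are preferred exactly because DQ² is designed to flag overfitting.
Prediction accuracy thresholds ŷ at 0.5; a tie counts as incorrect
(deterministic and conservative).

Permutation tests shuffle y only, never X, re-running the full LOOCV per
permutation at the model size chosen on the observed labels (re-optimising
the size per permutation would multiply cost for no change in the null's
meaning). The p-value uses the add-one rule p = (1 + #{null PA ≥ observed
PA}) / (1 + n_perm), so p is never zero and the finest value at n_perm = 1000
is 1/1001 ≈ 0.001 — matching the "<0.001" granularity of screen-style
reporting. Because fold kernels are response-independent they are cached once
per dataset and shared by the observed model and all permutations, and the
permutation null is evaluated batched (all permutations per fold in a few
BLAS products); the batched path is verified element-identical to the naive
per-permutation loop. Full runs use n_perm = 1000; routine verification uses
99 (199 where a p < 0.01 decision is needed, since 1/(99+1) cannot fall below
0.01).

## Biomarker interpretation

The S-plot pools all blocks of one factor model: for each feature,
cov = t_p^T x_j / (n − 1) and corr = cov / (sd(t_p) sd(x_j)) against the
*consensus* predictive score, using each block's scaled matrix with no extra
λ reweighting. Zero-variance features are excluded with a warning. Area 1
(up-regulated) requires corr ≥ 0.5 and cov at or above the 75th percentile of
the positive covariances; area 4 mirrors both signs. The thresholds are
package defaults — quadrant-based selection has no canonical cutoffs — and
are fully configurable; raising either never adds a feature (monotonicity is
tested). On the simulated screen these defaults select with precision ≥ 0.8
against ground truth and place ≥ 95% of strongly (≥ 2 SD) regulated features
in the matching quadrant.

The metabolite × factor loading matrix keeps one column per model with
empirical p below 0.05 (which, on the emulated screen, retains 17 of 19
models, dropping the two null nutrients) and one row per identified
metabolite, each cell the *mean* covariance of the metabolite's ion features
— mean rather than max for robustness to one noisy adduct. Rows are clustered
with Euclidean distance and Ward linkage; rows are sorted by label first so
the leaf order is deterministic without any seed. Heat maps use a diverging
map centered at zero so sign (up/down regulation) reads directly. A
consistency check flags hormone groups whose indicator columns are linearly
dependent (they sum to one): a metabolite showing the same strong sign for
*every* member of a family cannot be real relative regulation and is
reported, not mutated.

## Numerical and degenerate-input policy

- Constant response, fewer than 2 samples per class, all-zero kernels,
  zero-variance columns under Pareto scaling, unknown sample/feature/indicator
  names: explicit `ValueError`/`KeyError` naming the offender.
- Infeasible design requests name the violated divisibility constraint.
- Score sign is arbitrary (as in any latent-variable method); tests compare
  up to sign and S-plot orientation is made explicit where it matters.
- All randomness flows through explicit integer seeds (design run order,
  simulator, permutation draws); identical seeds give byte-identical CSVs.

## Problem sizes used for verification

Routine verification runs the simulator in reduced form — blocks of
200/180/180 features, n_perm = 99–199, at most 2 orthogonal components —
which preserves every qualitative property of the full-size configuration
while keeping a complete check of the suite fast. The acceptance script uses
a single 300-feature block with a 3-SD effect on 50 features and the full
n_perm = 1000 for the permutation target.

## Known limitations

- Binary one-vs-rest models only; no multi-class single model, no O2PLS/OnPLS
  variants, and only linear kernels (the fusion and back-projection logic
  assumes them).
- The class-assignment threshold is fixed at 0.5 per column; a max-response
  rule across a hormone family's columns is a plausible alternative and is
  not implemented.
- LOOCV accuracy on null data is slightly pessimistic (the well-known
  leave-one-out anticorrelation effect); the permutation test inherits and
  thereby neutralises this bias, but raw PA values for null factors can sit
  below the majority baseline.
- The design builder covers mixed-level screens expressible as (multi-level
  full factorial) × 2^k with four-level factors decomposed into pseudo-bits;
  it is not a general orthogonal-array catalogue, not D-optimal, and does not
  do blocking.
- Metabolite aggregation assumes the ion-feature map is given; no m/z-based
  annotation or MS/MS identification is attempted.
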