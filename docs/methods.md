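# Methods

## Synthetic cohort generator

The generator emulates one stained whole-blood tube per sample. Each
event belongs to one of twelve populations (neutrophils, seven monocyte
subsets M1–M7, mDC, pDC, and a lymphoid FILLER remainder); population
fractions come from per-condition concentration tables divided by the
condition's total leukocyte concentration.

**Concentration anchors.** The three lineage concentrations per condition
(cells/µl) are the published cohort means: healthy neutrophils 3368,
lymphocytes 2016, monocytes 561; H2 8687/1792/682; H24 9944/922/1071;
H48 8706/1296/1173; BSI 13 543/999/1040. Total WBC is their sum. Monocyte
subsets and DCs are parameterized as healthy concentrations (M2 15, M3 20,
M4 12, M5 8, M6 25, M7 6, mDC 12, pDC 6 cells/µl) times condition fold-
changes; the prose-stated anchors are matched exactly (M7 ×20 at H24 and
>×10 in BSI; M3 ×10 at H48 and ×11 in BSI; M5 ×7 in BSI; M2 ×6 at H24 and
×4 in BSI; mDC/pDC ×0.25 in BSI), and classical M1 monocytes absorb the
remainder so every condition's total monocyte concentration equals its
anchor. Fold-changes for H2 and for the LOCAL_INF condition are
interpolations and are documented in `calibration.py`; they are design
choices, not measured values.

**Intensities.** Marker fluorescence is lognormal per population ×
condition with geometric means in `calibration.py` and a default CV of
0.30 (scatter 0.12–0.15). Condition-dependent MFI shifts are
multiplicative on the healthy geometric means; anchored shifts include
neutrophil CD64 ×3 and M6 CD64 ×6 in BSI, M6 CD14 ×2 postoperative / ×4
BSI, M3/M5 CD14 ×2 at H24–H48 but ×1 in BSI, HLA-DR depression on M5/M7
through H48 and in BSI, and neutrophil CD123 elevation in BSI. Lognormal
intensities are positive and right-skewed, and make the fold-change
calibration multiplicative — both properties of real fluorescence data.

**Subject effects.** Each subject carries one mean-one lognormal
multiplicative effect per channel (and for WBC), log-SD 0.15, shared
across all of that subject's samples. This induces the within-subject
correlation across repeated postoperative time points that subject-grouped
cross-validation must respect; record-level CV on such data is leaky.

**Acquisition.** Events are recorded in stream order until 6000 true
monocyte events have been seen (hard cap 200 000 events, after which the
sample is flagged degenerate rather than rejected). WBC is drawn
lognormal with the arithmetic mean anchored to the condition's total
concentration (CV 0.20), so gated fractions × WBC recover absolute
concentrations in expectation.

**Spillover.** Default spillover is the identity; a non-trivial synthetic
8×8 example (`example_spillover`) exercises the compensation round-trip.
The original bead-derived instrument matrix is not public.

**What the generator does not emulate:** doublets, acquisition time
drift, viability artifacts, hematological-malignancy phenotypes, and —
importantly — realistic within-group variances: the published material
states fold-changes but not variances, so the CVs above are free
parameters. Passing tests therefore demonstrate that the pipeline
recovers the structure it was calibrated to, not that the score would
reach the same discrimination on real patients.

## Gating

Gating operates on arcsinh(x/150)-transformed fluorescence and raw
scatter; cofactor 150 suits the simulated intensity scale and is
configurable. MFIs are always computed on linear (compensated,
untransformed) values. The singlet gate is a 0.8–1.2 band on the
FSC-H/FSC-A ratio (no geometry was published; the generator draws the
ratio with log-SD 0.05).

Manual per-sample gate adjustment is replaced by deterministic
density-valley placement: for each designated 1D boundary (HLA-DR±,
CD91low/CD91+, CD14low/CD14+, β7−/β7+, CD16−/low and CD16low/+) the
marginal of the parent population is histogrammed (128 bins, Gaussian
smoothing σ = 3 bins) and the cut goes at the center of the deepest
near-minimal density run inside a configured search window, requiring
clearly higher density on both flanks (factor 1.2 plus 0.2% of the peak).
Without a valid valley the boundary falls back to a configured quantile
of the marginal (clipped to the window) and the sample is flagged; an
empty parent keeps the default threshold and is flagged. Thresholds are
adjusted in hierarchy order so downstream parents reflect upstream cuts.
The exact CD16low/CD16+ boundary and the monocyte-gate axes are not fully
specified in the source material; the shipped defaults document an
assumed tri-modal CD16 split without claiming fidelity.

## Features

The registry enumerates 80 MFIs (8 markers × mononuclear, neutrophils,
total monocytes, M1–M7), 9 percentages (mDC, pDC, M1–M7) and 10 counts
(mDC, pDC, total monocytes, M1–M7); the published total of 101 exceeds
this enumeration by two, so the registry adds `CNT.NEUTROPHILS` and
`PCT.MONOCYTES_TOTAL` as explicitly labelled reconciliation entries.
Percentage denominators are likewise a documented decision: monocyte
subsets relative to total monocytes, DCs relative to mononuclear cells,
total monocytes relative to all leukocytes. An MFI needs ≥ 30 events
(`min_events`); smaller populations yield MISSING, which the boosters
route natively. Absolute counts are gated-fraction × WBC and never go
missing. No MFI exists for DC subsets.

## Ensemble and score

32 XGBoost classifiers (binary logistic, 300 trees, depth 3, learning
rate 0.1, row subsample 0.8, `hist`, single thread) are each fit on a
subject-level bootstrap resample — all samples of a subject enter or
leave together, mirroring the grouped-CV argument. The published
hyperparameter optimization reports no values; these defaults are the
package's own and a grid search is deliberately out of scope.

Influence trimming follows the TreeNet convention: after an initial fit,
the ⌈0.1 n⌉ rows with predicted probability farthest from 0.5 are dropped
and the booster refit once (XGBoost exposes no per-stage exclusion hook).
The alternative literal reading — dropping rows *near* the threshold —
is available via `TrainConfig.trim_near_threshold` but not endorsed.

The printed probability formula p = e^(−2r)/(1+e^(−2r)) decreases in r,
so responses are oriented with infection on the negative half-log-odds
side (s_b = −m_b/2 with label 1 = infectious); then p equals the sigmoid
of the mean ensemble log-odds and the 0–100 score is an infection-risk
scale. p is computed with the overflow-safe logistic.

## Evaluation

Subject-grouped k-fold CV uses class-stratified grouped folds (falling
back to plain grouped folds when k exceeds the minority-class subject
count, e.g. leave-one-subject-out). Temporal binning assigns subjects to
folds within sampling-time strata. Single-class training folds are
skipped with a warning. The randomization null permutes labels across
subjects (a subject's records all change together) and re-runs the full
CV per shuffle. AUROC is trapezoidal over the empirical curve; its 95% CI
is a stratified percentile bootstrap (2000 resamples) because no analytic
CI method was specified. Operating points use the strict "positive iff
score > cutoff" convention. Mann–Whitney panels are reported without
multiple-testing correction, matching the raw p < 0.05 convention of the
source analysis.

## Importance

RVIS permutes one column at a time (default 10 permutations), measures
the mean AUROC drop of the ensemble score on the evaluation table (no
retraining — retraining is the expensive oracle used only in tests),
floors negative drops at zero and rescales so the top variable is exactly
100 (ties share 100; rank ties break by registry order). A log-loss
variant is available by flag. Partial dependence replaces the variable
with each of 25 grid values across all rows and averages the 0–100 score.

## Problem sizes and numerical choices

The shipped analyses use a 250-sample discovery-style cohort
(46/22/80/43/59), 100 healthy subjects for concentration recovery, and a
reduced ensemble (4 boosters × 60 trees) inside the 30-shuffle
randomization null; the null's location is insensitive to ensemble size
and a full-size null ensemble adds nothing but runtime. Monte-Carlo
checks compare within 3 standard errors estimated from the generated data
(delta method for ratios of means). All stochastic stages consume
explicit seeds; identical seeds give bit-identical cohorts, models and
reports.

## Known limitations

Generator CVs are free parameters, so discrimination difficulty is
tunable rather than faithful; the near-perfect synthetic AUROC reflects
the calibrated separation, not expected clinical performance. The gating
geometry reproduces the published hierarchy but not the original
instrument coordinates. Published validation-cohort operating points
(e.g. sensitivity 97% / specificity 93% at cutoff > 54.5) depend on the
original patient cohort and are consumed here only as reference cutoffs
for reporting.
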