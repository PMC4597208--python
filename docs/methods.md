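# Methods

## Overview

`crpsig` implements a biomarker-signature discovery and evaluation pipeline
for a binary clinical outcome (next-day C-reactive protein increase) from a
patient × protein abundance-ratio matrix, together with a synthetic cohort
generator that reproduces the statistical structure the pipeline assumes.
This note records the model choices, the tunable parameters and their
defaults, the numerical conventions, and what the synthetic experiments do
and do not demonstrate.

## The prediction model

### Screening and shrinkage selection

Per-protein Pearson correlations `r_p` are computed between the protein's
abundance ratio and the *continuous* CRP change (ΔCRP, mg/L), not the
binary event flag — weak but consistent monotone associations survive this
better than dichotomized screening. Selection keeps `{p : |r_p| ≥ θ}`; a
protein with zero variance gets `r_p = 0` (with a warning) and is therefore
never selected.

The threshold grid is 40 evenly spaced magnitudes from 0 to the 95th
percentile of `|r_p|`. The upper cap guarantees every grid value selects a
non-empty set; 40 points makes the grid step (~0.005–0.01 in practice)
finer than the sampling noise of `r_p` at n ≈ 90 (SE ≈ 0.1), so the grid
resolution is not the limiting factor. For each grid value the
misclassification rate of the classifier on the selected proteins is
estimated by an inner cross-validation on the training cohort — inner
leave-one-out by default (deterministic), k-fold configurable; thresholds
that select identical protein sets are evaluated once. Ties in inner error
break toward the **larger** threshold (fewer proteins, parsimony).

### Classifier

A soft-margin SVM with Gaussian (RBF) kernel at the classical package
defaults: cost C = 1 and kernel width γ = 1/P′ (P′ = number of selected
proteins) on features standardized to zero mean / unit variance using
training-fold statistics only. No hyperparameter tuning is performed — the
signature method treats the classifier as fixed and tunes only the
selection threshold. Class probabilities come from a Platt sigmoid fitted
on decision values via internal stratified 3-fold cross-validation
(`sklearn` `CalibratedClassifierCV(..., method="sigmoid", ensemble=False)`);
when a class has fewer than 3 members the fold count drops accordingly, and
with fewer than 2 a plain logistic map of the decision value is used. The
inner threshold-tuning loop uses uncalibrated SVM class labels — the error
estimate does not depend on the probability map.

### Double (nested) cross-validation

The outer loop is leave-one-out over patients. Within each outer training
fold: screening correlations are recomputed (`mode="nested"`), the
threshold is tuned by the inner loop, the SVM is refitted, and the held-out
patient receives a probability and a class (probability ≥ cutoff, cutoff =
training-fold event prevalence; a probability exactly at the cutoff counts
as an event). `mode="paper"` instead computes the screening correlations
once on **all** patients before the outer loop. This variant reproduces a
common but optimistic practice — the held-out patient's outcome then
influences which proteins the model may use — and the package's null
experiments quantify the resulting bias (below). Honest error estimation
should use `mode="nested"`; `mode="paper"` exists for comparison.

The final reported signature is fitted on the full cohort (screen → tune →
fit), with probability cutoff = events/n. Per-fold selected sets and
thresholds from the outer loop are retained for inspection, since a
full-data fit and the fold consensus can differ.

Determinism and order-invariance: patients are processed in sorted-
identifier order internally, the internal calibration folds are stratified
without shuffling, and no step draws random numbers, so permuting the rows
of the input tables changes no prediction.

## Evaluation statistics

* **Confusion metrics**: sensitivity = correctly predicted events / events,
  specificity = correctly predicted non-events / non-events, accuracy =
  correct / n, from the out-of-fold classes.
* **AUC**: rank (Mann-Whitney) estimator, ties counted ½. Variance by the
  paired placement-value (DeLong-type) estimator; 95% normal-theory CI
  truncated to [0, 1]; two-sided normal p-value against AUC = 0.5. With
  degenerate variance (perfect separation) the p-value is reported as 0 (or
  1 at AUC = 0.5) rather than NaN.
* **Per-protein AUC table**: one ROC analysis per protein, ranked, with no
  multiplicity correction — it mirrors the descriptive table it emulates
  and must be read accordingly.
* **Spearman association**: scipy's rank correlation with a Fisher-z CI
  using SE = 1/√(n−3); undefined (and signaled) for constant input.
* **Group comparisons**: Mann-Whitney with tie-corrected normal
  approximation for continuous variables (exact enumeration when both
  groups ≤ 10), Fisher's exact test for binary categories.
* **Outcome ROC for clinical endpoints** (e.g. hospitalization days
  against the signature-predicted class, or against same-day CRP above vs
  below its median): obtained by passing the endpoint as the score and the
  binary grouping as the event flag to `auc_ci`. The orientation of such a
  reconstruction is ambiguous in general; the two orientations give AUC and
  1 − AUC, so both are recoverable from either.

## Risk-model comparison (cfNRI / IDI)

The base risk model is a logistic regression of the event on donor age —
the one clinical covariate that survives backward selection in this setting
— and the extended model adds the signature score, by default the
*out-of-fold* probability (so the score itself is not optimistically
in-sample; a binary-class form is configurable). Logistic fits use
maximum likelihood (IRLS via statsmodels GLM) with Wald standard errors;
non-convergence and (quasi-)separation — slope |β| > 15 or non-finite SE —
are flagged, never silently reported. Backward selection removes the
largest-p covariate at P ≥ 0.05 until all retained p < 0.05, logging the
removal order; if nothing survives, the intercept-only fit is returned and
flagged.

For a risk pair (p_base, p_new) and a risk-change threshold t (default 0):
a patient moves *up* if p_new − p_base > t, *down* if p_base − p_new > t;
exact ties move neither way (literal reading of "increased"/"decreased").
cfNRI_events = (up − down)/events, cfNRI_nonevents = (down − up)/non-events
(both in percent), total = sum, bounded by ±200%. IDI_events = mean risk
change among events, IDI_nonevents = −(mean risk change) among non-events,
total = sum = difference in discrimination slopes (an algebraic identity
the tests assert to 1e−12). The threshold-NRI curve evaluates cfNRI on a
grid of t.

Confidence intervals: nonparametric patient-level bootstrap, stratified by
event status (so both groups stay non-empty in every resample), percentile
2.5/97.5, default 2000 replicates, seeded. An asymptotic normal alternative
(`analytic_ci`) is provided: binomial-difference SEs for cfNRI components,
mean-difference SEs for IDI.

## The synthetic cohort generator

The generator emulates the study design the pipeline targets: 91 patients,
359 proteins quantified as positive abundance ratios, 59/91 event
prevalence, 82 outcome-informative proteins whose population correlations
with ΔCRP span 0.15–0.40 in magnitude with alternating sign, and ~10%
multiplicative technical noise.

Key modelling choices:

* **Ratios are log-normal around 1** — positive support and multiplicative
  error are the natural scale for reporter-ion ratios. Biological
  between-patient variation has log-SD 0.25; technical noise is log-normal
  with CV = `noise_cv` (default 0.10).
* **Informative proteins form independent latent modules.** Dozens of
  proteins cannot each correlate with one outcome at |r| up to 0.4 while
  being mutually independent (the squared correlations of independent
  predictors sum to at most 1), so correlation structure is unavoidable.
  One global factor is the opposite extreme — it makes the signature
  perfectly redundant with its top few proteins, which degenerates
  threshold selection. The default is 8 independent modules (a stand-in for
  the major co-regulated plasma groups: acute-phase positive/negative,
  complement, coagulation, immunoglobulins, lipoproteins, protease
  inhibitors, transport proteins), with proteins assigned to modules by
  target magnitude. Each module's outcome correlation c_g is the smallest
  value compatible with its targets at a within-module loading cap of 0.9;
  feasibility requires Σc_g² < 1 (≈ 0.87 at the defaults), and infeasible
  target configurations are rejected at construction.
* **ΔCRP** is mg/L-scaled (SD 45) with the intercept solved in closed form
  so P(ΔCRP > 0) equals the prevalence target; the event flag is the strict
  inequality, ties counting as non-events. Index CRP is log-normal around
  a median of 35 mg/L and floored at 1 − min(ΔCRP, 0) so next-day CRP stays
  positive — large decreases therefore start from high baselines, matching
  the clinical pattern.
* **Covariates**: donor age (+8 years in events), deceased-donor fraction
  (19/59 events vs 21/32 non-events), dialysis duration (median 8 vs 21
  months) and hospitalization (median 7 vs 5.5 days) are drawn conditional
  on the event; the remaining covariates are outcome-independent.

What the generator does **not** emulate: correlation among non-informative
proteins, missing values (the matrix is complete by construction), batch
structure from the two patient channels per iTRAQ set, and heavy-tailed or
skewed outcome noise. Consequently, passing the synthetic experiments shows
that the pipeline recovers the kind of signal it assumes, at the study's
dimensions, under honest cross-validation — not that any particular
real-data result is correct.

## Problem sizes used by the test suite

The statistical acceptance experiments run at the following sizes, chosen
so the full suite completes comfortably on one CPU:

* signal recovery: one default cohort (91 × 359, 82 informative, seed 1);
  full-data signature with the default 40-point grid and inner
  leave-one-out; nested double CV with inner 5-fold.
* null calibration: 100 null cohorts at n = 60, p = 100, nested and
  full-data screening, 8-point grid, inner 5-fold, uncalibrated
  probabilities (a monotone map of the SVM decision value — rank statistics
  such as AUC are unchanged by this). The leakage contrast being measured
  does not depend on grid resolution or the inner scheme.
* bootstrap coverage: 100 replicates of n = 91 at 500 bootstrap
  resamples, against the population value computed on 4×10⁵ draws.
* estimator/oracle equivalences: 200 random ROC instances (n ≤ 50) against
  brute-force pairwise counting; 1000 random risk pairs for the cfNRI/IDI
  identities.

Observed behaviour at these sizes (recomputed by the suite on every run):
nested screening on null cohorts is approximately centered (mean
out-of-fold AUC ≈ 0.45–0.50 — LOOCV's slight pessimism on null data is
expected), while full-data screening on the *same* cohorts inflates the
mean AUC to ≈ 0.64: the leakage the nested default exists to avoid.

## Known limitations

* The inner loop estimates error with uncalibrated SVM labels (decision at
  0), while the outer classification uses the prevalence cutoff on
  calibrated probabilities; on strongly imbalanced training folds these can
  disagree.
* The DeLong-style placement variance is computed by a per-observation loop
  (O(n₁·n₀)); fine at cohort scale, slow for very large score vectors.
* `backward_select` uses Wald p-values, which are anti-conservative under
  separation; separation is flagged but the fit is still reported.
* The generator's module structure is a modelling idealization; real plasma
  proteomes have overlapping, hierarchical covariation.
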