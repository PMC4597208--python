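# crpsig

Plasma-protein signature discovery for predicting next-day C-reactive
protein (CRP) increase after kidney transplantation.

## The problem

CRP rises within hours of an inflammatory stimulus, so whether a transplant
recipient's CRP will be higher *tomorrow* is an early warning of a brewing
complication. Given a patient × protein matrix of plasma abundance ratios
(iTRAQ-style quantification against a pooled healthy-control channel) and
CRP measured on the index day and the next day, `crpsig` builds and
evaluates a protein signature that predicts the binary outcome

  event  =  (CRP_next − CRP_index > 0).

The package is aimed at proteomics/biostatistics practitioners who want the
full discovery-and-evaluation loop — feature selection, honest
cross-validated error, and clinical added-value statistics — as tested,
reusable code, together with a synthetic cohort generator that emulates the
91-patient / 359-protein study design for end-to-end testing without any
patient data.

## The method

**Selection and classification** (module `signature`). For proteins
*p = 1..P* compute the Pearson correlation *r_p* between abundance ratio
and ΔCRP. Shrinkage selection keeps the set {p : |r_p| ≥ θ} (PAM-style
recursive shrinkage of small correlations to zero). The threshold θ is
tuned on a grid by inner cross-validated misclassification error of a
soft-margin RBF-kernel SVM (cost C = 1, kernel width γ = 1/P′ on
standardized features; Platt-sigmoid class probabilities), with ties broken
toward the larger θ (fewer proteins). The whole procedure sits inside an
outer leave-one-out loop ("double cross-validation"): each patient is
predicted once by a model that never saw them. Predicted class = 
probability ≥ cutoff, where the cutoff is the training-fold event
prevalence (59/91 = 0.648 at the study's design size).

Two screening modes are provided: `nested` (default) recomputes the
screening correlations inside every outer training fold, so feature
selection never sees the held-out patient; `paper` screens once on all
patients, which leaks outcome information into selection — it is kept to
quantify that optimism (see `docs/methods.md`).

**Evaluation** (modules `evaluation`, `reclassification`). Sensitivity /
specificity / accuracy from the out-of-fold predictions; rank (Mann-Whitney)
AUC with DeLong-type confidence intervals; per-protein AUC tables; Spearman
associations; Mann-Whitney and Fisher's exact group comparisons; logistic
risk models with backward selection (retention P < 0.05). Added clinical
value of the signature over a base model (donor age) is quantified by the
category-free net reclassification improvement

  cfNRI_total = cfNRI_events + cfNRI_nonevents   (max 200%)

and the integrated discrimination improvement

  IDI_total = IDI_events + IDI_nonevents
            = Δ(discrimination slope),

with stratified patient-level bootstrap percentile confidence intervals.

## Worked example

```bash
crpsig run-all --seed 3 --n-patients 91 --n-proteins 359 \
    --n-informative 82 --inner 5 --out runs/demo
```

which prints (abridged; `runs/demo/manifest.json` has the full record):

```
{
 "config": {"seed": 3, "mode": "nested", "n_patients": 91, "n_proteins": 359,
            "n_informative": 82, "n_grid": 40, "inner": "5", "reps": 2000},
 "config_hash": "f1335a2e32c8a1be",
 "seed": 3
}
```

with stage outputs in `runs/demo/`: the generated cohort
(`cohort/protein_matrix.csv`, `cohort/clinical.csv`, `cohort/truth.json`),
per-patient out-of-fold probabilities (`oof_predictions.tsv`), the fitted
signature (`signature_model.json` — selected proteins, threshold,
probability cutoff), discrimination (`roc.json`, `confusion.json`) and
added-value statistics (`reclassification.json`). On this run the final
signature keeps 117 proteins; the nested out-of-fold AUC is 0.937 and
accuracy 0.879 (sensitivity 0.87, specificity 0.90) at the
event-prevalence probability cutoff; adding the signature to a
donor-age-only risk model gives cfNRI_total = 131.5% and IDI_total = 0.430
— most events are reclassified to higher risk and most non-events to lower
risk once the protein signature enters the model. Exact numbers are
seed-dependent; rerunning the command reproduces them exactly.

The same stages are available individually (`crpsig simulate`, `fit`,
`evaluate`, `reclassify`) for use with your own CSV matrix and clinical
table; see `crpsig --help`.

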