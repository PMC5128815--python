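# seqdx — sequencing-based breast cancer diagnostics

`seqdx` implements an RNA/DNA-sequencing-based diagnostic workflow for
primary breast cancer as a tested, reusable Python library: it predicts the
status of the routine biomarkers (ER, PR, HER2, Ki-67) from bulk RNA-seq
expression, derives a composite **transcriptomic grade** (TG) as an
alternative to histological grading, assigns intrinsic molecular subtypes
with a nearest-shrunken-centroid classifier over a PAM50-style gene panel,
calls gene-level copy-number status (the ERBB2/HER2 locus in particular)
from low-pass whole-genome binned read counts, encodes the clinical status
rules and re-examination concordance logic used in routine pathology, and
matches somatic alterations to an actionability knowledge base with
approved > late-phase > early-phase priority.

It is aimed at people building or evaluating molecular diagnostics
pipelines who need the statistical machinery — not the wet lab: the
package consumes expression matrices, clinical tables, alteration tables
and binned read counts, and ships a synthetic cohort generator that
emulates the data structure of a diagnostic study so every stage is
testable end-to-end without patient data.

## The models

* **Receptor status.** For marker M ∈ {ER, PR, HER2} with marker gene g
  (ESR1, PGR, ERBB2), a univariate logistic regression
  `logit P(M = +) = β₀ + β₁ x_g` on log2-CPM expression. Ki-67 percent is
  modeled by a linear elastic net over all genes (mixing weight α = 0.5,
  penalty λ tuned by inner cross-validation).
* **Performance estimation.** Nested cross-validation (5 outer × 5 inner
  stratified folds): every sample is scored by a model whose training and
  tuning never saw it. ROC curves, trapezoidal AUC, DeLong variance and
  confidence intervals, and unpaired DeLong AUC comparison between
  cohorts. The decision boundary is the ROC point with minimal Euclidean
  distance to the top-left corner.
* **Transcriptomic grade.** Three binomial elastic nets, one per
  Nottingham grade subcomponent (mitotic count, nuclear atypia, tubular
  formation), each trained on tumors scored 1 or 3 for that component;
  the TG score is ŷ_mitotic + ŷ_nuclearity + ŷ_tubularity ∈ [0, 3], with a
  low/high boundary placed on nested-CV scores of grade 1 vs grade 3
  tumors. Grade 2 tumors are then reclassified into low/high TG.
* **Subtyping.** Nearest shrunken centroids: standardized class-vs-overall
  differences d_ik soft-thresholded by Δ, discriminant
  δ_k(x) = Σᵢ (xᵢ − x̄'ᵢk)²/(sᵢ + s₀)² − 2 log π_k over
  {Basal, LumA, LumB, Her2} (Normal-like excluded).
* **Copy number.** Per-bin ratio of library-size-normalized tumor vs
  baseline counts; gene calls are overlap-weighted mean ratios with
  categories deep deletion (< 0.6), neutral, low-grade amplification
  ([1.8, 3.0), "ratio close to two") and high-grade amplification (≥ 3.0).

## Worked example

```python
from seqdx import (CohortConfig, generate_cohort, normalize_log_cpm,
                   ModelSpec, nested_cv_scores, auc_score)

cohort = generate_cohort(CohortConfig(n_samples=400, marker_shift=2.0,
                                      noise_sd=1.0, seed=0))
m = normalize_log_cpm(cohort.expression)
labels = cohort.clinical["er_status"]
scores, folds = nested_cv_scores(
    m, labels, ModelSpec(kind="single_gene_logistic", gene="ESR1"), seed=0)
print(round(auc_score(scores.to_numpy(), labels.to_numpy()), 3))
```

This prints `0.906`: the cross-validated AUC for recovering ER status from
ESR1 expression in a cohort simulated with a 2 log2-unit expression shift
between ER-positive and ER-negative tumors under unit log-scale noise —
i.e. the model recovers the simulated receptor signal almost perfectly,
with the residual gap set by the configured noise.

The same workflow is available from the shell:

```bash
seqdx simulate --n-samples 200 --seed 0 --outdir cohort/
seqdx markers --expression cohort/expression.tsv --clinical cohort/clinical.csv \
      --seed 0 --outdir markers/
seqdx concordance --outdir concordance/
seqdx run-all --seed 0 --outdir report/
```

`seqdx concordance` reproduces the re-examination concordance of the
packaged discordant-case table: of patients whose sequencing-based call
disagreed with the medical record, 6 of 10 re-examined ER cases (60%) and
2 of 6 re-examined HER2 cases (33%) were reclassified by pathology
re-examination to agree with the sequencing-based call.

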