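# Methods

This note documents the statistical procedures implemented in `seqdx`,
the choices made where the design was genuinely open, and what the
synthetic cohorts do and do not establish about real data.

## Expression handling

Expression matrices are genes × samples. Raw abundances are normalized to
`log2(1e6 · x / sample_total + 1)` (log2-CPM with a +1 offset) before any
modeling. The normalization was an open choice — the upstream
quantification pipeline's output units are not prescribed — and log2-CPM
was chosen because it is standard, monotone, invariant to library-size
scaling, and sufficient for the rank-driven classifiers used here. A
`scale` marker (`raw`/`log2`) travels with every matrix so models cannot
be fed the wrong scale; all model-fitting entry points assert `log2`.

## Receptor-status models

ER, PR and HER2 status are modeled by univariate logistic regression on
the log2-CPM expression of the corresponding gene (ESR1, PGR, ERBB2),
fitted by Newton/IRLS with a ridge penalty of 1e-8 on the slope. The
ridge is a separation guard: on perfectly separable data the maximum
likelihood estimate diverges, and the tiny penalty yields finite
estimates while being numerically invisible (≤ 1e-6 effect) away from
separation. The predictor is centered internally for conditioning.

Ki-67 is continuous (percent positively stained cells) and is modeled by
a linear elastic net over all genes; its predictions are evaluated as a
classifier against the ≥ 20% "high" labels through the same ROC
machinery as the binary markers.

## Elastic net

The penalized models minimize the glmnet-parametrized objective
(1/n)·loss + λ(α‖β‖₁ + (1−α)/2·‖β‖₂²) with α = 0.5 throughout.
Predictors are standardized internally (population SD; zero-variance
genes get coefficient 0) and coefficients are returned on the original
scale. Numerically:

* **Linear family:** scikit-learn's coordinate-descent `ElasticNet`
  (identical parametrization, `alpha` = λ).
* **Binomial family:** penalized IRLS — outer Newton steps on the
  log-likelihood, each solving a weighted elastic-net least-squares
  subproblem (working response z = η + (y − μ)/w, weights w = μ(1 − μ)
  rescaled to sum to n) with the same coordinate-descent solver,
  warm-started across IRLS iterations and across the λ path. Fitted
  probabilities are clipped to [1e-5, 1 − 1e-5]; if coefficients exceed
  10³ on the standardized scale the fit is treated as saturated
  (separation) and iteration stops.

λ is selected on a log-spaced grid descending from λ_max (the smallest λ
that zeroes every gene coefficient, computed in closed form from the
standardized gradient at the null model) down by a factor of 1e-4 when
n > p and 1e-2 when p ≥ n, following the glmnet convention — in the p ≥ n
regime the far tail of the path only produces saturated, separable fits.
The grid holds 50 values by default; cohort-level analyses in this
package use 20, which is past the point where the selected λ stabilizes
here. Selection minimizes mean inner-CV deviance (squared error for the
linear family), ties preferring the larger, more parsimonious λ; the
model is then refit on all provided data at the selected λ. The path
also exits early once the training deviance falls below 1% of the null
deviance, after which smaller λ values only overfit.

## Nested cross-validation

Performance is always estimated with nested CV: stratified 5-fold outer
resampling provides out-of-fold scores from models whose training and λ
tuning (inner 5-fold, on outer-training data only) never saw the scored
sample. Fold assignment is deterministic given the seed. Fold counts are
a package choice; 5×5 balances bias and cost at cohort sizes of a few
hundred. Classification models contribute probabilities as scores, the
linear Ki-67 model its predicted percent.

## ROC machinery and DeLong comparison

ROC curves have one step per distinct score value (ties grouped) with
endpoints (0,0) and (1,1); AUC is the trapezoidal area, which equals the
fraction of correctly ranked (positive, negative) pairs with half credit
for ties. The operating point is the curve point with minimal Euclidean
distance to (0,1); exact distance ties resolve to the lower
false-positive-rate point (the more conservative call).

AUC variance uses DeLong placement values: var = S₁₀/m + S₀₁/n with
sample variances of the per-positive and per-negative placements. Two
independent cohorts are compared with z = (AUC₁ − AUC₂)/√(var₁ + var₂)
against a standard normal, two-sided. (R's pROC agrees with the AUCs and
z to 1e-9 but refers the unpaired statistic to a t distribution; the
normal reference is used here and reported p-values are labelled
accordingly.) Confidence intervals are DeLong-based normal intervals.

## Transcriptomic grade

Three binomial elastic nets, one per Nottingham subcomponent (mitotic
count, nuclear atypia, tubular formation), each trained only on tumors
scored 1 or 3 for that component (event = score 3); the count of excluded
score-2 tumors is recorded on the fitted model as an audit field. The TG
score is the sum of the three predicted probabilities, so it lies in
[0, 3] by construction. Components are probabilities (rather than linear
predictors) so the three contributions are bounded and comparable — an
open choice, made for interpretability of the summed score.

The low/high boundary is placed with the ROC operating-point rule on
summed scores of histological grade 1 vs 3 tumors. Those scores come from
a dedicated nested CV in which all three component models are refitted
within each outer fold, so the boundary is set on predictions from models
that never saw the scored tumor; setting it on refit (resubstitution)
scores would bias it optimistically. Scores exactly on the boundary are
called low (conservative toward lower grade).

## Subtyping

Nearest shrunken centroids over a packaged 50-gene intrinsic-subtype
panel and four classes (Basal, LumA, LumB, Her2); the Normal-like class
is excluded. Training computes per-gene pooled within-class SDs s_i, the
fudge constant s₀ = median(s_i), standardized differences
d_ik = (x̄_ik − x̄_i)/(m_k (s_i + s₀)) with m_k = √(1/n_k + 1/n), and
soft-thresholds them by Δ. The m_k convention follows the published
description of the classifier; the √(1/n_k − 1/n) variant used by some
implementations is available behind a switch. Class priors default to
empirical frequencies and Δ defaults to 0 (no shrinkage); published
centroid values are not redistributed, so centroids are always estimated
from caller-supplied training data. Classification minimizes
δ_k(x) = Σᵢ (xᵢ − x̄'ᵢk)²/(sᵢ + s₀)² − 2 log π_k, ties resolving in the
fixed class order above.

## Copy-number calls

Tumor and baseline binned read counts on a shared grid are library-size
normalized and compared bin-by-bin; bins with zero baseline count are
flagged and excluded. Gene calls average the ratio over overlapping bins,
weighted by overlap length, and categorize with half-open thresholds
0.6 / 1.8 / 3.0 (deep deletion / neutral / low-grade amplification /
high-grade amplification). The thresholds reproduce the qualitative
"low-grade amplification, ratio close to two" vs "high-grade" distinction;
no published cutoffs exist for this assay, and they are package constants,
not fitted quantities. No segmentation and no tumor-purity correction are
applied; the matched-grid baseline is a deliberate simplification of
low-pass CNV pipelines.

A practical caveat: because ratios are library-size normalized, an
amplified segment that is a non-trivial fraction of the binned genome
deflates its own normalized ratio (a 450 kb amplicon in a 6 Mb toy grid
costs ~8%, pushing a true ratio 2 to ~1.85). With genome-scale grids
(≥ ~40 Mb here) the effect is negligible.

## Clinical rules and concordance

ER/PR: positive at ≥ 10% IHC staining, or > 0.05 fmol/ug DNA by
radioimmunoassay for older samples; IHC is preferred when both exist.
HER2: in-situ hybridization decides when present; otherwise IHC 3+ is
positive. Ki-67: high at ≥ 20%, the threshold value itself counting as
high (inclusivity was unspecified; the inclusive reading is used and
documented here). Categorical "high"/"low" records pass through.

Re-examination concordance counts, per marker, the distinct re-examined
patients and those *reclassified and concordant*: a patient qualifies
when **any** re-examined tumor piece has a re-examined status that
differs from the medical record and equals the sequencing-based call.
Multi-piece patients count once. The any-piece rule matters for patients
whose two pieces disagree on re-examination and is the documented
convention of this package. The packaged discordant-case table is a
verbatim transcription, including NA cells, and reproduces 6/10 (ER) and
2/6 (HER2).

## Actionability matching

Somatic SNVs, indels, amplifications and deep deletions match
knowledge-base entries on gene + alteration class; protein-level hotspot
matching is deliberately not required. Germline events are never matched
(they surface only through the BRCA1/2 flag, annotated somatic vs
germline). The breast-only scope excludes the ERBB2-amplification entry,
which routine IHC/ISH already captures. Entries may carry a HER2-positive
co-requirement (combination trials); they match only patients with a
positive recorded HER2 status. Per-patient counting keeps the single
highest-priority match (approved > late > early), ties broken by
(gene, therapy) lexicographic order. The packaged 15-entry knowledge base
is schema-true but illustrative; it is not a redistribution of any
curated database.

## Group statistics

The subtype-distribution comparisons use a two-sided Fisher exact test on
2 × k tables (k ≤ 5), computed by full enumeration: with margins fixed,
the p-value sums the probabilities of all tables no more probable than
the observed one (log-space comparison with a 1e-7 slack for float ties;
the last free cell is vectorized, so 2 × 4 tables with a few hundred
counts enumerate in well under a second). Mean comparisons use the Welch
two-sided t-test. All p-values are reported raw and labelled unadjusted.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes:

* log2-scale Gaussian expression around per-gene baselines
  (Uniform(3, 9)), exponentiated to abundances;
* marker genes shifted by `marker_shift` (default 2.0 log2 units) in
  status-positive tumors; statuses drawn with prevalences ER 80%, PR 70%,
  HER2 15%, Ki-67 50% — typical of unselected breast-cancer cohorts;
* per-gene noise `noise_sd` (default 1.0 log2 units);
* three disjoint 30-gene programs whose means scale linearly with the
  1–3 subcomponent scores at `grade_effect` (default 1.5) log2 units per
  score step; subcomponent scores jitter around a latent grade
  (80% same, 10% one step either way) and the overall grade is the
  Elston–Ellis-like binning of their sum (3–5 → 1, 6–7 → 2, 8–9 → 3);
* the optional `grade2_mixture` mode replaces the intermediate score-2
  program level with a per-sample 50:50 mixture of grade-1-like and
  grade-3-like levels, modeling grade 2 as an unresolved mixture rather
  than a true intermediate;
* subtype structure: per-class Gaussian centroid offsets (SD 1.0) on the
  non-marker panel genes; marker genes carry their receptor-status shift
  instead, so receptor signal and subtype signal are separable;
* Ki-67 percent as a logistic transform (slope 2 per log2 unit, centered
  between the negative and positive MKI67 means) of MKI67 expression,
  scaled to 0–100% — noisy and imperfectly concordant with the latent
  status, like the clinical assay;
* low-pass CNV bins (default 1000 × 100 kb, ~500 reads per bin, the
  depth of 0.5× coverage with 100 bp reads) Poisson-distributed, with a
  450 kb ERBB2-spanning amplicon at `erbb2_amp_ratio` (default 2.0) in
  HER2-positive tumors; the bin grid is anchored to always cover the
  locus;
* recorded ER/PR/HER2 labels equal the molecular truth except for a
  `discordance_rate` fraction flipped uniformly at random (one named
  stream per use, exact count per marker);
* a small alteration table (PIK3CA 30%, linked FGF3/FGF4 amplification
  14%, TOP2A 8%, rare ERBB2 SNVs restricted to HER2-negative tumors,
  rare somatic/germline BRCA1/2) for the actionability stage.

All randomness flows from one seed through named `SeedSequence`
sub-streams; identical configurations give byte-identical cohorts.

What passing on these cohorts shows: the estimators recover the signals
they target at the configured strengths, are calibrated under the null,
and agree with independent brute-force oracles. What it does not show:
performance on real tumors — the generator has no gene–gene correlation
beyond its block structure, no compositional or batch effects, no
zero-inflation, no purity variation, and its subtypes are exact Gaussian
centroid classes. Reported AUCs on synthetic cohorts characterize the
implementation, not the biology.

## Problem sizes and determinism

Cohort-level analyses in this repository use n = 400–500 samples with 500
genes, 20-value λ grids and 5×5 nested CV; DeLong calibration uses 1000
replicate cohort pairs of n = 100, and CNV recovery 200 replicate
profiles of 1000 bins — sizes at which every quantity is stable to well
within the tolerances asserted, while a full run stays in the minutes
range on one CPU. The pipeline expands a single global seed into
per-stage streams, so any stage can be re-run in isolation and
re-running an identical configuration reproduces every reported number.

## Known limitations

* The elastic-net gene signatures are refitted per cohort; no attempt is
  made to reproduce any published fixed gene signature or centroid set.
* The single-gene receptor models ignore all other genes by design;
  multivariate receptor models are out of scope.
* CNV calling has no segmentation, no purity/ploidy model, and a
  simplified matched-grid baseline.
* The Fisher enumeration is exact only for 2 × k tables with k ≤ 5.
* The actionability knowledge base is a toy; results with it demonstrate
  the matching logic, not clinical coverage.
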