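# Methods

This note documents the model implemented by `sbcln`, its assumptions, the
parameters that matter, and the numerical and design choices made where the
method left room.

## The classification model

The classifier targets six small B-cell lymphoid neoplasm (SBCLN) entities
— CLL/SLL, cMCL, FL, nnMCL, MZL, LPL/WM — from targeted digital expression
counts, with nonmalignant biopsies as an explicit control class and an
"undetermined" rejection option. Multiclass discrimination is decomposed
into a **cascade of one-vs-rest binary random forests**:

* **Step order.** Entities are ordered by ascending Davies–Bouldin index
  computed on the normalized candidate-gene matrix:
  S_e is the mean Euclidean distance of entity-e samples to their centroid,
  and D_e = max over other entities f of (S_e + S_f) / ‖μ_e − μ_f‖. A lower
  D_e means the entity separates more cleanly from its hardest neighbor, so
  it is discriminated earlier. Ties break alphabetically. Control samples
  are excluded from the index. Coincident centroids of two entities are an
  error, not a silent infinity. A forced order (including the published
  six-entity order CLL/SLL → cMCL → FL → nnMCL → MZL → LPL/WM) can be passed
  instead.
* **Step training.** Each step fits a binary random forest (scikit-learn,
  standard parameters: 100 trees, √p features per split, unlimited depth,
  fixed per-step seed) of target entity vs **all** other samples — other
  entities plus every control. The rest class is static along the cascade;
  whether earlier-called entities should drop out of later rest classes is
  ambiguous in principle, and the static choice is the reproducible one.
* **Marker refinement.** Candidates are ranked by the forest's Gini
  (impurity-decrease) importance; genes whose mean normalized expression in
  the target is not above the rest mean are discarded ("upregulated only"),
  the top k survivors are kept and the forest is retrained on them. Default
  k per entity follows the published model (CLL/SLL 5, cMCL 6, FL 8,
  nnMCL 4, MZL 6, LPL/WM 7); a fixed integer or an automatic per-step
  search (leave-one-out Youden index over k ∈ [3, 10]) is available for
  novel panels. Note the published text says "LPL/WM with 6 markers" while
  its own gene table lists 7; 7 is the count consistent with the published
  35-gene total (CCND1 being the one gene shared between the two
  mantle-cell steps), so 7 is used here.
* **Prediction.** A sample walks the cascade; the probability of the target
  at each step is the fraction of trees voting for it, and the first step
  with p ≥ 0.5 (boundary inclusive) names the entity. If no step fires the
  sample is *undetermined*. This gives specificity by construction: an
  out-of-distribution sample is rejected, never forced into an entity.
* **Leave-one-out evaluation.** Each sample is predicted by a cascade whose
  forests are refit without it. Marker sets and step order are frozen from
  the full fit by default — full per-fold re-selection is available behind
  a flag but is combinatorially heavier and rarely changes the sets; the
  frozen variant is therefore the default and is what the accuracy figures
  in this repository mean. Step forests within a fold are fitted lazily:
  once a step fires for the held-out sample, later steps are not needed.

## Normalization

Counts are normalized per cohort against the geometric mean of a
housekeeping set: factor f_s = reference / (housekeeping geometric mean of
sample s), value = log2(count · f_s + 1). The +1 pseudocount keeps zero
counts finite; it is the standard choice for count data. The reference
defaults to the cohort's arithmetic mean of per-sample housekeeping
geometric means, which keeps values on the raw-count scale. Any fixed
reference differs from it only by a constant log2 shift shared by all
samples of the cohort, which cancels in every rank- or difference-based
downstream step; with the default (data-dependent) reference, rescaling one
sample's library moves the cohort reference slightly and hence shifts all
values by that common constant, while a user-pinned reference makes
normalized values exactly invariant to per-sample library scaling. Cohorts
(e.g. training vs validation) are normalized strictly independently.

Housekeeping candidates are ranked by the geNorm stability value
M_g — the mean over partner candidates k of the standard deviation (ddof 1)
across samples of log2(c_g / c_k); a constant ratio gives M = 0. The final
set drops candidates with geometric-mean count < 64 or coefficient of
variation > 0.5 and keeps the k = 4 lowest-CV survivors (ties by input
order). All three thresholds are configurable; the defaults encode "well
expressed, stable" for NanoString-scale counts, where a ~4-gene reference
set is customary. The classic iterative-exclusion geNorm variant is
available as a separate function.

## Marker screening

Differential expression runs on the normalized log2 matrix with one-vs-rest
or one-vs-one contrasts. The per-contrast statistic is a Welch t-test
(robust to unequal group variances); a global one-way ANOVA F across all
groups is reported alongside, since both views are conventional for
multi-entity panels. Benjamini–Hochberg FDR is applied within each
contrast. Selection requires |log2FC| > 1 **and** FDR < 0.05, both strict
inequalities. Groups where both sides are exactly constant short-circuit to
p = 1 (equal means) or p = 0 (unequal) rather than dividing by zero.
Candidate panels are the union of DE-selected genes (ordered by best FDR)
and literature supplements, deduplicated.

Clustering feasibility — "does unsupervised structure track the entities at
all?" — is measured by Ward/Euclidean agglomerative clustering cut into a
chosen number of branches; a sample is appropriately clustered when its
branch's majority label matches its own. Majority-label membership is one
reasonable operationalization of a visual dendrogram judgment; linkage and
metric are configurable.

## Evaluation and purity calibration

With a rejection option, this package follows the operational definitions:
**sensitivity** = correct / all samples, **specificity** = correct /
assigned samples. An undetermined call therefore costs sensitivity but not
specificity; with nothing assigned, specificity is explicitly undefined
rather than zero.

Tumor-cell content ρ dilutes the malignant signal, so per-entity minimal
content cutoffs ρ\*_e are calibrated: the smallest observed content c such
that strictly more than 90 % of the entity's samples with ρ ≥ c have
true-entity probability strictly above 0.5. The scan runs over observed
content values by default (a fixed grid is available); if no value
qualifies, the maximum observed content is returned flagged "not
attainable". Cumulative sensitivity/specificity curves recompute both
metrics on every suffix subset {ρ ≥ t}. Group accuracy comparisons (e.g.
FFPE vs fresh-frozen) use a two-sided Fisher exact test; a degenerate 2×2
table returns p = 1 with a flag.

## Genetic-marker integration

Four lesions supplement expression: IGH-BCL2 → FL, MYD88 L265P → LPL/WM,
EZH2 Y646 → FL, and BRAF V600E → HCL. The first three only rescue
*undetermined* samples by default — the conservative reading, since the
method's published behavior for marker-vs-confident-call conflicts is not
fully traceable; BRAF V600E always overrides because HCL has no expression
step at all, so the expression model cannot be "right" about it. Both
precedences are configurable per rule. When several markers are positive,
one rule fires by specificity order BRAF > MYD88 > IGH-BCL2, with a
warning. A candidate rule is admitted into the combined model only if,
applied alone, it correctly reclassifies at least 2 cases.

Variant tables are consumed pre-annotated; the filter keeps exonic
nonsynonymous or splice-site variants with ≥ 20 supporting reads whose
population frequency is ≤ 1e-4 or that carry a lymphoma-relevance flag. No
external database is queried.

## The synthetic cohort generator

The simulator emulates exactly the structure the classifier assumes:

* each entity upregulates a private block of marker genes (default 8) by a
  log2 effect size (default 2.0) over a shared background (default 60
  genes, baseline mean 100 counts);
* housekeeping genes (default 6, mean 500) are flat across classes;
* every sample carries a log-normal library factor (sd 0.3 on the natural
  log — ≈ 35 % CV, a realistic library-size spread);
* counts are negative binomial with size r = 20 (variance μ + μ²/r), i.e.
  mildly overdispersed; the true dispersion of the real assay is unknown,
  so r is an explicit free parameter;
* tumor purity ρ mixes the entity mean with the background mean linearly
  *before* sampling — a bulk mixture at the mean level; read-level mixing
  would be an equivalent alternative and is not implemented;
* genetic markers are independent Bernoulli draws at entity-conditional
  prevalences (IGH-BCL2: 0.80 in FL / 0.03 elsewhere; MYD88 L265P: 0.90 in
  LPL/WM; BRAF V600E: 0.90 in HCL; 0.05 otherwise; controls negative);
* entities listed as signature-less (HCL, other_SBCLN) get background
  expression only — they are visible to genetics, invisible to expression.

Defaults (6 entities × 20 samples, 40 controls, 74 endogenous + 6
housekeeping genes) are the study conditions used throughout the tests and
the acceptance script: panel-scale data at desk cost. What passing tests on
this generator shows is that the *method* behaves as designed under its own
assumptions — marker recovery, rejection of diluted or out-of-distribution
samples, monotone purity degradation. It does **not** show performance on
real cohorts: the generator has no batch effects, no FFPE degradation, no
correlated background biology, no class-dependent library sizes, and
disjoint marker blocks are cleaner than real signatures.

## Numerical choices and degenerate inputs

* Probabilities are tree-vote fractions, so a 100-tree forest has 1 %
  granularity; the p = 0.5 boundary is inclusive by definition.
* All randomness flows from explicit seeds (per-step seeds are base + step
  index); fixed seed ⇒ bit-identical models, probabilities and files.
* geNorm requires ≥ 2 candidates and positive counts (a pseudocount rescues
  zeros); zero housekeeping geometric means name the offending sample.
* Gini importances are normalized to sum to 1 per step; an all-zero
  importance vector (constant features) is left unnormalized.
* DBI with coincident centroids raises with a diagnostic rather than
  returning infinity.
* Model bundles are joblib archives with an explicit format version;
  truncated or mismatched files raise immediately.

## Problem sizes used in this repository

Leave-one-out on the default cohort (160 samples, 6 steps) refits on the
order of 600 forests and takes ≈ 1 minute on one CPU; the 10-seed recovery
and accuracy study in the test suite and acceptance script is the dominant
cost (≈ 13 minutes). The purity sweep uses 54 entity samples per stratum at
ρ ∈ {0.9, 0.7, 0.5, 0.3}. These sizes are the package's chosen study
conditions, matched to the generator defaults above.

## Known limitations

* The expression model cannot represent HCL or rarer SBCLNs; they enter
  only through genetic rules (and the simulator's signature-less classes).
* Frozen-marker LOO slightly understates selection variance compared to
  full nested re-selection (available behind a flag).
* The operational specificity is not the epidemiological true-negative
  rate; comparisons with other tools must use matching definitions.
* The simulator's independence assumptions (genes, markers, library sizes)
  are idealizations; real-data calibration of dispersion and effect sizes
  requires a real cohort.
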