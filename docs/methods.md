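# Methods

## Scope and data model

The package analyzes SRM-style targeted-proteomics tables: features
(peptides or proteins) × samples, non-negative absolute amounts or
intensities, with an explicit missing marker.  Missingness is treated as
missing-not-at-random (MNAR): a cell is absent because the analyte fell
below what the instrument quantifies, so missing is never coerced to
zero and imputation is detection-limit-aware.  Clinical annotations
carry cohort membership, group (healthy-control batches HC1/HC2, tumor
Stage I–IV), age, sex, overall-survival time and event indicator, an
optional curative-resection flag, and an eligibility flag.  Eligibility
is supplied as data rather than derived, because real eligibility
criteria are protocol-specific; the pipeline simply excludes ineligible
patients.

## Stage 1: candidate screening

* **Quantification limit.**  Present values below the configured limit
  (default 1500 intensity units) are censored to missing before any
  statistics.  The operation is idempotent and monotone in the limit.
* **MWW screen.**  Two-sided Mann–Whitney–Wilcoxon per feature in three
  comparisons (Stage I vs HC1, Stage IV vs HC2, Stage I vs Stage IV) on
  present values only.  With both groups ≤ 8 observations the exact
  permutation null is enumerated (midranks, so ties are handled
  correctly — shift-algorithm "exact" methods are not used because they
  assume no ties); otherwise the normal approximation with tie and
  continuity correction.  A comparison whose group is empty for a
  feature is marked not computable and the screen continues.  Raw
  p < 0.05 is the selection rule — the screen is a candidate generator,
  deliberately uncorrected for multiplicity; a feature is selected if
  *any* of the three comparisons is significant (the per-comparison
  provenance letters are the scientific output, linking candidates to
  early diagnosis vs progression contrasts).
* **Fold changes** per comparison are ratios of geometric means of
  present values, matching the log-scale display convention.
* **Unsupervised random forest.**  The synthetic contrast class permutes
  each feature column independently; a forest (default 1000 trees)
  classifies real vs synthetic, feature importance is mean impurity
  decrease (permutation importance available), and proximity is the
  fraction of trees in which two real samples share a terminal node.
  Note a structural property of this construction: it detects
  *dependence* among features, so a lone marker that is independent of
  everything else is invisible to it (permutation reproduces an
  independent joint distribution exactly).  Group structure expressed
  across several proteins — the realistic case — is detected.  Missing
  cells are imputed by the half-minimum rule before fitting, consistent
  with stage 2.
* **MDS.**  Classical (Torgerson) scaling of 1 − proximity: double-center
  the squared dissimilarities, take the top two eigenpairs, clip
  negative eigenvalues.
* **Assembly.**  Selected set = MWW-selected ∪ top-50 importance of the
  patient-only forest ∪ top-50 of the patients-plus-controls forest,
  with provenance accumulated and counts reported at feature and
  protein level (peptides collapse to proteins by the mean of present
  peptides, the conventional SRM roll-up).

## Stage 2: consensus subtyping

* **Imputation.**  `half_min` (default): per feature, missing ← half the
  minimum present value.  Alternatives: `min`, and `knn` (feature-space
  k-nearest-neighbour average, k = 5, log scale).  Features with no
  present value in the analyzed sample set are dropped and reported, not
  imputed.
* **Standardization.**  log2, then per-feature z-score.  Abundances span
  orders of magnitude; without standardization Euclidean distances would
  be dominated by the most abundant proteins.
* **Resampling.**  For each k in the configured range (default 2–8) and
  each of `n_resamples` rounds (default 1000; 250 in the test and
  acceptance runs, which is ample for a 110-sample cohort), ⌈0.8·n⌉
  samples are drawn without replacement and partitioned by the inner
  clusterer — k-means with 10 restarts by default (fast, seedable),
  Ward agglomeration or a user callable as alternatives.  Co-clustering
  and co-draw counts accumulate; the consensus index is their ratio.  A
  pair never co-drawn is an error advising more resamples.
* **PAC and k selection.**  PAC = CDF(x2) − CDF(x1) of the
  upper-triangle consensus indices with (x1, x2) = (0.1, 0.9); the CDF
  uses "≤", so entries exactly at x1 are excluded and entries at x2
  included.  The k minimizing PAC is selected, ties toward the smaller
  k (preferring the more parsimonious subtype structure).
* **Final labels.**  Average-linkage agglomerative clustering of 1 − M
  cut at the chosen k; clusters are numbered by decreasing size so
  "subtype 1" is stable across seeds.

## Survival and markers

* Kaplan–Meier, two-group log-rank and Cox regression are computed with
  lifelines; Cox uses Efron tie handling (day-resolution times tie
  often).  Constant or collinear covariates and missing values are hard
  errors naming the offending columns.  Protein covariates enter on
  log2 scale.  A stage-IV-only refit is a pipeline option.
* **Median split**: "above the median" is strict; ties at the median go
  to the low group.
* **Volcano screen** between the two major clusters: fold change of
  geometric means and MWW p, both thresholds strict (FC > 2, p < 0.05).
  In the end-to-end pipeline the comparison is oriented so the cluster
  with the higher event rate is the numerator — "up" proteins are those
  elevated where survival is worse, which is the clinically meaningful
  direction; the orientation is recorded in the run summary.
* **Correlation network**: Pearson on log2 values (default) or Spearman
  over all protein pairs, Benjamini–Hochberg adjustment, edges kept at
  q < 1e-4 (positive correlations only by default), optionally
  restricted to edges touching the volcano-up focus set.

## Synthetic cohorts

The generator emulates the data-generating process the analysis assumes:

* per-protein baselines log-uniform over 1e3–1e6 (a wide SRM dynamic
  range); sample values are baseline × exp(N(0, σ)) with
  σ = √log(1 + CV²), CV defaulting to 0.3 — a typical biological
  coefficient of variation for plasma proteins (the motivating panel
  reports none);
* 12 of 99 proteins elevated ×2.5 in latent subtype 1 of the
  110-patient cohort (subtype proportions 0.4/0.6), and ×2.5 in
  Stage IV samples of the 59 + 59 screening cohort (progression-marker
  emulation; the spec-level group sizes 30/29/15/15/14/15 reproduce the
  59 patients + 59 controls design);
* MNAR censoring at an absolute detection limit (default 1800, giving
  roughly 8–10% missing cells concentrated in low-abundance proteins);
* exponential survival with hazard 1/1000 per day times 2.5 for
  subtype 1, and independent uniform administrative censoring whose
  horizon is solved numerically so the expected censored fraction
  matches the target (default 30%);
* curative resection among Stage IV patients is more likely in the
  favorable subtype (0.70 vs 0.45), giving the Fisher test something
  realistic to measure.

What the generator does *not* emulate: peptide-level interference,
batch effects, correlated noise between non-planted proteins, informative
censoring, or stage–hazard confounding.  Passing recovery tests
therefore demonstrate that the machinery is correct under its stated
model, not that the pipeline is robust to every artifact of real plasma
data.

The returned truth object (planted labels, planted protein set, true
log hazard ratio, detection limit, seed) is sufficient to score every
stage: ARI for clustering, sensitivity/false-positive rate for the
volcano, and β̂ against log 2.5 ≈ 0.916 for Cox.

## Numerical choices and degenerate inputs

* All randomized stages draw from children of one seed sequence, so the
  pipeline summary is byte-identical across reruns and stages are
  individually reproducible.
* Exact MWW enumeration is limited to groups of ≤ 8 (worst case
  C(16, 8) = 12 870 assignments); the two-sided exact p doubles the
  smaller tail via the symmetric-deviation rule, which gives p = 1 for
  identical groups.
* Zero-variance features are left centered (not scaled) before
  clustering; zero-variance proteins make their correlation pairs
  not-computable rather than raising.
* Degenerate median splits (all values identical), empty survival
  groups, all-missing features, and out-of-range configuration values
  are hard errors; zero-event log-rank comparisons return a
  not-computable marker so batch screens continue.

## Test and acceptance problem sizes

The validation suite runs the planted default scenario (99 proteins,
110 patients) over 20 generator seeds with 250 consensus resamples and
k ∈ 2–6, 200-replicate null calibrations for the MWW screen, log-rank
test and FDR control, and exhaustive-enumeration oracles for the
consensus matrix (8 samples, all 28 size-6 subsets), the exact MWW test
(all group sizes ≤ 6) and Benjamini–Hochberg (100 random vectors).
These sizes were chosen so the full suite completes in minutes while
keeping every binomial acceptance band meaningful.

## Known limitations

* The unsupervised-RF importance cannot rank a marker whose information
  is purely marginal (see above); such markers are still caught by the
  MWW screen.
* PAC with k-means inner clustering can prefer k = 2 on unimodal
  elliptical data; the structureless-data check in the acceptance suite
  guards the planted-vs-null contrast, not general model selection.
* Half-minimum imputation induces ties and can attenuate fold changes
  of heavily censored proteins; the kNN alternative trades that for
  smoothing.  The imputation-robustness acceptance check shows the
  subtype structure itself is insensitive to the choice.
* Cox assumes proportional hazards; no competing risks or time-varying
  covariates.
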