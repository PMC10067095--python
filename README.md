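# evsubtype

Biomarker screening and prognostic subtyping for targeted proteomics of
plasma extracellular vesicles (EVs).

Liquid-biopsy studies quantify panels of candidate marker proteins in
plasma EVs by selected reaction monitoring (SRM) and ask two questions:
which proteins distinguish cancer patients from healthy controls or early
from late tumor stages, and do the patients fall into molecular subtypes
with different overall survival?  `evsubtype` implements that two-stage
analysis as a tested, reusable pipeline for researchers working with
SRM-style protein × sample abundance tables, and ships a synthetic-cohort
generator with known ground truth so every stage can be validated by
parameter recovery.

## The analysis

**Stage 1 — candidate screening** (case/control cohort).  Signals below
the quantification limit (default 1500 intensity units) are censored to
missing.  Each feature is tested with the Mann–Whitney–Wilcoxon (MWW)
test in three comparisons — Stage I vs healthy batch 1 (A), Stage IV vs
healthy batch 2 (B), Stage I vs Stage IV (C) — with exact permutation
p-values for small groups.  In parallel, Breiman-style *unsupervised*
random forests (real samples vs a permutation-contrast synthetic class)
are fit on the patient samples (D) and on patients plus controls (E);
sample proximities are embedded by classical multidimensional scaling.
The candidate set is the union of features with p < 0.05 in any
comparison and the top-50 features by importance in each forest, with
per-feature provenance letters A–E.

**Stage 2 — consensus subtyping** (patient cohort).  Detection-limit
(missing-not-at-random) cells are imputed with the half-minimum rule.
For each candidate cluster number k, the cohort is repeatedly subsampled
(80% of samples, 1000 rounds by default) and partitioned by k-means; the
consensus index

&nbsp;&nbsp;&nbsp;&nbsp;M(i, j) = (# rounds i, j co-cluster) / (# rounds i, j co-drawn)

measures how reliably two patients travel together.  The proportion of
ambiguous clustering, PAC = CDF(0.9) − CDF(0.1) of the off-diagonal
consensus indices, scores each k; the k with minimum PAC is selected and
final subtype labels come from average-linkage clustering of 1 − M.
Subtypes are characterized by Kaplan–Meier curves and the log-rank test,
a volcano screen (fold change > 2 and MWW p < 0.05) for
subtype-elevated proteins, median-split survival for fully quantified
markers, multivariate Cox proportional-hazards regression (age, sex, TNM
stage, log2 protein levels; Efron ties), Fisher's exact test for the
curative-resection association, and an all-pairs Pearson (log2)
correlation network thresholded at Benjamini–Hochberg FDR < 1e-4.

## Worked example

```python
from evsubtype import (SimulationParams, generate_cohort,
                       ConsensusSubtyper, logrank_test)
from evsubtype.io import drop_unquantified_features

params = SimulationParams(seed=7)          # 99 proteins, 110 patients,
matrix, annotations, truth = generate_cohort(params)  # 12 planted markers

patients = annotations.loc[annotations["cohort"] == "cohort2", "sample_id"]
cohort2, _ = drop_unquantified_features(matrix.subset_samples(patients))

model = ConsensusSubtyper(cohort2, k_range=(2, 6), n_resamples=250)
run = model.fit(seed=11)
print(run.summary())

surv = annotations.set_index("sample_id").loc[run.labels.index]
stat, p = logrank_test(surv["os_time"], surv["os_event"], run.labels)
print(f"log-rank chi2 = {stat:.2f}, p = {p:.4f}")
```

prints

```
Consensus clustering
  samples: 110   PAC interval: (0.1, 0.9)
  k    PAC
  2    0.0000  <- selected
  3    0.3611
  4    0.5129
  5    0.5154
  6    0.5151
  subtype sizes: 1: n=66, 2: n=44
log-rank chi2 = 12.60, p = 0.0004
```

PAC is minimized at k = 2 (0.0 means no ambiguous patient pair), the
recovered subtype sizes match the planted 60/40 split, and the two
subtypes differ sharply in overall survival — the planted hazard ratio
of 2.5 is detected at p = 4e-4.

The same analysis is available from the shell:

```bash
evsubtype simulate --outdir sim --seed 7
evsubtype all --abundance sim/abundance.tsv --annotations sim/annotations.tsv \
              --outdir results --seed 11
```

which writes candidate, consensus, survival, volcano and network tables
plus a machine-readable `summary.json`.

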