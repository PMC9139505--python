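# Methods

This note records the scientific model behind `cellpheno`, the defaults
that matter, and the choices made where the design was genuinely open.

## Problem setting

The unit of analysis is a manually selected region of interest (ROI) of a
digitized lymph-node biopsy, at least 512 px (0.256 mm) on a side at
0.50 µm/pixel. An external instance segmenter supplies one record per
nucleus: pixel area, mean grayscale intensity (0–255), centroid, and
solidity (area / convex-hull area). The task is three-class staging —
CLL vs accelerated CLL (aCLL) vs Richter transformation (RT) — from
per-ROI summaries of these nuclei.

## Quality filtering

Two rules, applied jointly and idempotently:

- **solidity ≥ 0.84** (inclusive keep). Low solidity flags merged or
  overlapping segmentations; the boundary case is kept because the
  comparison direction at equality is otherwise arbitrary and inclusive
  keep is deterministic.
- **area in [8, 108] µm²**, endpoints inclusive (32–432 px at
  0.50 µm/pixel), the biologically plausible nuclear size range.

Every removed cell is attributed to exactly one rule (solidity checked
first) so that the removal counts in the `FilterReport` always sum to the
number removed. Nuclei touching the ROI border are kept — border handling
belongs to the segmenter, and the downstream features are robust to the
small area bias of clipped nuclei.

Intensity is the mean grayscale value over the nucleus mask. Whether
"nuclear intensity" should instead be a stain-deconvolved optical density
is an open question for real slides; the definition is isolated in
`cells_from_mask` so it can be swapped without touching anything else.

## Phenotype discovery

Clustering operates on exactly two features per cell, (area µm², mean
intensity), z-standardized on the clustering sample. Standardization
matters: the raw intensity scale (0–255) would otherwise dominate the area
scale (8–108).

Because a cohort can hold millions of QC-passed nuclei, clustering runs on
a pooled subsample: 5000 cells per disease class by default, drawn without
replacement from the union of each class's ROIs (training side only in the
full pipeline). Spectral clustering uses a symmetrized 10-nearest-neighbour
connectivity graph, the normalized graph Laplacian, and seeded k-means
(10 restarts) on the embedding; for strongly separated phenotypes the kNN
graph may be disconnected, which is expected and harmless — each component
embeds to its own coordinate.

Clusters are named by a fixed morphological rule: the cluster with the
largest mean standardized size is **RT-like**; of the remaining two, the
dimmer is **CLL-like** and the brighter **aCLL-like**. Exact ties in a
deciding statistic raise an error rather than being broken silently, since
a tie means the phenotypes are not identifiable. Naming is therefore
invariant to any permutation of raw cluster indices.

Labels are propagated to all remaining cells by a multinomial logistic
regression (L2 penalty at unit strength, lbfgs, tolerance 1e-6) fitted on
the clustered subsample's standardized features. Prediction is the argmax
probability with ties broken toward the fixed order
CLL-like < aCLL-like < RT-like — probability ties are measure-zero but
determinism must not depend on that.

`stability_analysis` repeats the whole discovery at configurable subsample
sizes and seeds (defaults mirror a 9000/12000/4×15000/18000/21000 design),
scoring each run by downstream diagnostic accuracy on one fixed patient
split and by pairwise propagated-label agreement between runs.

## Per-ROI features (20)

| family | features |
|---|---|
| unsupervised (6) | per-phenotype cell ratio and density (cells/mm²) |
| mixed (4) | mean nuclear area, mean intensity, mean nearest-neighbour distance (µm), cell density |
| supervised (10) | large-cell ratio; correlation, symmetric chi-square and 1-D Wasserstein distance between small- and large-cell intensity PDFs; small/large cell densities; mean S→S, S→L, L→S, L→L nearest-neighbour distances |

Conventions:

- **ROI area** is the full rectangle (width × height), not the convex hull
  of the cells — deterministic and invariant under cell filtering. This
  gives the partition identities `Σ phenotype densities = cell density`
  and `small + large density = cell density` exactly.
- **"Large"** means area strictly greater than the cutoff.
- **Intensity PDFs** are 32-bin histograms on [0, 256) normalized to sum 1.
  Chi-square uses the symmetric form Σ (p−q)²/(p+q) over occupied bins.
  The Wasserstein distance is computed on the raw (unbinned) samples so
  the translation property (a shift by δ gray levels gives distance δ) is
  exact rather than bin-quantized.
- **Nearest-neighbour distances** exclude self for same-set queries and
  use a k-d tree; they agree with the O(n²) all-pairs definition and are
  invariant under rigid motions of the point set.
- **Degenerate inputs give missing values, not zeros.** An empty ROI has
  no mean size; an ROI without large cells has no L→L distance. XGBoost
  routes missing values natively, whereas fabricated zeros would inject
  signal. Ratios of an empty group are 0 (a genuine count), distances and
  PDF comparisons are NaN.

### Size-cutoff optimization

The supervised family needs a small/large boundary. For each candidate
cutoff c on the integer grid 8…108 µm², the per-ROI large-cell ratio is
#(area > c)/total, `R_k` is its mean over class k's training ROIs, and the
objective (R_RT − R_aCLL)(R_aCLL − R_CLL)(R_RT − R_CLL) is maximized;
ties break to the smallest cutoff. The ratio is computed as a boolean mean
in exactly the form a brute-force reimplementation would use, so the
search is bit-for-bit checkable against an exhaustive oracle.

On synthetic cohorts the expected objective is constant across the
generating size gap and strictly lower outside it, so the argmax falls in
the gap and the tie rule returns its lower edge. Because generated areas
are pixel-quantized, cells can sit exactly on the large-archetype boundary
and sampling noise occasionally favours the upper gap edge instead; both
edges separate the archetypes.

## Diagnosis and evaluation

- **Classifier**: XGBoost multiclass (softprob), library-default
  hyperparameters (100 histogram trees), single-threaded with a fixed
  seed; hyperparameters are recorded in the model artifact. No tuning is
  performed anywhere.
- **Feature selection**: impurity-based importances from a seeded
  extremely-randomized-trees ensemble (200 trees), normalized to sum 1;
  features with importance ≥ 0.02 are kept in canonical order. NaNs are
  median-imputed for the importance fit only.
- **Splitting**: patient-level 1:1. Patients are grouped into joint strata
  of (disease class × binary covariates: gender, age ≥ 60, outside source,
  needle biopsy, short overall survival), shuffled within stratum, and
  halved; odd-stratum leftovers alternate sides within each class so
  per-class counts differ by at most one. This balanced-assignment scheme
  replaces propensity matching, which is neither identifiable nor needed
  for synthetic covariates.
- **Metrics**: per-ROI accuracy; one-vs-rest ROC AUC per class
  (trapezoidal), macro-averaged unweighted. A class absent from a test
  split has no AUC; the macro average is over present classes with a
  recorded warning.
- **Repeated splitting**: default 100 repeats (20 in the test suite),
  per-repeat seeds derived from the master seed; all strategies share the
  identical split within a repeat, so accuracies are paired.
- **Comparison**: one-tailed (upper) Welch t-test on the repeat
  accuracies. The repeats share data and are not truly independent — the
  resulting p-values are descriptive, a caveat inherited by any repeated
  random-splitting design. When both samples are exactly constant the
  statistic is undefined; p = 0.5 at equal means by convention.

## Synthetic cohorts

The generator realizes the study conditions the pipeline targets:

- **Three phenotype archetypes** (size lognormal, intensity truncated
  normal, solidity rescaled beta): CLL-like median 15 µm² / intensity
  110 ± 7; aCLL-like 15 µm² / 160 ± 7; RT-like 45 µm² / 130 ± 10. The two
  small phenotypes deliberately share one size distribution and differ
  only in intensity — size separates small from large, intensity separates
  the two small phenotypes, mirroring the morphological description of the
  disease stages. Small sizes are truncated to [8, 22] µm² and RT-like to
  [28, 108] µm², leaving a known 22–28 µm² gap that makes cutoff recovery
  well-posed.
- **Class mixtures** over (CLL-like, aCLL-like, RT-like):
  CLL (0.80, 0.15, 0.05), aCLL (0.30, 0.55, 0.15), RT (0.10, 0.20, 0.70) —
  the RT-like fraction rises and the CLL-like fraction falls with disease
  stage. A null variant gives all classes the mixture (0.40, 0.35, 0.25),
  carrying no class signal.
- **Cohort hierarchy**: 20 patients per class, 1–2 slides each, 1–8 ROIs
  per slide, 150–400 cells per ROI, 1024×1024 px ROIs at 0.50 µm/pixel,
  with five Bernoulli(½) binary covariates per patient.
- **Contaminants**: 5% of cells are corrupted to violate exactly one QC
  rule (solidity U(0.5, 0.84), debris < 8 µm², or clumps > 108 µm²), so QC
  retention is predictable from the contaminant fraction.
- **Spatial model**: homogeneous uniform placement. The features consume
  only densities and nearest-neighbour summaries, which a Poisson-like
  pattern exercises; attraction/repulsion processes are out of scope.
- **Seeds**: one master seed; per-ROI streams are derived by stable
  hashing of (master, patient, slide, ROI), so any subset regenerates
  identically.
- **Mask rendering** draws each cell as a non-overlapping ellipse whose
  rasterized pixel count is calibrated to within 5% of the recorded area
  (random positions are retried when the recorded centroid is crowded),
  with the grayscale image filled at the rounded mean intensity — enough
  fidelity for round-trip testing of the mask-ingestion path.

What the generator does **not** emulate: stain variation and color, nuclear
texture, spatial clustering of phenotypes, segmentation errors beyond the
solidity/size contaminants, and class-dependent covariate distributions.
Passing tests therefore demonstrate correctness of the pipeline's
computations and recovery of known ground truth under clean conditions —
not clinical performance. On these cleanly separated cohorts all feature
families classify nearly perfectly, so ordering between strategies is
assessed as non-strict (unsupervised ≥ mixed > chance).

## Problem sizes in the test suite

The suite runs a 60-patient cohort (~400 ROIs, ~110k cells) for
parameter-recovery checks with 20 split repeats, a 36-patient null cohort
with 10 repeats, and small 12–18-ROI cohorts elsewhere; the acceptance
script uses the same 60-patient conditions with 10 repeats across all five
strategies. These sizes give binomial 3-SD bands of well under one
percentage point on phenotype-ratio recovery while keeping the whole suite
fast.

## Known limitations

- k = 3 phenotypes is assumed throughout naming; `cluster_phenotypes`
  accepts other k but the naming rule is defined only for three clusters.
- The solidity hull oracle and `regionprops` can disagree by a few percent
  on very small irregular regions because convex-hull rasterization at
  pixel scale is not unique.
- Decision boundaries of the propagator are not numerically comparable to
  any published figure, since the clustering sample's standardization is
  cohort-dependent.
- Accuracy/AUC are computed per ROI; per-slide or per-patient aggregation
  is deliberately not implemented.
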