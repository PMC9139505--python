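# cellpheno

Cellular feature engineering for staging chronic lymphocytic leukemia (CLL)
progression from digitized pathology slides.

Distinguishing CLL from its accelerated phase (aCLL) and from Richter
transformation (RT) on lymph-node histology is clinically decisive and
morphologically subtle. `cellpheno` implements a pathomics pipeline that
works at the level of individual segmented nuclei: starting from per-ROI
cell tables (nuclear area, mean intensity, centroid, solidity) produced by
any external nuclear segmenter, it

1. **quality-filters** nuclei (solidity ≥ 0.84 removes merged/overlapping
   segmentations; area restricted to the biological window 8–108 µm², i.e.
   32–432 px at 0.50 µm/pixel);
2. **discovers three cell phenotypes** — CLL-like (small, dim), aCLL-like
   (small, bright), RT-like (large) — by spectral clustering of a pooled
   subsample (5000 cells per disease class) on standardized
   (area, intensity), and propagates the labels to all cells with a
   multinomial logistic regression;
3. **computes 20 per-ROI features** in three families: *unsupervised*
   (per-phenotype cell ratios and densities, 6), *mixed* (mean nuclear size
   and intensity, mean nearest-neighbour distance, cell density, 4), and
   *supervised* (large-cell ratio and small/large-cell statistics at an
   optimized size cutoff, 10). The cutoff c maximizes

       J(c) = (R_RT − R_aCLL) · (R_aCLL − R_CLL) · (R_RT − R_CLL)

   where `R_k` is the class-mean fraction of nuclei with area > c, searched
   over an integer grid from 8 to 108 µm²;
4. **trains an XGBoost classifier** per feature family (plus fused and
   importance-selected variants, threshold 0.02) and evaluates it with
   per-ROI accuracy and macro-averaged one-vs-rest ROC AUC under repeated
   (default 100×) patient-level 1:1 splits balanced on disease class and
   binary clinical covariates, with one-tailed Welch t-tests comparing
   strategies.

Because clinical slides cannot be redistributed, the package ships a
first-class synthetic-cohort generator (`cellpheno.synthetic`) with known
per-cell ground truth — class-dependent phenotype mixtures, a
patient/slide/ROI hierarchy, QC contaminants, and optional rendered label
masks — so every stage is testable end to end.

## Worked example

```python
import cellpheno as cp
from cellpheno.data import DISEASE_CLASSES

# synthetic cohort: 10 patients per class, ground truth attached
cfg = cp.CohortConfig(patients_per_class=10, seed=1)
manifest, tables = cp.generate_cohort(cfg)
labels = manifest.roi_labels()

# QC filter, pool by class
filtered = {r: cp.filter_cells(t)[0] for r, t in tables.items()}
by_class = {c: [] for c in DISEASE_CLASSES}
for r, t in filtered.items():
    by_class[labels[r]].append(t)

# phenotype discovery + propagation
model = cp.fit_phenotype_model(by_class, n_per_class=5000, seed=1)
labeled = [cp.propagate_labels(model, filtered[r]) for r in sorted(filtered)]

# supervised size cutoff and the 20-feature matrix
search = cp.optimize_size_cutoff(labeled, labels=labels)
print(f"optimal size cutoff: {search.optimal_cutoff_um2:.0f} um^2 "
      f"(objective {search.objective:.3f})")
feats = cp.build_feature_matrix(labeled, cutoff_um2=search.optimal_cutoff_um2,
                                manifest=manifest)

# repeated patient-level evaluation
rep = cp.repeated_split_eval(
    manifest, feats,
    {"unsupervised": cp.UNSUPERVISED_FEATURES, "mixed": cp.MIXED_FEATURES},
    n_repeats=10, master_seed=1,
)
print(rep.summary().round(3))
p = cp.one_tailed_ttest(rep.accuracies("unsupervised"), rep.accuracies("mixed"))
print(f"P(unsupervised > mixed): {p:.3f}")
```

prints

```
optimal size cutoff: 21 um^2 (objective 0.036)
              mean_accuracy  sd_accuracy  mean_auc  sd_auc  n_repeats
strategy
unsupervised          0.991        0.006       1.0     0.0         10
mixed                 0.986        0.010       1.0     0.0         10
P(unsupervised > mixed): 0.116
```

The recovered cutoff sits at the edge of the gap separating the generator's
small and large nuclear archetypes; both feature families classify this
cleanly separated cohort almost perfectly, and the t-test correctly finds
no significant difference between them.

## Command line

The same stages are available as a CLI:

```sh
cellpheno simulate --config cohort.json --out data/ --seed 7
cellpheno qc --in data/cells/roi.csv --out roi_qc.csv
cellpheno phenotype fit --cells-dir data/cells --manifest data/manifest.json \
    --n-per-class 5000 --seed 7 --out model.json
cellpheno featurize --cells-dir data/cells --model model.json \
    --manifest data/manifest.json --cutoff auto --out features.csv
cellpheno run --config pipeline.json --seed 7   # full experiment in one go
```

`cellpheno ingest` extracts cell tables from instance label masks
(16-bit TIFF) plus grayscale images; `cellpheno run` writes every
intermediate artifact (QC report, phenotype model, cutoff curve, feature
matrix, per-strategy summaries, pairwise t-test table) into one run
directory. Exit codes: 0 success, 2 validation error, 3 stage failure.

## Layout

- `cellpheno.synthetic` — cohort generator and mask renderer
- `cellpheno.ingest` — mask/CSV ingestion and quality filters
- `cellpheno.phenotyping` — spectral clustering, naming, label propagation,
  stability analysis
- `cellpheno.features` — the 20 per-ROI features and the cutoff search
- `cellpheno.modeling` — splits, XGBoost training, selection, evaluation
- `cellpheno.pipeline` / `cellpheno.cli` — orchestration and CLI

See `docs/methods.md` for the modelling assumptions, parameter defaults and
known limitations.
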