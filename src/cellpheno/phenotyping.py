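"""Cell phenotype discovery by subsampled spectral clustering and propagation.

Millions of QC-passed nuclei are too many to cluster directly, so a fixed
number of cells per disease class (5000 by default) is pooled and clustered
on standardized (nuclear area, mean intensity) with spectral clustering on a
symmetrized k-nearest-neighbour affinity graph.  The three clusters are
named by their morphology — RT-like is the largest-sized cluster, and of
the two small clusters the dimmer is CLL-like, the brighter aCLL-like.
A multinomial logistic regression fitted on the clustered sample then
propagates phenotype labels to every remaining cell.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import SpectralClustering
from sklearn.linear_model import LogisticRegression

from cellpheno.data import DISEASE_CLASSES, CellTable, CohortManifest, derive_seed

#: fixed phenotype order; ties in propagation break toward the earlier name
PHENOTYPE_ORDER = ("CLL-like", "aCLL-like", "RT-like")

#: clustering feature columns, in order
CLUSTER_FEATURES = ("area_um2", "mean_intensity")


@dataclass
class PhenotypeModel:
    """Fitted scaler + clustering + naming + propagation classifier.

    ``scaler_mean``/``scaler_sd`` standardize (area_um2, mean_intensity) as
    fitted on the clustering sample; ``name_map`` maps raw cluster indices to
    phenotype names; ``propagator`` is the multinomial logistic regression
    used to label unseen cells.
    """

    scaler_mean: np.ndarray
    scaler_sd: np.ndarray
    cluster_assignments: np.ndarray
    name_map: dict[int, str]
    propagator: LogisticRegression | None
    seed: int

    def standardize(self, cells: pd.DataFrame) -> np.ndarray:
        X = cells.loc[:, list(CLUSTER_FEATURES)].to_numpy(float)
        return (X - self.scaler_mean) / self.scaler_sd

    # ------------------------------------------------------------------ I/O
    def to_dict(self) -> dict:
        d = {
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_sd": self.scaler_sd.tolist(),
            "name_map": {str(k): v for k, v in self.name_map.items()},
            "seed": self.seed,
        }
        if self.propagator is not None:
            d["propagator"] = {
                "classes": list(self.propagator.classes_),
                "coef": self.propagator.coef_.tolist(),
                "intercept": self.propagator.intercept_.tolist(),
            }
        return d

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "PhenotypeModel":
        with open(path) as fh:
            d = json.load(fh)
        prop = None
        if "propagator" in d:
            prop = LogisticRegression()
            prop.classes_ = np.asarray(d["propagator"]["classes"], dtype=object)
            prop.coef_ = np.asarray(d["propagator"]["coef"], dtype=float)
            prop.intercept_ = np.asarray(d["propagator"]["intercept"], dtype=float)
        return cls(
            scaler_mean=np.asarray(d["scaler_mean"], dtype=float),
            scaler_sd=np.asarray(d["scaler_sd"], dtype=float),
            cluster_assignments=np.empty(0, dtype=int),
            name_map={int(k): v for k, v in d["name_map"].items()},
            propagator=prop,
            seed=int(d["seed"]),
        )


def subsample_cells(
    tables_by_class: Mapping[str, Sequence[CellTable]],
    n_per_class: int = 5000,
    seed: int = 0,
    allow_smaller: bool = False,
) -> pd.DataFrame:
    """Pool QC-passed cells per disease class and sample without replacement.

    Returns a DataFrame with the clustering features plus ``source_class``.
    Raises when a class pool is smaller than ``n_per_class`` unless
    ``allow_smaller`` (which then takes the whole pool).
    """
    rng = np.random.default_rng(seed)
    parts = []
    for cls in DISEASE_CLASSES:
        if cls not in tables_by_class:
            continue
        # carry ground-truth labels through when every table has them
        cols = list(CLUSTER_FEATURES)
        if all("truth_phenotype" in t.cells.columns for t in tables_by_class[cls]):
            cols.append("truth_phenotype")
        pool = pd.concat(
            [t.cells.loc[:, cols] for t in tables_by_class[cls]], ignore_index=True
        )
        if len(pool) < n_per_class:
            if not allow_smaller:
                raise ValueError(f"class {cls} has {len(pool)} < {n_per_class} cells")
            take = np.arange(len(pool))
        else:
            take = rng.choice(len(pool), size=n_per_class, replace=False)
        part = pool.iloc[np.sort(take)].reset_index(drop=True)
        part["source_class"] = cls
        parts.append(part)
    return pd.concat(parts, ignore_index=True)


def cluster_phenotypes(
    sample: pd.DataFrame,
    k: int = 3,
    seed: int = 0,
    n_neighbors: int = 10,
) -> tuple[np.ndarray, PhenotypeModel]:
    """Spectral clustering of the pooled sample on standardized (size, intensity).

    The affinity is a symmetrized k-nearest-neighbour connectivity graph;
    the normalized-Laplacian embedding is partitioned with seeded k-means
    (10 restarts).  Returns raw cluster labels and an unnamed model holding
    the scaler and assignments.
    """
    if len(sample) < k:
        raise ValueError(f"sample of {len(sample)} cells cannot form {k} clusters")
    X = sample.loc[:, list(CLUSTER_FEATURES)].to_numpy(float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    if (sd == 0).all():
        raise ValueError("degenerate sample: zero variance in both clustering features")
    sd = np.where(sd == 0, 1.0, sd)
    Z = (X - mean) / sd
    sc = SpectralClustering(
        n_clusters=k,
        affinity="nearest_neighbors",
        n_neighbors=n_neighbors,
        assign_labels="kmeans",
        n_init=10,
        random_state=seed,
    )
    import warnings

    with warnings.catch_warnings():
        # a disconnected kNN graph is expected for strongly separated
        # phenotypes; the embedding of each component is still valid
        warnings.filterwarnings(
            "ignore", message="Graph is not fully connected", category=UserWarning
        )
        labels = sc.fit_predict(Z)
    model = PhenotypeModel(
        scaler_mean=mean,
        scaler_sd=sd,
        cluster_assignments=labels,
        name_map={},
        propagator=None,
        seed=seed,
    )
    return labels, model


def assign_phenotype_names(cluster_stats: pd.DataFrame) -> dict[int, str]:
    """Name three clusters from their mean standardized (size, intensity).

    RT-like is the cluster with the largest mean size; of the remaining two,
    CLL-like has the lower mean intensity and aCLL-like the higher.  Exact
    ties in a deciding statistic are ambiguous and raise.

    ``cluster_stats`` must have one row per cluster (index = cluster id) and
    columns ``mean_size`` and ``mean_intensity``.
    """
    if len(cluster_stats) != 3:
        raise ValueError(f"naming requires exactly 3 clusters, got {len(cluster_stats)}")
    sizes = cluster_stats["mean_size"]
    top = sizes.max()
    largest = cluster_stats.index[sizes == top]
    if len(largest) > 1:
        raise ValueError(f"ambiguous phenotypes: clusters {list(largest)} tie on mean size")
    rt = largest[0]
    rest = cluster_stats.drop(index=rt)
    ints = rest["mean_intensity"]
    if ints.iloc[0] == ints.iloc[1]:
        raise ValueError(f"ambiguous phenotypes: clusters {list(rest.index)} tie on mean intensity")
    cll = ints.idxmin()
    acll = ints.idxmax()
    return {int(cll): "CLL-like", int(acll): "aCLL-like", int(rt): "RT-like"}


def _cluster_stats(model: PhenotypeModel, sample: pd.DataFrame, labels: np.ndarray) -> pd.DataFrame:
    Z = model.standardize(sample)
    rows = {}
    for c in np.unique(labels):
        sel = labels == c
        rows[int(c)] = {"mean_size": Z[sel, 0].mean(), "mean_intensity": Z[sel, 1].mean()}
    return pd.DataFrame.from_dict(rows, orient="index")


def fit_propagator(
    sample: pd.DataFrame,
    phenotype_names: Sequence[str],
    model: PhenotypeModel,
) -> LogisticRegression:
    """Fit the multinomial logistic-regression label propagator.

    Trained on the clustering sample's standardized features against its
    named phenotypes; L2 penalty at unit strength, lbfgs, tol 1e-6, so the
    fit is deterministic for fixed inputs.
    """
    names = np.asarray(phenotype_names, dtype=object)
    if len(np.unique(names)) < 2:
        raise ValueError("propagator needs at least 2 distinct phenotype labels")
    Z = model.standardize(sample)
    lr = LogisticRegression(C=1.0, tol=1e-6, max_iter=1000, solver="lbfgs")
    lr.fit(Z, names)
    return lr


def propagate_labels(model: PhenotypeModel, table: CellTable) -> CellTable:
    """Label every cell of a table with a phenotype name.

    Argmax of predicted probability, in the fixed order
    CLL-like < aCLL-like < RT-like so probability ties are deterministic.
    """
    if model.propagator is None:
        raise ValueError("model has no fitted propagator")
    if (model.scaler_sd <= 0).any():
        raise ValueError("invalid scaler: non-positive feature SD")
    cells = table.cells.copy()
    if len(cells) == 0:
        cells["phenotype"] = pd.Series(dtype=object)
        return table.with_cells(cells)
    proba = model.propagator.predict_proba(model.standardize(cells))
    # reorder probability columns to the canonical phenotype order
    order = [list(model.propagator.classes_).index(p) for p in PHENOTYPE_ORDER
             if p in model.propagator.classes_]
    names = np.asarray([model.propagator.classes_[j] for j in order], dtype=object)
    cells["phenotype"] = names[np.argmax(proba[:, order], axis=1)]
    return table.with_cells(cells)


def fit_phenotype_model(
    tables_by_class: Mapping[str, Sequence[CellTable]],
    n_per_class: int = 5000,
    seed: int = 0,
    allow_smaller: bool = False,
) -> PhenotypeModel:
    """Full phenotype-discovery pass: subsample, cluster, name, fit propagator."""
    sample = subsample_cells(tables_by_class, n_per_class, seed, allow_smaller)
    labels, model = cluster_phenotypes(sample, k=3, seed=seed)
    model.name_map = assign_phenotype_names(_cluster_stats(model, sample, labels))
    names = [model.name_map[int(c)] for c in labels]
    model.propagator = fit_propagator(sample, names, model)
    return model


# ----------------------------------------------------------------- stability


@dataclass
class StabilityRun:
    seed: int
    sample_size: int
    accuracy: float
    macro_auc: float


@dataclass
class StabilityReport:
    """Clustering-reproducibility summary across subsample sizes and seeds."""

    runs: list[StabilityRun]
    pairwise_agreement: np.ndarray  # fraction of cells with identical phenotype

    @property
    def min_agreement(self) -> float:
        n = self.pairwise_agreement.shape[0]
        off = self.pairwise_agreement[~np.eye(n, dtype=bool)]
        return float(off.min()) if off.size else 1.0


def stability_analysis(
    manifest: CohortManifest,
    tables: Mapping[str, CellTable],
    sizes: Sequence[int] = (9000, 12000, 15000, 15000, 15000, 15000, 18000, 21000),
    master_seed: int = 0,
    split_seed: int | None = None,
    allow_smaller: bool = False,
) -> StabilityReport:
    """Repeat phenotype discovery at varying total sample sizes.

    For each configured run (size, derived seed): subsample size/3 cells per
    class, cluster, name, propagate over the whole cohort, extract
    unsupervised features, and train/evaluate a boosted-tree model on one
    fixed patient split shared by all runs.  Pairwise agreement is the
    fraction of cohort cells assigned the same phenotype name by two runs.
    """
    from cellpheno.features import UNSUPERVISED_FEATURES, build_feature_matrix
    from cellpheno.ingest import filter_cells
    from cellpheno.modeling import evaluate_model, split_cohort, train_classifier

    labels_map = manifest.roi_labels()
    filtered = {rid: filter_cells(t)[0] for rid, t in tables.items()}
    by_class: dict[str, list[CellTable]] = {c: [] for c in DISEASE_CLASSES}
    for rid, t in filtered.items():
        by_class[labels_map[rid]].append(t)

    split = split_cohort(manifest, seed=master_seed if split_seed is None else split_seed)
    runs: list[StabilityRun] = []
    all_labels: list[np.ndarray] = []
    for i, size in enumerate(sizes):
        run_seed = derive_seed(master_seed, "stability", i)
        model = fit_phenotype_model(
            by_class, n_per_class=size // 3, seed=run_seed, allow_smaller=allow_smaller
        )
        labeled = {rid: propagate_labels(model, t) for rid, t in filtered.items()}
        all_labels.append(
            np.concatenate([labeled[rid].cells["phenotype"].to_numpy() for rid in sorted(labeled)])
        )
        feats = build_feature_matrix(labeled.values(), manifest=manifest)
        train = feats[feats["patient_id"].isin(split.train_patients)]
        test = feats[feats["patient_id"].isin(split.test_patients)]
        clf = train_classifier(
            train[list(UNSUPERVISED_FEATURES)], train["label"], seed=run_seed
        )
        report = evaluate_model(clf, test[list(UNSUPERVISED_FEATURES)], test["label"])
        runs.append(StabilityRun(run_seed, size, report.accuracy, report.macro_auc))

    n = len(sizes)
    agree = np.ones((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            agree[a, b] = agree[b, a] = float(np.mean(all_labels[a] == all_labels[b]))
    return StabilityReport(runs, agree)
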