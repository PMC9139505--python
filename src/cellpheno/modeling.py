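"""Boosted-tree diagnosis, feature selection, and repeated-split evaluation.

The diagnosis model is an XGBoost multiclass classifier over per-ROI
feature vectors; feature selection keeps features whose normalized
impurity-based importance (from a seeded forest of randomized trees)
reaches a threshold of 0.02.  Evaluation is per-ROI accuracy and
macro-averaged one-vs-rest ROC AUC, under patient-level 1:1 splits that
are balanced within joint strata of disease class and binary covariates —
repeated 100 times by default, with a one-tailed Welch t-test comparing
strategy accuracies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import ExtraTreesClassifier
from sklearn.metrics import confusion_matrix, roc_auc_score
from xgboost import XGBClassifier

from cellpheno.data import DISEASE_CLASSES, CohortManifest, derive_seed

#: impurity-importance threshold below which a feature is dropped
IMPORTANCE_THRESHOLD = 0.02


# ----------------------------------------------------------------- splitting


@dataclass
class SplitSpec:
    """A patient-level train/test partition."""

    train_patients: list[str]
    test_patients: list[str]
    seed: int
    strata: dict[str, int] = field(default_factory=dict)  # stratum key -> size

    def __post_init__(self) -> None:
        overlap = set(self.train_patients) & set(self.test_patients)
        if overlap:
            raise ValueError(f"patients on both sides: {sorted(overlap)}")


def split_cohort(manifest: CohortManifest, seed: int = 0) -> SplitSpec:
    """Patient-level 1:1 split balanced within joint covariate strata.

    Patients are grouped by (disease class, binary covariate vector); each
    stratum is shuffled by the seeded RNG and divided as evenly as possible.
    Odd-stratum leftovers alternate sides within each disease class so
    per-class train/test counts never differ by more than one.
    """
    rng = np.random.default_rng(seed)
    by_class = manifest.patients_by_class()
    for cls, ps in by_class.items():
        if len(ps) == 0:
            raise ValueError(f"disease class {cls} has no patients")
    train: list[str] = []
    test: list[str] = []
    strata: dict[str, int] = {}
    for cls in DISEASE_CLASSES:
        groups: dict[tuple, list[str]] = {}
        for p in by_class[cls]:
            key = tuple(sorted(p.covariates.items()))
            groups.setdefault(key, []).append(p.patient_id)
        extra_to_train = bool(rng.integers(0, 2))  # alternating odd-leftover side
        for key in sorted(groups):
            ids = sorted(groups[key])
            rng.shuffle(ids)
            strata[f"{cls}|{key}"] = len(ids)
            half = len(ids) // 2
            if len(ids) % 2 == 1:
                half += int(extra_to_train)
                extra_to_train = not extra_to_train
            train.extend(ids[:half])
            test.extend(ids[half:])
    return SplitSpec(sorted(train), sorted(test), seed, strata)


# ------------------------------------------------------------------- training


@dataclass
class DiagnosisModel:
    """Trained boosted-tree ensemble over a named feature subset."""

    booster: XGBClassifier
    feature_names: list[str]
    classes: tuple[str, ...]
    seed: int
    hyperparameters: dict = field(default_factory=dict)

    def predict_proba(self, features: pd.DataFrame) -> np.ndarray:
        X = features.loc[:, self.feature_names].to_numpy(float)
        return self.booster.predict_proba(X)

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        proba = self.predict_proba(features)
        return np.asarray(self.classes, dtype=object)[np.argmax(proba, axis=1)]

    def save(self, model_dir) -> None:
        import json
        import pathlib

        d = pathlib.Path(model_dir)
        d.mkdir(parents=True, exist_ok=True)
        self.booster.save_model(d / "booster.json")
        with open(d / "model_meta.json", "w") as fh:
            json.dump(
                {
                    "feature_names": self.feature_names,
                    "classes": list(self.classes),
                    "seed": self.seed,
                    "hyperparameters": self.hyperparameters,
                },
                fh,
                indent=1,
            )

    @classmethod
    def load(cls, model_dir) -> "DiagnosisModel":
        import json
        import pathlib

        d = pathlib.Path(model_dir)
        booster = XGBClassifier()
        booster._estimator_type = "classifier"
        booster.load_model(d / "booster.json")
        with open(d / "model_meta.json") as fh:
            meta = json.load(fh)
        return cls(
            booster,
            meta["feature_names"],
            tuple(meta["classes"]),
            meta["seed"],
            meta["hyperparameters"],
        )


def train_classifier(
    features: pd.DataFrame,
    labels: Sequence[str],
    feature_subset: Sequence[str] | None = None,
    seed: int = 0,
    **xgb_params,
) -> DiagnosisModel:
    """Fit the XGBoost diagnosis model.

    Missing feature values are routed natively by the trees.  Library
    default hyperparameters, a fixed seed, and single-threaded histogram
    trees keep the fit deterministic; overrides go through ``xgb_params``.
    """
    labels = np.asarray(labels, dtype=object)
    present = [c for c in DISEASE_CLASSES if c in labels]
    if len(present) < 2:
        raise ValueError(f"training set has {len(present)} class(es); need >= 2")
    subset = list(feature_subset) if feature_subset is not None else list(features.columns)
    params = dict(
        n_estimators=100,
        tree_method="hist",
        n_jobs=1,
        random_state=seed,
        objective="multi:softprob",
        eval_metric="mlogloss",
    )
    params.update(xgb_params)
    clf = XGBClassifier(**params)
    # xgboost's save_model still expects the _estimator_type attribute that
    # recent scikit-learn mixins no longer provide
    clf._estimator_type = "classifier"
    y = np.array([present.index(l) for l in labels])
    clf.fit(features.loc[:, subset].to_numpy(float), y)
    return DiagnosisModel(clf, subset, tuple(present), seed, params)


def select_features(
    features: pd.DataFrame,
    labels: Sequence[str],
    threshold: float = IMPORTANCE_THRESHOLD,
    seed: int = 0,
    n_estimators: int = 200,
) -> tuple[list[str], pd.Series]:
    """Impurity-importance feature selection with a seeded randomized forest.

    Importances are normalized to sum 1; features with importance >=
    ``threshold`` are kept, preserving the canonical feature order.  Missing
    values are median-imputed for the importance fit only (the diagnosis
    model itself routes missing values natively).
    """
    if not (0 < threshold < 1):
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    labels = np.asarray(labels, dtype=object)
    if len(np.unique(labels)) < 2:
        raise ValueError("feature selection needs >= 2 classes")
    X = features.to_numpy(float)
    med = np.nanmedian(X, axis=0)
    med = np.where(np.isnan(med), 0.0, med)
    X = np.where(np.isnan(X), med, X)
    est = ExtraTreesClassifier(n_estimators=n_estimators, random_state=seed, n_jobs=1)
    est.fit(X, labels)
    imp = est.feature_importances_
    total = imp.sum()
    imp = imp / total if total > 0 else imp
    table = pd.Series(imp, index=features.columns, name="importance")
    selected = [c for c in features.columns if table[c] >= threshold]
    return selected, table


# ----------------------------------------------------------------- evaluation


@dataclass
class EvalReport:
    """Per-split diagnostic performance."""

    accuracy: float
    macro_auc: float
    confusion: np.ndarray  # rows: true class, cols: predicted, in class order
    per_class_auc: dict[str, float]
    n_test_rois: int
    warnings: list[str] = field(default_factory=list)


def evaluate_model(
    model: DiagnosisModel, features: pd.DataFrame, labels: Sequence[str]
) -> EvalReport:
    """Accuracy, confusion matrix, and macro one-vs-rest AUC on a test set.

    A class absent from the test labels has no AUC; the macro average is
    then taken over present classes, with a warning recorded.
    """
    labels = np.asarray(labels, dtype=object)
    if labels.size == 0:
        raise ValueError("empty test set")
    pred = model.predict(features)
    proba = model.predict_proba(features)
    acc = float(np.mean(pred == labels))
    cm = confusion_matrix(labels, pred, labels=list(model.classes))
    per_class: dict[str, float] = {}
    warn: list[str] = []
    for j, cls in enumerate(model.classes):
        mask = labels == cls
        if mask.all() or not mask.any():
            per_class[cls] = np.nan
            warn.append(f"class {cls} degenerate in test labels; AUC undefined")
            continue
        per_class[cls] = float(roc_auc_score(mask.astype(int), proba[:, j]))
    present = [v for v in per_class.values() if np.isfinite(v)]
    macro = float(np.mean(present)) if present else np.nan
    return EvalReport(acc, macro, cm, per_class, int(labels.size), warn)


@dataclass
class RepeatedSplitReport:
    """Aggregated performance over repeated patient-level splits."""

    reports: dict[str, list[EvalReport]]  # strategy -> per-repeat reports
    splits: list[SplitSpec]

    def accuracies(self, strategy: str) -> np.ndarray:
        return np.array([r.accuracy for r in self.reports[strategy]])

    def aucs(self, strategy: str) -> np.ndarray:
        return np.array([r.macro_auc for r in self.reports[strategy]])

    def summary(self) -> pd.DataFrame:
        rows = []
        for strat in self.reports:
            acc = self.accuracies(strat)
            auc = self.aucs(strat)
            rows.append(
                {
                    "strategy": strat,
                    "mean_accuracy": acc.mean(),
                    "sd_accuracy": acc.std(ddof=1) if acc.size > 1 else 0.0,
                    "mean_auc": np.nanmean(auc),
                    "sd_auc": np.nanstd(auc, ddof=1) if auc.size > 1 else 0.0,
                    "n_repeats": acc.size,
                }
            )
        return pd.DataFrame(rows).set_index("strategy")


def repeated_split_eval(
    manifest: CohortManifest,
    features: pd.DataFrame,
    strategies: Mapping[str, Sequence[str]],
    n_repeats: int = 100,
    master_seed: int = 0,
) -> RepeatedSplitReport:
    """Repeat 1:1 patient-level splitting; train and evaluate every strategy.

    ``features`` must carry ``patient_id`` and ``label`` columns plus the
    feature columns each strategy names.  All strategies within one repeat
    share the identical patient split, so their accuracies are paired.
    """
    reports: dict[str, list[EvalReport]] = {s: [] for s in strategies}
    splits: list[SplitSpec] = []
    for r in range(n_repeats):
        seed_r = derive_seed(master_seed, "repeat", r)
        split = split_cohort(manifest, seed=seed_r)
        splits.append(split)
        train = features[features["patient_id"].isin(split.train_patients)]
        test = features[features["patient_id"].isin(split.test_patients)]
        for strat, cols in strategies.items():
            cols = list(cols)
            model = train_classifier(train[cols], train["label"], seed=seed_r)
            reports[strat].append(evaluate_model(model, test[cols], test["label"]))
    return RepeatedSplitReport(reports, splits)


def one_tailed_ttest(acc_a: Sequence[float], acc_b: Sequence[float]) -> float:
    """Upper-tail Welch t-test p-value for mean(a) > mean(b).

    Both samples need length >= 2.  When both samples have zero variance the
    statistic is undefined; by convention p = 0.5 at equal means, else 0 or
    1 according to the direction of the difference.
    """
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need length >= 2")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.5
        return 0.0 if a.mean() > b.mean() else 1.0
    res = stats.ttest_ind(a, b, equal_var=False, alternative="greater")
    return float(res.pvalue)
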