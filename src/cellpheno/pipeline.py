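"""End-to-end orchestration: simulate -> QC -> phenotype -> featurize -> model.

`run_pipeline` executes the full experiment from a single config and a
master seed, writing every intermediate artifact (cell tables, phenotype
model, feature matrix, evaluation reports, pairwise t-test table) into one
run directory so any stage can be re-run or audited in isolation.
"""

from __future__ import annotations

import json
import logging
import pathlib
from dataclasses import dataclass
from typing import Mapping, Sequence

from cellpheno import synthetic
from cellpheno.data import DISEASE_CLASSES, CellTable, CohortManifest, derive_seed
from cellpheno.features import (
    ALL_FEATURES,
    MIXED_FEATURES,
    SUPERVISED_FEATURES,
    UNSUPERVISED_FEATURES,
    build_feature_matrix,
    optimize_size_cutoff,
)
from cellpheno.ingest import AREA_WINDOW_UM2, SOLIDITY_MIN, filter_cells, read_cell_table
from cellpheno.modeling import (
    IMPORTANCE_THRESHOLD,
    one_tailed_ttest,
    repeated_split_eval,
    select_features,
    split_cohort,
)
from cellpheno.phenotyping import fit_phenotype_model, propagate_labels

log = logging.getLogger("cellpheno")

STRATEGY_FEATURES: dict[str, tuple[str, ...]] = {
    "unsupervised": UNSUPERVISED_FEATURES,
    "mixed": MIXED_FEATURES,
    "supervised": SUPERVISED_FEATURES,
    "fused": ALL_FEATURES,
}


@dataclass
class PipelineConfig:
    """Everything one experiment needs, in a single JSON-serializable record."""

    # input: either a directory of cells + manifest, or a simulation config
    cells_dir: str | None = None
    manifest_path: str | None = None
    simulate: synthetic.CohortConfig | None = None
    null_mixtures: bool = False
    # QC
    solidity_min: float = SOLIDITY_MIN
    area_window_um2: tuple[float, float] = AREA_WINDOW_UM2
    # phenotyping
    n_per_class: int = 5000
    allow_smaller_sample: bool = False
    # featurization
    cutoff_mode: str = "auto"  # "auto" => optimize on training ROIs, else a number
    # modeling
    strategies: tuple[str, ...] = ("unsupervised", "mixed", "supervised", "fused", "selected")
    selection_threshold: float = IMPORTANCE_THRESHOLD
    n_repeats: int = 100
    master_seed: int = 0
    out_dir: str = "cellpheno_run"

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        if self.simulate is not None:
            d["simulate"] = dict(self.simulate.__dict__)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        d = dict(d)
        if d.get("simulate") is not None:
            sim = dict(d["simulate"])
            for k in ("slides_per_patient", "rois_per_slide", "cells_per_roi"):
                if k in sim:
                    sim[k] = tuple(sim[k])
            d["simulate"] = synthetic.CohortConfig(**sim)
        if "area_window_um2" in d:
            d["area_window_um2"] = tuple(d["area_window_um2"])
        if "strategies" in d:
            d["strategies"] = tuple(d["strategies"])
        return cls(**d)


def _load_inputs(config: PipelineConfig) -> tuple[CohortManifest, dict[str, CellTable]]:
    if config.simulate is not None:
        mixtures = synthetic.NULL_MIXTURES if config.null_mixtures else None
        return synthetic.generate_cohort(config.simulate, mixtures=mixtures)
    if config.cells_dir is None or config.manifest_path is None:
        raise ValueError("config needs either a simulation config or cells_dir + manifest_path")
    manifest = CohortManifest.read_json(config.manifest_path)
    tables = {}
    for path in sorted(pathlib.Path(config.cells_dir).glob("*.csv")):
        t = read_cell_table(path)
        tables[t.roi_id] = t
    labels = manifest.roi_labels()
    for rid, t in tables.items():
        if t.disease_label is None and rid in labels:
            t.disease_label = labels[rid]
    return manifest, tables


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full experiment; returns the final report dict.

    Stages: load/simulate, QC filter, phenotype discovery on the training
    side of a reference split, label propagation, size-cutoff optimization
    (training ROIs only), featurization, per-strategy repeated-split
    evaluation, and the pairwise one-tailed t-test table on accuracies.
    """
    out = pathlib.Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    artifacts: list[dict] = []

    def record(stage: str, path: pathlib.Path, **extra) -> None:
        artifacts.append({"stage": stage, "path": str(path.relative_to(out)), **extra})

    try:
        manifest, tables = _load_inputs(config)
    except Exception as e:  # noqa: BLE001 - stage boundary
        raise PipelineError("load", str(e)) from e
    manifest.write_json(out / "manifest.json")
    record("load", out / "manifest.json", n_patients=len(manifest), n_rois=len(tables))
    log.info("loaded %d patients, %d ROIs", len(manifest), len(tables))

    # ---- QC
    try:
        filtered: dict[str, CellTable] = {}
        qc_counts = {"n_input": 0, "n_kept": 0}
        for rid, t in tables.items():
            ft, rep = filter_cells(t, config.solidity_min, config.area_window_um2)
            filtered[rid] = ft
            qc_counts["n_input"] += rep.n_input
            qc_counts["n_kept"] += rep.n_kept
    except Exception as e:
        raise PipelineError("qc", str(e)) from e
    with open(out / "qc_report.json", "w") as fh:
        json.dump(qc_counts, fh)
    record("qc", out / "qc_report.json", **qc_counts)

    # ---- reference split (phenotype sample + cutoff use the training side only)
    ref_split = split_cohort(manifest, seed=derive_seed(config.master_seed, "ref-split"))
    labels_map = manifest.roi_labels()
    patients_map = manifest.roi_patients()
    train_rois = {rid for rid in filtered if patients_map[rid] in set(ref_split.train_patients)}

    # ---- phenotype discovery
    try:
        by_class: dict[str, list[CellTable]] = {c: [] for c in DISEASE_CLASSES}
        for rid in train_rois:
            by_class[labels_map[rid]].append(filtered[rid])
        model = fit_phenotype_model(
            by_class,
            n_per_class=config.n_per_class,
            seed=derive_seed(config.master_seed, "phenotype"),
            allow_smaller=config.allow_smaller_sample,
        )
    except Exception as e:
        raise PipelineError("phenotype", str(e)) from e
    model.save(out / "phenotype_model.json")
    record("phenotype", out / "phenotype_model.json", n_per_class=config.n_per_class)

    labeled = {rid: propagate_labels(model, t) for rid, t in filtered.items()}

    # ---- size cutoff
    try:
        if config.cutoff_mode == "auto":
            search = optimize_size_cutoff(
                [labeled[rid] for rid in sorted(train_rois)], labels=labels_map
            )
            cutoff = search.optimal_cutoff_um2
            search.curve.to_csv(out / "cutoff_curve.csv", index=False)
            record("cutoff", out / "cutoff_curve.csv", optimal_cutoff_um2=cutoff)
        else:
            cutoff = float(config.cutoff_mode)
    except Exception as e:
        raise PipelineError("cutoff", str(e)) from e
    log.info("size cutoff: %.1f µm²", cutoff)

    # ---- features
    try:
        feats = build_feature_matrix(
            [labeled[rid] for rid in sorted(labeled)], cutoff_um2=cutoff, manifest=manifest
        )
    except Exception as e:
        raise PipelineError("featurize", str(e)) from e
    feats.to_csv(out / "features.csv", index=False)
    record("featurize", out / "features.csv", n_rois=len(feats))

    # ---- strategies (selection fitted on the reference training side)
    strategies: dict[str, Sequence[str]] = {}
    for strat in config.strategies:
        if strat == "selected":
            train_feats = feats[feats["patient_id"].isin(ref_split.train_patients)]
            selected, importances = select_features(
                train_feats[list(ALL_FEATURES)],
                train_feats["label"],
                threshold=config.selection_threshold,
                seed=derive_seed(config.master_seed, "selection"),
            )
            importances.to_csv(out / "feature_importances.csv")
            record("selection", out / "feature_importances.csv", n_selected=len(selected))
            if len(selected) == 0:
                log.warning("selection kept no features; skipping 'selected' strategy")
                continue
            strategies[strat] = selected
        elif strat in STRATEGY_FEATURES:
            strategies[strat] = STRATEGY_FEATURES[strat]
        else:
            raise PipelineError("strategies", f"unknown strategy {strat!r}")

    # ---- repeated-split evaluation
    try:
        rep = repeated_split_eval(
            manifest,
            feats,
            strategies,
            n_repeats=config.n_repeats,
            master_seed=derive_seed(config.master_seed, "repeats"),
        )
    except Exception as e:
        raise PipelineError("evaluate", str(e)) from e
    summary = rep.summary()
    summary.to_csv(out / "summary.csv")
    record("evaluate", out / "summary.csv", n_repeats=config.n_repeats)

    # ---- pairwise one-tailed t-tests on accuracies
    names = list(strategies)
    ttests = {
        f"{a}>{b}": one_tailed_ttest(rep.accuracies(a), rep.accuracies(b))
        for a in names
        for b in names
        if a != b
    }

    report = {
        "config": config.to_dict(),
        "qc": qc_counts,
        "cutoff_um2": cutoff,
        "strategies": {s: list(c) for s, c in strategies.items()},
        "summary": summary.reset_index().to_dict(orient="records"),
        "ttest_upper_p": ttests,
        "artifacts": artifacts,
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=float)
    log.info("report written to %s", out / "report.json")
    return report


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name for the CLI exit path."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
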