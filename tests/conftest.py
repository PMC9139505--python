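"""Shared synthetic cohorts.

The session-scoped fixtures are generated once and reused: a small cohort
for fast unit/property tests and a 60-patient cohort at the pipeline's
default study conditions for end-to-end parameter-recovery checks.
"""

from __future__ import annotations

import pytest

import cellpheno as cp
from cellpheno.data import DISEASE_CLASSES


def prepare(manifest, tables):
    """QC-filter a cohort and group the filtered tables by disease class."""
    labels = manifest.roi_labels()
    filtered = {rid: cp.filter_cells(t)[0] for rid, t in tables.items()}
    by_class = {c: [] for c in DISEASE_CLASSES}
    for rid, t in filtered.items():
        by_class[labels[rid]].append(t)
    return filtered, by_class


@pytest.fixture(scope="session")
def small_cohort():
    cfg = cp.CohortConfig(
        patients_per_class=4,
        slides_per_patient=(1, 1),
        rois_per_slide=(2, 3),
        cells_per_roi=(120, 220),
        roi_width_px=512,
        roi_height_px=512,
        seed=11,
    )
    return cp.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_pipeline(small_cohort):
    """Small cohort taken through QC, phenotyping, propagation, features."""
    manifest, tables = small_cohort
    filtered, by_class = prepare(manifest, tables)
    model = cp.fit_phenotype_model(by_class, n_per_class=500, seed=7)
    labeled = {rid: cp.propagate_labels(model, t) for rid, t in filtered.items()}
    feats = cp.build_feature_matrix(
        [labeled[rid] for rid in sorted(labeled)], manifest=manifest
    )
    return {
        "manifest": manifest,
        "tables": tables,
        "filtered": filtered,
        "by_class": by_class,
        "model": model,
        "labeled": labeled,
        "features": feats,
    }


@pytest.fixture(scope="session")
def big_cohort():
    """60 patients at the default study conditions (20 per class)."""
    cfg = cp.CohortConfig(seed=20301)
    return cp.generate_cohort(cfg)


@pytest.fixture(scope="session")
def big_pipeline(big_cohort):
    manifest, tables = big_cohort
    filtered, by_class = prepare(manifest, tables)
    model = cp.fit_phenotype_model(by_class, n_per_class=5000, seed=42)
    labeled = {rid: cp.propagate_labels(model, t) for rid, t in filtered.items()}
    search = cp.optimize_size_cutoff(
        [labeled[rid] for rid in sorted(labeled)], labels=manifest.roi_labels()
    )
    feats = cp.build_feature_matrix(
        [labeled[rid] for rid in sorted(labeled)],
        cutoff_um2=search.optimal_cutoff_um2,
        manifest=manifest,
    )
    return {
        "manifest": manifest,
        "filtered": filtered,
        "by_class": by_class,
        "model": model,
        "labeled": labeled,
        "cutoff_search": search,
        "features": feats,
    }


@pytest.fixture(scope="session")
def big_repeated_report(big_pipeline):
    """Shared 20-repeat evaluation of the unsupervised and mixed strategies."""
    return cp.repeated_split_eval(
        big_pipeline["manifest"],
        big_pipeline["features"],
        {"unsupervised": cp.UNSUPERVISED_FEATURES, "mixed": cp.MIXED_FEATURES},
        n_repeats=20,
        master_seed=99,
    )
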