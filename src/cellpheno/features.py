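"""Per-ROI pathomics features: unsupervised, mixed, and supervised families.

Twenty features per ROI, in a fixed canonical order:

====  =========================  =============================================
 #    name                       definition
====  =========================  =============================================
 1-3  *_ratio                    per-phenotype cell fraction
 4-6  *_density                  per-phenotype cells / mm² of ROI rectangle
 7    mean_cell_size             mean nuclear area (µm²)
 8    mean_cell_intensity        mean nuclear gray level
 9    mean_nn_dist               mean cell-to-nearest-neighbour distance (µm)
 10   cell_density               total cells / mm²
 11   large_cell_ratio           fraction of cells with area > size cutoff
 12   intensity_pdf_corr         Pearson corr. of small vs large intensity PDFs
 13   intensity_pdf_chi2         symmetric chi-square of the two PDFs
 14   intensity_pdf_wasserstein  1-D earth-mover's distance of raw intensities
 15   small_cell_density         small cells / mm²
 16   large_cell_density         large cells / mm²
 17   s2s_nn_dist                mean small -> nearest small distance (µm)
 18   s2l_nn_dist                mean small -> nearest large distance (µm)
 19   l2s_nn_dist                mean large -> nearest small distance (µm)
 20   l2l_nn_dist                mean large -> nearest large distance (µm)
====  =========================  =============================================

The size cutoff separating small from large cells is optimized on training
ROIs by maximizing (R_RT − R_aCLL)(R_aCLL − R_CLL)(R_RT − R_CLL), the
product of pairwise differences of class-mean large-cell ratios.

Degenerate inputs (empty ROI, a group with no cells) yield missing values,
never fabricated zeros: the downstream boosted-tree classifier routes
missing values natively.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import wasserstein_distance

from cellpheno.data import CellTable, CohortManifest, DISEASE_CLASSES
from cellpheno.phenotyping import PHENOTYPE_ORDER

UNSUPERVISED_FEATURES = (
    "cll_like_ratio",
    "acll_like_ratio",
    "rt_like_ratio",
    "cll_like_density",
    "acll_like_density",
    "rt_like_density",
)
MIXED_FEATURES = (
    "mean_cell_size",
    "mean_cell_intensity",
    "mean_nn_dist",
    "cell_density",
)
SUPERVISED_FEATURES = (
    "large_cell_ratio",
    "intensity_pdf_corr",
    "intensity_pdf_chi2",
    "intensity_pdf_wasserstein",
    "small_cell_density",
    "large_cell_density",
    "s2s_nn_dist",
    "s2l_nn_dist",
    "l2s_nn_dist",
    "l2l_nn_dist",
)
ALL_FEATURES = UNSUPERVISED_FEATURES + MIXED_FEATURES + SUPERVISED_FEATURES

#: default size cutoff (µm²) separating small from large nuclei
DEFAULT_SIZE_CUTOFF_UM2 = 24.0

#: intensity histogram: 32 uniform bins on [0, 256)
INTENSITY_BINS = np.linspace(0.0, 256.0, 33)


def unsupervised_features(table: CellTable) -> dict[str, float]:
    """Features 1–6: per-phenotype cell ratios and densities.

    Requires a ``phenotype`` column (propagated labels).  A zero-cell ROI
    yields six missing values.
    """
    out = {name: np.nan for name in UNSUPERVISED_FEATURES}
    n = len(table)
    if n == 0:
        return out
    if "phenotype" not in table.cells.columns:
        raise ValueError(f"ROI {table.roi_id}: cells carry no phenotype labels")
    counts = table.cells["phenotype"].value_counts()
    area_mm2 = table.roi_area_mm2
    for pheno, ratio_name, dens_name in zip(
        PHENOTYPE_ORDER, UNSUPERVISED_FEATURES[:3], UNSUPERVISED_FEATURES[3:]
    ):
        c = int(counts.get(pheno, 0))
        out[ratio_name] = c / n
        out[dens_name] = c / area_mm2
    return out


def mixed_features(table: CellTable) -> dict[str, float]:
    """Features 7–10: mean size, mean intensity, mean NN distance, density."""
    out = {name: np.nan for name in MIXED_FEATURES}
    n = len(table)
    if n == 0:
        return out
    cells = table.cells
    out["mean_cell_size"] = float(cells["area_um2"].mean())
    out["mean_cell_intensity"] = float(cells["mean_intensity"].mean())
    out["cell_density"] = n / table.roi_area_mm2
    pts = cells[["centroid_x_um", "centroid_y_um"]].to_numpy(float)
    out["mean_nn_dist"] = mean_nn_distance(pts, pts, same_set=True)
    return out


def mean_nn_distance(
    source_points: np.ndarray, target_points: np.ndarray, same_set: bool
) -> float:
    """Mean over source points of the distance to the nearest target point.

    With ``same_set`` the point itself is excluded (requires >= 2 sources);
    cross-set requires >= 1 target.  Violated preconditions yield NaN.
    """
    src = np.atleast_2d(np.asarray(source_points, dtype=float))
    tgt = np.atleast_2d(np.asarray(target_points, dtype=float))
    if same_set:
        if len(src) < 2:
            return np.nan
        d, _ = cKDTree(src).query(src, k=2)
        return float(d[:, 1].mean())
    if len(tgt) < 1 or len(src) < 1:
        return np.nan
    d, _ = cKDTree(tgt).query(src, k=1)
    return float(d.mean())


def intensity_pdf_similarity(
    small_intensities: np.ndarray, large_intensities: np.ndarray
) -> tuple[float, float, float]:
    """Features 12–14: similarity of small- vs large-cell intensity PDFs.

    PDFs are 32-bin histograms on [0, 256) normalized to sum 1.  Returns
    (Pearson correlation of the binned PDFs, symmetric chi-square
    Σ (p−q)²/(p+q) over bins with p+q > 0, and the 1-D Wasserstein distance
    between the raw unbinned samples).  Either group empty => all NaN; a
    zero-variance PDF leaves only the correlation undefined.
    """
    s = np.asarray(small_intensities, dtype=float)
    l = np.asarray(large_intensities, dtype=float)
    if s.size == 0 or l.size == 0:
        return (np.nan, np.nan, np.nan)
    p = np.histogram(s, bins=INTENSITY_BINS)[0].astype(float)
    q = np.histogram(l, bins=INTENSITY_BINS)[0].astype(float)
    p /= p.sum()
    q /= q.sum()
    if p.std() == 0 or q.std() == 0:
        corr = np.nan
    else:
        corr = float(np.corrcoef(p, q)[0, 1])
    m = p + q > 0
    chi2 = float((((p[m] - q[m]) ** 2) / (p[m] + q[m])).sum())
    w = float(wasserstein_distance(s, l))
    return (corr, chi2, w)


def supervised_features(
    table: CellTable, cutoff_um2: float = DEFAULT_SIZE_CUTOFF_UM2
) -> dict[str, float]:
    """Features 11–20: large-cell ratio, PDF similarities, group densities,
    and the four small/large nearest-neighbour distances.

    "Large" means area strictly greater than the cutoff.  An empty ROI gives
    ten missing values; an empty small or large group leaves the features
    that need it missing.
    """
    out = {name: np.nan for name in SUPERVISED_FEATURES}
    n = len(table)
    if n == 0:
        return out
    cells = table.cells
    large = cells["area_um2"].to_numpy(float) > cutoff_um2
    pts = cells[["centroid_x_um", "centroid_y_um"]].to_numpy(float)
    s_pts, l_pts = pts[~large], pts[large]
    area_mm2 = table.roi_area_mm2

    out["large_cell_ratio"] = float(large.mean())
    out["small_cell_density"] = float((~large).sum() / area_mm2)
    out["large_cell_density"] = float(large.sum() / area_mm2)
    corr, chi2, w = intensity_pdf_similarity(
        cells.loc[~large, "mean_intensity"].to_numpy(float),
        cells.loc[large, "mean_intensity"].to_numpy(float),
    )
    out["intensity_pdf_corr"] = corr
    out["intensity_pdf_chi2"] = chi2
    out["intensity_pdf_wasserstein"] = w
    out["s2s_nn_dist"] = mean_nn_distance(s_pts, s_pts, same_set=True)
    out["s2l_nn_dist"] = mean_nn_distance(s_pts, l_pts, same_set=False)
    out["l2s_nn_dist"] = mean_nn_distance(l_pts, s_pts, same_set=False)
    out["l2l_nn_dist"] = mean_nn_distance(l_pts, l_pts, same_set=True)
    return out


def featurize_roi(
    table: CellTable, cutoff_um2: float = DEFAULT_SIZE_CUTOFF_UM2
) -> pd.Series:
    """All 20 features of one ROI in canonical order, named, with roi_id."""
    vals: dict[str, float] = {}
    vals.update(unsupervised_features(table))
    vals.update(mixed_features(table))
    vals.update(supervised_features(table, cutoff_um2))
    s = pd.Series({k: vals[k] for k in ALL_FEATURES}, name=table.roi_id)
    return s


def build_feature_matrix(
    tables: Iterable[CellTable],
    cutoff_um2: float = DEFAULT_SIZE_CUTOFF_UM2,
    manifest: CohortManifest | None = None,
) -> pd.DataFrame:
    """Feature matrix: one row per ROI with roi_id, patient_id, label, 20 features."""
    rows = []
    roi_patients = manifest.roi_patients() if manifest is not None else {}
    roi_labels = manifest.roi_labels() if manifest is not None else {}
    for t in tables:
        rec = {"roi_id": t.roi_id}
        rec["patient_id"] = roi_patients.get(t.roi_id)
        rec["label"] = roi_labels.get(t.roi_id, t.disease_label)
        rec.update(featurize_roi(t, cutoff_um2).to_dict())
        rows.append(rec)
    return pd.DataFrame(rows, columns=["roi_id", "patient_id", "label", *ALL_FEATURES])


# ------------------------------------------------------------- cutoff search


@dataclass
class CutoffSearchResult:
    """Outcome of the supervised size-cutoff grid search."""

    optimal_cutoff_um2: float
    objective: float
    curve: pd.DataFrame  # columns: cutoff_um2, objective, R_CLL, R_aCLL, R_RT
    class_mean_ratios: dict[str, float]


def optimize_size_cutoff(
    tables: Sequence[CellTable],
    labels: Mapping[str, str] | None = None,
    grid: np.ndarray | None = None,
) -> CutoffSearchResult:
    """Search the size cutoff maximizing class separation of large-cell ratios.

    For each candidate cutoff c on an integer µm² grid from 8 to 108, the
    per-ROI large-cell ratio is #(area > c)/total; R_class is its mean over
    that class's ROIs, and the objective is
    (R_RT − R_aCLL)(R_aCLL − R_CLL)(R_RT − R_CLL).  Returns the grid argmax,
    breaking ties toward the smallest cutoff.
    """
    grid = np.arange(8.0, 109.0) if grid is None else np.asarray(grid, dtype=float)
    by_class: dict[str, list[np.ndarray]] = {c: [] for c in DISEASE_CLASSES}
    for t in tables:
        label = labels.get(t.roi_id) if labels is not None else t.disease_label
        if label not in by_class:
            raise ValueError(f"ROI {t.roi_id}: unknown or missing class label {label!r}")
        if len(t) == 0:
            continue
        by_class[label].append(t.cells["area_um2"].to_numpy(float))
    for c, rois in by_class.items():
        if not rois:
            raise ValueError(f"class {c} has no (non-empty) ROIs")

    R = {}
    for c, rois in by_class.items():
        # per-ROI ratio of areas strictly greater than each cutoff
        ratios = np.stack([(a[None, :] > grid[:, None]).mean(axis=1) for a in rois])
        R[c] = ratios.mean(axis=0)
    obj = (R["RT"] - R["aCLL"]) * (R["aCLL"] - R["CLL"]) * (R["RT"] - R["CLL"])
    best = int(np.argmax(obj))  # first max => smallest cutoff on ties
    curve = pd.DataFrame(
        {
            "cutoff_um2": grid,
            "objective": obj,
            "R_CLL": R["CLL"],
            "R_aCLL": R["aCLL"],
            "R_RT": R["RT"],
        }
    )
    return CutoffSearchResult(
        optimal_cutoff_um2=float(grid[best]),
        objective=float(obj[best]),
        curve=curve,
        class_mean_ratios={c: float(R[c][best]) for c in DISEASE_CLASSES},
    )
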