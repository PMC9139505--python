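"""Synthetic cohort generator with known per-cell ground truth.

Emulates the structure of a lymph-node biopsy study: each disease class
(CLL, aCLL, RT) is a mixture over three nuclear phenotypes that differ in
size and staining intensity; cells are scattered uniformly inside
rectangular ROIs; ROIs hang off a patient -> slide hierarchy carrying
binary clinical covariates.  A configurable contaminant fraction produces
cells that fail the solidity/size quality filters, exercising the QC stage.

Phenotype archetypes
--------------------
The defaults realize the qualitative picture of disease progression:
small dim nuclei (CLL-like), small bright nuclei (aCLL-like), and large
nuclei (RT-like).  Small and large archetypes are separated by a size gap
(no nucleus between 22 and 28 µm²) so that supervised size-cutoff recovery
has a well-defined answer.  All archetype parameters are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from cellpheno.data import (
    COVARIATE_NAMES,
    DISEASE_CLASSES,
    CellTable,
    CohortManifest,
    Patient,
    Slide,
    derive_seed,
)

PHENOTYPE_NAMES = ("CLL-like", "aCLL-like", "RT-like")

#: global biologically plausible nuclear size window (µm²)
SIZE_WINDOW_UM2 = (8.0, 108.0)


@dataclass(frozen=True)
class PhenotypeParams:
    """Sampling distributions for one nuclear phenotype.

    size is lognormal with median ``size_median_um2`` and log-sd
    ``size_sigma``, truncated to ``size_window_um2`` (itself within the
    global 8–108 µm² window); intensity is normal truncated to [0, 255];
    solidity is a beta(a, b) variate rescaled to [0.7, 1.0].
    """

    name: str
    size_median_um2: float
    size_sigma: float
    intensity_mu: float
    intensity_sd: float
    solidity_a: float = 8.0
    solidity_b: float = 1.5
    size_window_um2: tuple[float, float] = SIZE_WINDOW_UM2

    def __post_init__(self) -> None:
        lo, hi = self.size_window_um2
        if not (SIZE_WINDOW_UM2[0] <= lo < hi <= SIZE_WINDOW_UM2[1]):
            raise ValueError(
                f"size window {self.size_window_um2} must lie within {SIZE_WINDOW_UM2}"
            )

    def sample(self, n: int, rng: np.random.Generator) -> pd.DataFrame:
        size = _truncated(
            lambda m: np.exp(rng.normal(np.log(self.size_median_um2), self.size_sigma, m)),
            n,
            self.size_window_um2,
            rng,
        )
        intensity = _truncated(
            lambda m: rng.normal(self.intensity_mu, self.intensity_sd, m), n, (0.0, 255.0), rng
        )
        solidity = 0.7 + 0.3 * rng.beta(self.solidity_a, self.solidity_b, n)
        return pd.DataFrame(
            {"area_um2": size, "mean_intensity": intensity, "solidity": solidity}
        )


def _truncated(draw, n: int, bounds: tuple[float, float], rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample ``n`` values of ``draw`` inside closed ``bounds``."""
    lo, hi = bounds
    out = np.empty(0)
    while out.size < n:
        x = np.asarray(draw(max(n - out.size, 16) * 2))
        out = np.concatenate([out, x[(x >= lo) & (x <= hi)]])
    return out[:n]


@dataclass(frozen=True)
class ClassMixture:
    """Phenotype mixing proportions of one disease class."""

    disease_class: str
    proportions: tuple[float, float, float]

    def __post_init__(self) -> None:
        p = np.asarray(self.proportions, dtype=float)
        if (p < 0).any() or abs(p.sum() - 1.0) > 1e-12:
            raise ValueError(f"proportions must be >= 0 and sum to 1, got {self.proportions}")


#: archetype defaults: small/dim, small/bright, large — with a 22–28 µm² size gap.
#: The two small phenotypes share one size distribution and differ only in
#: intensity; size separates only small from large, so the supervised cutoff
#: search has a well-defined answer inside the gap.
DEFAULT_PHENOTYPES: dict[str, PhenotypeParams] = {
    "CLL-like": PhenotypeParams(
        "CLL-like", size_median_um2=15.0, size_sigma=0.12, intensity_mu=110.0,
        intensity_sd=7.0, size_window_um2=(8.0, 22.0),
    ),
    "aCLL-like": PhenotypeParams(
        "aCLL-like", size_median_um2=15.0, size_sigma=0.12, intensity_mu=160.0,
        intensity_sd=7.0, size_window_um2=(8.0, 22.0),
    ),
    "RT-like": PhenotypeParams(
        "RT-like", size_median_um2=45.0, size_sigma=0.15, intensity_mu=130.0,
        intensity_sd=10.0, size_window_um2=(28.0, 108.0),
    ),
}

#: size gap (µm²) separating small from large archetypes under the defaults
DEFAULT_SIZE_GAP_UM2 = (22.0, 28.0)

#: phenotype enrichment shifting across disease stages
DEFAULT_MIXTURES: dict[str, ClassMixture] = {
    "CLL": ClassMixture("CLL", (0.80, 0.15, 0.05)),
    "aCLL": ClassMixture("aCLL", (0.30, 0.55, 0.15)),
    "RT": ClassMixture("RT", (0.10, 0.20, 0.70)),
}

#: identical mixtures across classes — a no-signal null cohort
NULL_MIXTURES: dict[str, ClassMixture] = {
    c: ClassMixture(c, (0.40, 0.35, 0.25)) for c in DISEASE_CLASSES
}


@dataclass(frozen=True)
class CohortConfig:
    """Size and noise parameters of a generated cohort."""

    patients_per_class: int = 20
    slides_per_patient: tuple[int, int] = (1, 2)
    rois_per_slide: tuple[int, int] = (1, 8)
    cells_per_roi: tuple[int, int] = (150, 400)
    roi_width_px: int = 1024
    roi_height_px: int = 1024
    resolution: float = 0.50
    contaminant_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.roi_width_px < 512 or self.roi_height_px < 512:
            raise ValueError("ROI dimensions must be at least 512 px")
        if not (0 <= self.contaminant_fraction < 1):
            raise ValueError("contaminant_fraction must be in [0, 1)")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        for name in ("slides_per_patient", "rois_per_slide", "cells_per_roi"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} range {lo}..{hi} invalid")


def generate_roi_cells(
    disease_class: str,
    n_cells: int,
    mixtures: Mapping[str, ClassMixture] | None = None,
    phenotype_params: Mapping[str, PhenotypeParams] | None = None,
    roi_dims_px: tuple[int, int] = (1024, 1024),
    resolution: float = 0.50,
    seed: int = 0,
    roi_id: str = "roi",
    contaminant_fraction: float = 0.0,
) -> CellTable:
    """Sample one ROI's cells for ``disease_class``.

    Centroids are uniform over the ROI rectangle; each cell's phenotype is
    drawn from the class mixture, its attributes from that phenotype's
    distributions.  A ``contaminant_fraction`` of cells is corrupted to
    violate a QC rule (solidity < 0.84, or area outside 8–108 µm²); the
    returned table carries ``truth_phenotype`` and ``is_contaminant``
    columns as ground truth.
    """
    mixtures = DEFAULT_MIXTURES if mixtures is None else mixtures
    phenotype_params = DEFAULT_PHENOTYPES if phenotype_params is None else phenotype_params
    if disease_class not in mixtures:
        raise ValueError(
            f"unknown disease class {disease_class!r}; mixtures define {sorted(mixtures)}"
        )
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    w_px, h_px = roi_dims_px
    rng = np.random.default_rng(seed)

    props = np.asarray(mixtures[disease_class].proportions, dtype=float)
    pheno_idx = rng.choice(3, size=n_cells, p=props)
    area_um2 = np.empty(n_cells)
    intensity = np.empty(n_cells)
    solidity = np.empty(n_cells)
    truth = np.empty(n_cells, dtype=object)
    for i, name in enumerate(PHENOTYPE_NAMES):
        pos = np.flatnonzero(pheno_idx == i)
        df_i = phenotype_params[name].sample(len(pos), rng)
        area_um2[pos] = df_i["area_um2"]
        intensity[pos] = df_i["mean_intensity"]
        solidity[pos] = df_i["solidity"]
        truth[pos] = name
    cells = pd.DataFrame(
        {
            "area_um2": area_um2,
            "mean_intensity": intensity,
            "solidity": solidity,
            "truth_phenotype": truth,
        }
    )

    is_cont = rng.random(n_cells) < contaminant_fraction
    cells["is_contaminant"] = is_cont
    if is_cont.any():
        mode = rng.integers(0, 3, size=int(is_cont.sum()))
        idx = np.flatnonzero(is_cont)
        # mode 0: overlapping-nucleus artifact (low solidity)
        cells.loc[idx[mode == 0], "solidity"] = rng.uniform(0.5, 0.8399, (mode == 0).sum())
        # mode 1: debris below the size window; mode 2: clump above it
        cells.loc[idx[mode == 1], "area_um2"] = rng.uniform(1.0, 7.5, (mode == 1).sum())
        cells.loc[idx[mode == 2], "area_um2"] = rng.uniform(110.0, 300.0, (mode == 2).sum())

    area_px = np.maximum(1, np.rint(cells["area_um2"].to_numpy(float) / resolution**2)).astype(int)
    out = pd.DataFrame(
        {
            "cell_id": np.arange(1, n_cells + 1),
            "area_px": area_px,
            "mean_intensity": cells["mean_intensity"].to_numpy(float),
            "centroid_x_px": rng.uniform(0, w_px, n_cells),
            "centroid_y_px": rng.uniform(0, h_px, n_cells),
            "solidity": cells["solidity"].to_numpy(float),
            "truth_phenotype": cells["truth_phenotype"].to_numpy(object),
            "is_contaminant": is_cont,
        }
    )
    return CellTable(roi_id, out, resolution, w_px, h_px, disease_label=disease_class)


def generate_cohort(
    config: CohortConfig,
    mixtures: Mapping[str, ClassMixture] | None = None,
    phenotype_params: Mapping[str, PhenotypeParams] | None = None,
) -> tuple[CohortManifest, dict[str, CellTable]]:
    """Generate a full cohort: manifest plus one cell table per ROI.

    Per-ROI random streams are derived by stable hashing of
    (master seed, patient, slide, roi), so any subset of the cohort is
    reproducible in isolation.
    """
    mixtures = DEFAULT_MIXTURES if mixtures is None else mixtures
    phenotype_params = DEFAULT_PHENOTYPES if phenotype_params is None else phenotype_params
    rng = np.random.default_rng(derive_seed(config.seed, "hierarchy"))
    patients: list[Patient] = []
    tables: dict[str, CellTable] = {}
    for cls in DISEASE_CLASSES:
        for i in range(config.patients_per_class):
            pid = f"{cls}_p{i:03d}"
            covs = {name: int(rng.integers(0, 2)) for name in COVARIATE_NAMES}
            n_slides = int(rng.integers(config.slides_per_patient[0], config.slides_per_patient[1] + 1))
            slides = []
            for s in range(n_slides):
                sid = f"{pid}_s{s}"
                n_rois = int(rng.integers(config.rois_per_slide[0], config.rois_per_slide[1] + 1))
                roi_ids = []
                for r in range(n_rois):
                    rid = f"{sid}_r{r}"
                    n_cells = int(rng.integers(config.cells_per_roi[0], config.cells_per_roi[1] + 1))
                    tables[rid] = generate_roi_cells(
                        cls,
                        n_cells,
                        mixtures,
                        phenotype_params,
                        (config.roi_width_px, config.roi_height_px),
                        config.resolution,
                        seed=derive_seed(config.seed, pid, sid, rid),
                        roi_id=rid,
                        contaminant_fraction=config.contaminant_fraction,
                    )
                    roi_ids.append(rid)
                slides.append(Slide(sid, roi_ids))
            patients.append(Patient(pid, cls, covs, slides))
    return CohortManifest(patients), tables


# --------------------------------------------------------------------- rendering

def render_label_mask(
    table: CellTable,
    max_attempts: int = 50,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Render a cell table as an instance label mask plus a grayscale image.

    Each cell is drawn as an ellipse of its recorded pixel area, first at its
    recorded centroid and, on overlap, at random positions (up to
    ``max_attempts``); cells that cannot be placed are skipped and reported.

    Returns
    -------
    mask : uint16 array (H, W) with labels 1..n, background 0
    image : uint8 array (H, W), each nucleus filled with its mean intensity
    placed_cell_ids : cell ids actually drawn, in mask-label order
    """
    from skimage.draw import ellipse

    h, w = table.roi_height_px, table.roi_width_px
    mask = np.zeros((h, w), dtype=np.uint16)
    image = np.zeros((h, w), dtype=np.uint8)
    rng = np.random.default_rng(seed)
    placed: list[int] = []
    label = 0
    for row in table.cells.itertuples(index=False):
        area = float(row.area_px)
        ratio = rng.uniform(0.75, 1.0)  # minor/major axis ratio
        a = np.sqrt(area / (np.pi * ratio))  # semi-major (continuous estimate)
        pos = [(float(row.centroid_y_px), float(row.centroid_x_px))]
        if h > 2 * a + 2 and w > 2 * a + 2:
            pos += [
                (rng.uniform(a + 1, h - a - 1), rng.uniform(a + 1, w - a - 1))
                for _ in range(max_attempts - 1)
            ]
        for cy, cx in pos:
            # the rasterized pixel count of a small ellipse deviates from
            # pi*a*b and depends on the fractional center, so pick the axis
            # scale whose pixel count is closest to the requested area
            best = None
            for s in np.linspace(0.85, 1.15, 16):
                rr, cc = ellipse(cy, cx, a * s, a * s * ratio)
                if (
                    rr.size == 0
                    or rr.min() < 0
                    or cc.min() < 0
                    or rr.max() >= h
                    or cc.max() >= w
                    or mask[rr, cc].any()
                ):
                    continue
                d = abs(rr.size - area)
                if best is None or d < best[0]:
                    best = (d, rr, cc)
            if best is None or best[0] > 0.05 * area:
                continue  # crowded or clipped here; try the next position
            label += 1
            mask[best[1], best[2]] = label
            image[best[1], best[2]] = int(np.clip(round(float(row.mean_intensity)), 0, 255))
            placed.append(int(row.cell_id))
            break
    return mask, image, placed


def write_cohort(
    out_dir,
    manifest: CohortManifest,
    tables: Mapping[str, CellTable],
    render_masks: bool = False,
    seed: int = 0,
) -> None:
    """Write a generated cohort to disk (manifest JSON, per-ROI CSV, optional TIFFs)."""
    import pathlib

    from cellpheno.ingest import write_cell_table

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest.write_json(out / "manifest.json")
    cells_dir = out / "cells"
    cells_dir.mkdir(exist_ok=True)
    for rid, table in tables.items():
        write_cell_table(table, cells_dir / f"{rid}.csv")
    if render_masks:
        import tifffile

        mask_dir = out / "masks"
        mask_dir.mkdir(exist_ok=True)
        for rid, table in tables.items():
            mask, image, _ = render_label_mask(table, seed=derive_seed(seed, "mask", rid))
            tifffile.imwrite(mask_dir / f"{rid}_mask.tif", mask)
            tifffile.imwrite(mask_dir / f"{rid}_gray.tif", image)
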