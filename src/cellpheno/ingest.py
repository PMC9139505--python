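"""Reading segmentation outputs and applying nuclear quality filters.

The segmenter itself (e.g. a pretrained Hover-Net) is external: this module
consumes its instance label masks, or per-cell CSV tables produced by any
tool, and applies the two quality rules used throughout the pipeline —
a solidity cutoff of 0.84 that removes merged/overlapping nuclei, and a
biological size window of 8–108 µm² (32–432 px at 0.50 µm/pixel).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from cellpheno.data import (
    CELL_COLUMNS,
    DISEASE_CLASSES,
    CellTable,
    SchemaError,
)

#: default QC thresholds
SOLIDITY_MIN = 0.84
AREA_WINDOW_UM2 = (8.0, 108.0)


def pixel_area_to_um2(area_px, resolution_um_per_px: float):
    """Convert a pixel count to physical area: area_px × resolution².

    At 0.50 µm/pixel the 32–432 px segmentation window maps to 8–108 µm².
    """
    if resolution_um_per_px <= 0:
        raise ValueError(f"resolution must be positive, got {resolution_um_per_px}")
    area_px = np.asarray(area_px)
    if (area_px < 0).any():
        raise ValueError("area_px must be >= 0")
    out = area_px * resolution_um_per_px**2
    return float(out) if out.ndim == 0 else out


def cells_from_mask(
    label_mask: np.ndarray,
    intensity_image: np.ndarray,
    resolution: float,
    roi_id: str = "roi",
    disease_label: str | None = None,
) -> CellTable:
    """Extract per-nucleus attributes from an instance label mask.

    One cell per positive label: area is the pixel count, intensity the mean
    of ``intensity_image`` over the label's pixels, the centroid the
    unweighted pixel centroid (x = column, y = row, 0-based), and solidity
    the ratio of the area to its convex-hull pixel area.
    """
    from skimage.measure import regionprops

    label_mask = np.asarray(label_mask)
    intensity_image = np.asarray(intensity_image)
    if label_mask.shape != intensity_image.shape:
        raise ValueError(
            f"mask shape {label_mask.shape} != image shape {intensity_image.shape}"
        )
    if not np.issubdtype(label_mask.dtype, np.integer):
        raise ValueError(f"label mask must be integer-typed, got {label_mask.dtype}")

    rows = []
    for rp in regionprops(label_mask, intensity_image=intensity_image):
        cy, cx = rp.centroid  # (row, col), unweighted
        rows.append(
            {
                "cell_id": int(rp.label),
                "area_px": int(rp.area),
                "mean_intensity": float(rp.intensity_mean),
                "centroid_x_px": float(cx),
                "centroid_y_px": float(cy),
                "solidity": float(rp.solidity),
            }
        )
    cells = pd.DataFrame(rows, columns=list(CELL_COLUMNS))
    h, w = label_mask.shape
    return CellTable(roi_id, cells, resolution, w, h, disease_label=disease_label)


# ------------------------------------------------------------------------ I/O

_META_KEYS = ("roi_id", "resolution", "roi_width_px", "roi_height_px", "disease_label")


def write_cell_table(table: CellTable, path) -> None:
    """Write a cell table as CSV with ROI metadata in ``#``-comment header lines."""
    cols = [c for c in table.cells.columns if c not in ("area_um2", "centroid_x_um", "centroid_y_um")]
    with open(path, "w") as fh:
        fh.write(f"# roi_id={table.roi_id}\n")
        fh.write(f"# resolution={table.resolution!r}\n")
        fh.write(f"# roi_width_px={table.roi_width_px}\n")
        fh.write(f"# roi_height_px={table.roi_height_px}\n")
        fh.write(f"# disease_label={table.disease_label or ''}\n")
        table.cells[cols].to_csv(fh, index=False)


def read_cell_table(
    path,
    resolution: float | None = None,
    roi_width_px: int | None = None,
    roi_height_px: int | None = None,
) -> CellTable:
    """Read a cell-table CSV (schema-checked, range-validated).

    ROI metadata is taken from ``#``-comment header lines when present;
    explicit arguments override.  Missing required columns raise
    :class:`~cellpheno.data.SchemaError` naming the column; out-of-range
    intensity or solidity raises a validation error listing the rows.
    """
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        cells = pd.read_csv(fh)
    missing = [c for c in CELL_COLUMNS if c not in cells.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    resolution = resolution if resolution is not None else float(meta.get("resolution", "nan"))
    if not np.isfinite(resolution):
        raise ValueError(f"{path}: resolution not in header; pass resolution=")
    w = roi_width_px if roi_width_px is not None else int(meta.get("roi_width_px", 0))
    h = roi_height_px if roi_height_px is not None else int(meta.get("roi_height_px", 0))
    label = meta.get("disease_label") or None
    if label is not None and label not in DISEASE_CLASSES:
        label = None
    if "is_contaminant" in cells.columns:
        cells["is_contaminant"] = cells["is_contaminant"].astype(bool)
    return CellTable(meta.get("roi_id", str(path)), cells, resolution, w, h, disease_label=label)


# ------------------------------------------------------------------------ QC


@dataclass
class FilterReport:
    """Per-rule removal counts of one QC pass.

    Each removed cell is attributed to exactly one rule (solidity checked
    first), so the counts sum to ``n_input - n_kept``.
    """

    n_input: int
    n_kept: int
    removed_low_solidity: int
    removed_area_out_of_window: int
    n_both_violations: int = 0

    @property
    def n_removed(self) -> int:
        return self.n_input - self.n_kept


def filter_cells(
    table: CellTable,
    solidity_min: float = SOLIDITY_MIN,
    area_window_um2: tuple[float, float] = AREA_WINDOW_UM2,
) -> tuple[CellTable, FilterReport]:
    """Apply the solidity and size quality rules.

    Keeps cells with solidity >= ``solidity_min`` AND area within the closed
    ``area_window_um2``.  Relative cell order is preserved; the operation is
    idempotent.
    """
    lo, hi = area_window_um2
    if lo > hi:
        raise ValueError(f"area window low {lo} > high {hi}")
    cells = table.cells
    sol_ok = cells["solidity"].to_numpy() >= solidity_min
    area = cells["area_um2"].to_numpy()
    area_ok = (area >= lo) & (area <= hi)
    keep = sol_ok & area_ok
    report = FilterReport(
        n_input=len(cells),
        n_kept=int(keep.sum()),
        removed_low_solidity=int((~sol_ok).sum()),
        removed_area_out_of_window=int((sol_ok & ~area_ok).sum()),
        n_both_violations=int((~sol_ok & ~area_ok).sum()),
    )
    return table.with_cells(cells[keep].reset_index(drop=True)), report
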