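"""Core data containers: per-ROI cell tables and the patient/slide/ROI manifest.

A :class:`CellTable` wraps a pandas DataFrame of segmented nuclei together
with the ROI geometry (physical size, pixel resolution) needed to convert
pixel measurements into micrometres.  A :class:`CohortManifest` records the
patient -> slide -> ROI hierarchy with the disease label and the binary
clinical covariates used for balanced splitting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: canonical disease-class order used everywhere (labels, class indices, plots)
DISEASE_CLASSES = ("CLL", "aCLL", "RT")

#: columns every cell table must carry (pixel units, as written by segmenters)
CELL_COLUMNS = (
    "cell_id",
    "area_px",
    "mean_intensity",
    "centroid_x_px",
    "centroid_y_px",
    "solidity",
)

#: derived physical-unit columns added on construction
DERIVED_COLUMNS = ("area_um2", "centroid_x_um", "centroid_y_um")


@dataclass(frozen=True)
class Cell:
    """A single segmented nucleus (pixel units plus derived µm quantities)."""

    cell_id: int
    area_px: int
    mean_intensity: float
    centroid_x_px: float
    centroid_y_px: float
    solidity: float
    area_um2: float
    centroid_x_um: float
    centroid_y_um: float


class CellTable:
    """Segmented nuclei of one ROI plus ROI geometry.

    Parameters
    ----------
    roi_id
        Unique ROI identifier within the cohort.
    cells
        DataFrame with at least the columns in :data:`CELL_COLUMNS`.
        Extra columns (``phenotype``, ``truth_phenotype``, ``is_contaminant``)
        are preserved.
    resolution
        Pixel size in µm/pixel (0.50 for the 20x scans this pipeline targets).
    roi_width_px, roi_height_px
        ROI extent in pixels; must be >= 512 so the ROI holds enough cells.
    disease_label
        Optional class label (``CLL``/``aCLL``/``RT``) inherited from the
        patient.
    """

    def __init__(
        self,
        roi_id: str,
        cells: pd.DataFrame,
        resolution: float,
        roi_width_px: int,
        roi_height_px: int,
        disease_label: str | None = None,
        validate: bool = True,
    ) -> None:
        if resolution <= 0:
            raise ValueError(f"resolution must be positive, got {resolution}")
        self.roi_id = str(roi_id)
        self.resolution = float(resolution)
        self.roi_width_px = int(roi_width_px)
        self.roi_height_px = int(roi_height_px)
        if disease_label is not None and disease_label not in DISEASE_CLASSES:
            raise ValueError(
                f"unknown disease label {disease_label!r}; expected one of {DISEASE_CLASSES}"
            )
        self.disease_label = disease_label

        cells = cells.reset_index(drop=True).copy()
        missing = [c for c in CELL_COLUMNS if c not in cells.columns]
        if missing:
            raise SchemaError(f"cell table missing required column(s): {', '.join(missing)}")
        # derived physical-unit columns
        cells["area_um2"] = cells["area_px"].astype(float) * self.resolution**2
        cells["centroid_x_um"] = cells["centroid_x_px"].astype(float) * self.resolution
        cells["centroid_y_um"] = cells["centroid_y_px"].astype(float) * self.resolution
        if validate:
            _validate_cells(cells)
        self.cells = cells

    # ------------------------------------------------------------------ geometry
    @property
    def roi_width_um(self) -> float:
        return self.roi_width_px * self.resolution

    @property
    def roi_height_um(self) -> float:
        return self.roi_height_px * self.resolution

    @property
    def roi_area_mm2(self) -> float:
        """ROI rectangle area in mm² (density denominator)."""
        return self.roi_width_um * self.roi_height_um / 1e6

    # ------------------------------------------------------------------ protocol
    def __len__(self) -> int:
        return len(self.cells)

    def __iter__(self) -> Iterable[Cell]:
        for row in self.cells.itertuples(index=False):
            yield Cell(
                cell_id=int(row.cell_id),
                area_px=int(row.area_px),
                mean_intensity=float(row.mean_intensity),
                centroid_x_px=float(row.centroid_x_px),
                centroid_y_px=float(row.centroid_y_px),
                solidity=float(row.solidity),
                area_um2=float(row.area_um2),
                centroid_x_um=float(row.centroid_x_um),
                centroid_y_um=float(row.centroid_y_um),
            )

    def with_cells(self, cells: pd.DataFrame, validate: bool = False) -> "CellTable":
        """A copy of this table holding ``cells`` but the same ROI metadata."""
        return CellTable(
            self.roi_id,
            cells,
            self.resolution,
            self.roi_width_px,
            self.roi_height_px,
            self.disease_label,
            validate=validate,
        )

    def equals(self, other: "CellTable") -> bool:
        return (
            self.roi_id == other.roi_id
            and self.resolution == other.resolution
            and self.roi_width_px == other.roi_width_px
            and self.roi_height_px == other.roi_height_px
            and self.disease_label == other.disease_label
            and self.cells.equals(other.cells)
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"CellTable(roi_id={self.roi_id!r}, n_cells={len(self)}, "
            f"{self.roi_width_px}x{self.roi_height_px}px @ {self.resolution} µm/px, "
            f"label={self.disease_label!r})"
        )


class SchemaError(ValueError):
    """A cell-table file does not carry the required columns."""


class ValidationError(ValueError):
    """Cell attributes violate their physical ranges."""


def _validate_cells(cells: pd.DataFrame) -> None:
    """Range checks on intensity and solidity; offending row indices reported."""
    if len(cells) == 0:
        return
    bad_int = cells.index[
        (cells["mean_intensity"] < 0) | (cells["mean_intensity"] > 255)
    ].tolist()
    if bad_int:
        raise ValidationError(f"mean_intensity outside [0, 255] in rows {bad_int}")
    bad_sol = cells.index[(cells["solidity"] <= 0) | (cells["solidity"] > 1)].tolist()
    if bad_sol:
        raise ValidationError(f"solidity outside (0, 1] in rows {bad_sol}")
    bad_area = cells.index[cells["area_px"] < 1].tolist()
    if bad_area:
        raise ValidationError(f"area_px < 1 in rows {bad_area}")


# ---------------------------------------------------------------------- manifest

#: binary clinical covariates recorded per patient and used as split strata
COVARIATE_NAMES = ("gender", "age_ge_60", "outside_source", "needle_biopsy", "os_short")


@dataclass
class Slide:
    slide_id: str
    roi_ids: list[str] = field(default_factory=list)


@dataclass
class Patient:
    patient_id: str
    disease_class: str
    covariates: dict[str, int] = field(default_factory=dict)
    slides: list[Slide] = field(default_factory=list)

    @property
    def roi_ids(self) -> list[str]:
        return [r for s in self.slides for r in s.roi_ids]


class CohortManifest:
    """Patient -> slide -> ROI hierarchy with disease labels and covariates."""

    def __init__(self, patients: Sequence[Patient]) -> None:
        self.patients = list(patients)
        seen: dict[str, str] = {}
        for p in self.patients:
            if p.disease_class not in DISEASE_CLASSES:
                raise ValueError(f"patient {p.patient_id}: unknown class {p.disease_class!r}")
            for rid in p.roi_ids:
                if rid in seen:
                    raise ValueError(
                        f"ROI {rid!r} mapped to both patients {seen[rid]!r} and {p.patient_id!r}"
                    )
                seen[rid] = p.patient_id

    # ------------------------------------------------------------------ lookups
    def patient_of_roi(self, roi_id: str) -> Patient:
        for p in self.patients:
            if roi_id in p.roi_ids:
                return p
        raise KeyError(roi_id)

    def roi_ids(self) -> list[str]:
        return [r for p in self.patients for r in p.roi_ids]

    def patients_by_class(self) -> dict[str, list[Patient]]:
        out: dict[str, list[Patient]] = {c: [] for c in DISEASE_CLASSES}
        for p in self.patients:
            out[p.disease_class].append(p)
        return out

    def roi_labels(self) -> dict[str, str]:
        return {r: p.disease_class for p in self.patients for r in p.roi_ids}

    def roi_patients(self) -> dict[str, str]:
        return {r: p.patient_id for p in self.patients for r in p.roi_ids}

    def __len__(self) -> int:
        return len(self.patients)

    # ------------------------------------------------------------------ I/O
    def to_dict(self) -> dict:
        return {
            "patients": [
                {
                    "id": p.patient_id,
                    "class": p.disease_class,
                    "covariates": dict(p.covariates),
                    "slides": [{"id": s.slide_id, "rois": list(s.roi_ids)} for s in p.slides],
                }
                for p in self.patients
            ]
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortManifest":
        patients = [
            Patient(
                patient_id=str(pd_["id"]),
                disease_class=str(pd_["class"]),
                covariates={k: int(v) for k, v in pd_.get("covariates", {}).items()},
                slides=[
                    Slide(slide_id=str(sd["id"]), roi_ids=[str(r) for r in sd["rois"]])
                    for sd in pd_.get("slides", [])
                ],
            )
            for pd_ in d["patients"]
        ]
        return cls(patients)

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def read_json(cls, path) -> "CohortManifest":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def derive_seed(master_seed: int, *keys) -> int:
    """Derive a reproducible child seed (< 2**31) from a master seed and keys.

    Strings are folded in through a stable CRC so per-ROI streams do not
    depend on iteration order.
    """
    import zlib

    ints = [int(master_seed) & 0x7FFFFFFF]
    for k in keys:
        if isinstance(k, str):
            ints.append(zlib.crc32(k.encode()) & 0x7FFFFFFF)
        else:
            ints.append(int(k) & 0x7FFFFFFF)
    ss = np.random.SeedSequence(ints)
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
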