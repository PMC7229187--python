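"""Shared data model, file formats and configuration.

The pipeline operates on per-cell coordinate tables exported from a slide
scanner (one CSV per slide per patient), tumor geometry as GeoJSON (a tumor
polygon plus the invasive-front polyline, coordinates in micrometres), and a
cohort survival table.  Coordinates follow image convention: origin top-left,
y increasing downward; all distances are Euclidean in micrometres.

Every tunable of the pipeline lives in :class:`PipelineConfig`; printed
constants (classification thresholds, band widths, selection parameters) are
named defaults there, never hard-coded in the stage implementations.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import LineString, Polygon, mapping, shape
from shapely.validation import make_valid

COMPARTMENTS = ("nucleus", "cytoplasm", "membrane")
CHANNELS = ("FITC", "Cy5", "CY3_PCK")
PHENOTYPE_LABELS = ("CD3", "CD8", "CD68", "CD163", "TUMOR")


class SchemaError(ValueError):
    """A required column is missing or mis-declared."""


class ValidationError(ValueError):
    """A record violates an invariant of the data model."""


@dataclass
class CellRecord:
    """One segmented cell: centroid plus compartment intensities and/or flags.

    ``intensities`` maps ``"{compartment}_{channel}"`` (e.g. ``nucleus_FITC``)
    to a nonnegative mean dye intensity; ``phenotypes`` is the set of marker
    labels the cell carries.  At least one of the two must be present so the
    pipeline can be entered either before or after classification.
    """

    cell_id: str
    x_um: float
    y_um: float
    intensities: dict[str, float] = field(default_factory=dict)
    phenotypes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.x_um = float(self.x_um)
        self.y_um = float(self.y_um)
        if not (np.isfinite(self.x_um) and np.isfinite(self.y_um)):
            raise ValidationError(f"cell {self.cell_id}: non-finite coordinates")
        for key, val in self.intensities.items():
            if val < 0:
                raise ValidationError(f"cell {self.cell_id}: negative intensity {key}")
        if not self.intensities and not self.phenotypes:
            raise ValidationError(
                f"cell {self.cell_id}: need intensities or phenotypes"
            )
        unknown = set(self.phenotypes) - set(PHENOTYPE_LABELS)
        if unknown:
            raise ValidationError(f"cell {self.cell_id}: unknown phenotypes {unknown}")


@dataclass
class Transform2D:
    """Affine map ``p -> A p + t`` between slide coordinate frames (μm)."""

    linear: np.ndarray  # 2x2
    translation: np.ndarray  # (2,)
    kind: str = "similarity"  # identity | similarity | affine
    rmse_um: float = 0.0

    def __post_init__(self) -> None:
        self.linear = np.asarray(self.linear, dtype=float).reshape(2, 2)
        self.translation = np.asarray(self.translation, dtype=float).reshape(2)
        det = float(np.linalg.det(self.linear))
        if det == 0.0:
            raise ValidationError("transform linear part is singular")
        if self.kind == "similarity":
            # A = s R with R orthogonal, s > 0
            s = np.sqrt(abs(det))
            R = self.linear / s
            if not np.allclose(R @ R.T, np.eye(2), atol=1e-8):
                raise ValidationError("similarity transform is not s*R")

    @classmethod
    def identity(cls) -> "Transform2D":
        return cls(np.eye(2), np.zeros(2), kind="identity")

    def to_dict(self) -> dict:
        return {
            "linear": self.linear.tolist(),
            "translation": self.translation.tolist(),
            "kind": self.kind,
            "rmse_um": float(self.rmse_um),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Transform2D":
        return cls(
            np.asarray(d["linear"], dtype=float),
            np.asarray(d["translation"], dtype=float),
            kind=d.get("kind", "affine"),
            rmse_um=float(d.get("rmse_um", 0.0)),
        )


@dataclass
class SlidePair:
    """Two coregistered serial sections of one tumor.

    Slide 1 carries the lymphocyte panel (CD3/CD8/PCK), slide 2 the
    macrophage panel (CD68/CD163/PCK); ``transform`` maps slide-2 coordinates
    into the slide-1 frame.
    """

    slide1_cells: list[CellRecord]
    slide2_cells: list[CellRecord]
    transform: Transform2D = field(default_factory=Transform2D.identity)


@dataclass
class SurvivalRecord:
    """Disease-specific survival outcome for one patient."""

    patient_id: str
    time_months: float
    event: int
    covariates: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.time_months > 0:
            raise ValidationError(
                f"patient {self.patient_id}: time_months must be > 0"
            )
        if self.event not in (0, 1):
            raise ValidationError(f"patient {self.patient_id}: event must be 0/1")


@dataclass
class PipelineConfig:
    """All tunables of the pipeline, with the published defaults.

    Classification thresholds are dye-intensity cutoffs per compartment and
    channel; band widths define the invasive-margin (IM) and tumor-budding
    (TBROI) regions; the selection block parameterizes the LASSO Cox /
    random-forest / cutpoint chain that builds the index.
    """

    # -- classification (lymphocyte slide: CD3=FITC, CD8=Cy5) --------------
    lymph_nucleus_fitc: float = 0.15
    lymph_nucleus_cy5: float = 0.132
    lymph_cytoplasm_fitc: float = 0.5
    lymph_cytoplasm_cy5: float = 0.075
    lymph_membrane_fitc: float = 0.5
    lymph_membrane_cy5: float = 0.075
    # -- classification (macrophage slide: CD68=FITC, CD163=Cy5) -----------
    macro_nucleus_fitc: float = 0.200
    macro_nucleus_cy5: float = 0.132
    macro_cytoplasm_fitc: float = 0.500
    macro_cytoplasm_cy5: float = 0.075
    macro_membrane_fitc: float = 0.500
    macro_membrane_cy5: float = 0.075
    positivity_rule: str = "any"  # any | nucleus | cytoplasm_and_membrane
    pck_slide_threshold: float = 2.16e-2
    pck_buffer_um: float = 20.0
    # -- regions ------------------------------------------------------------
    im_half_width_um: float = 500.0
    tbroi_width_um: float = 1000.0
    # -- buds ---------------------------------------------------------------
    bud_link_distance_um: float = 15.0
    # -- proximity ----------------------------------------------------------
    proximity_radii_um: tuple[float, ...] = (50.0, 100.0)
    zero_bud_policy: str = "favorable"  # favorable | missing | zero
    # -- selection chain ----------------------------------------------------
    lasso_folds: int = 10
    lasso_lambda_rule: str = "min"  # min | 1se
    rf_trees: int = 500
    gini_threshold: float = 3.0
    correlation_prune_threshold: float = 0.8
    cutpoint_min_group_prop: float = 0.1
    forward_entry_p: float = 0.05
    refine_criterion: str = "wald_p"  # wald_p | lr_chi2
    # -- misc ---------------------------------------------------------------
    censor_horizon_months: float | None = None
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.im_half_width_um <= 0 or self.tbroi_width_um <= 0:
            raise ValidationError("band widths must be > 0")
        if self.bud_link_distance_um <= 0:
            raise ValidationError("bud_link_distance_um must be > 0")
        radii = tuple(float(r) for r in self.proximity_radii_um)
        if any(r <= 0 for r in radii) or list(radii) != sorted(radii):
            raise ValidationError("proximity radii must be positive and ascending")
        self.proximity_radii_um = radii
        if not 0 < self.cutpoint_min_group_prop < 0.5:
            raise ValidationError("cutpoint_min_group_prop must be in (0, 0.5)")

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["proximity_radii_um"] = list(d["proximity_radii_um"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "proximity_radii_um" in d:
            d["proximity_radii_um"] = tuple(d["proximity_radii_um"])
        return cls(**d)


# ---------------------------------------------------------------------------
# cell tables
# ---------------------------------------------------------------------------

_INTENSITY_COLS = [f"{c}_{ch}" for c in COMPARTMENTS for ch in CHANNELS]


def read_cell_table(
    path: str | Path, schema: Mapping[str, str] | None = None
) -> list[CellRecord]:
    """Read a per-cell CSV into :class:`CellRecord` s, preserving row order.

    ``schema`` maps canonical names (``cell_id``, ``x_um``, ``y_um``, the
    ``{compartment}_{channel}`` intensity names, ``phenotypes``) to the CSV's
    actual column names; identity by default.  Unknown columns are ignored.
    """
    schema = dict(schema or {})
    df = pd.read_csv(path, dtype=str)
    df.columns = [c.strip() for c in df.columns]

    def col(name: str) -> str | None:
        c = schema.get(name, name)
        return c if c in df.columns else None

    for coord in ("x_um", "y_um"):
        if col(coord) is None:
            raise SchemaError(f"missing coordinate column {schema.get(coord, coord)!r}")

    records: list[CellRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        row = dict(zip(df.columns, row))

        def num(name: str, row=row, i=i) -> float:
            raw = row[schema.get(name, name)]
            try:
                return float(raw)
            except (TypeError, ValueError):
                raise ValueError(f"row {i}: non-numeric value {raw!r} for {name}")

        intens: dict[str, float] = {}
        for key in _INTENSITY_COLS:
            c = col(key)
            if c is not None and row[c] not in (None, "") and row[c] == row[c]:
                intens[key] = num(key)
        phen: frozenset[str] = frozenset()
        pc = col("phenotypes")
        if pc is not None and isinstance(row[pc], str) and row[pc]:
            phen = frozenset(row[pc].split(";"))
        cid_col = col("cell_id")
        cid = str(row[cid_col]) if cid_col else str(i)
        records.append(
            CellRecord(cid, num("x_um"), num("y_um"), intens, phen)
        )
    return records


def write_cell_table(cells: Sequence[CellRecord], path: str | Path) -> None:
    """Write cells to CSV (inverse of :func:`read_cell_table`)."""
    rows = []
    for c in cells:
        row: dict[str, object] = {"cell_id": c.cell_id,
                                  "x_um": repr(float(c.x_um)),
                                  "y_um": repr(float(c.y_um))}
        for key in _INTENSITY_COLS:
            if key in c.intensities:
                row[key] = repr(float(c.intensities[key]))
        row["phenotypes"] = ";".join(sorted(c.phenotypes))
        rows.append(row)
    cols = ["cell_id", "x_um", "y_um", *_INTENSITY_COLS, "phenotypes"]
    df = pd.DataFrame(rows)
    df = df.reindex(columns=[c for c in cols if c in df.columns])
    df.to_csv(path, index=False)


def cells_to_frame(cells: Sequence[CellRecord]) -> pd.DataFrame:
    """Vector view of a cell list: one row per cell, phenotype flag columns."""
    n = len(cells)
    out = pd.DataFrame(
        {
            "cell_id": [c.cell_id for c in cells],
            "x_um": np.array([c.x_um for c in cells], dtype=float),
            "y_um": np.array([c.y_um for c in cells], dtype=float),
        },
        index=range(n),
    )
    for label in PHENOTYPE_LABELS:
        out[label] = np.array([label in c.phenotypes for c in cells], dtype=bool)
    return out


def coords(cells: Sequence[CellRecord]) -> np.ndarray:
    """(n, 2) array of centroids in μm."""
    if not cells:
        return np.empty((0, 2))
    return np.array([[c.x_um, c.y_um] for c in cells], dtype=float)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


def read_geometry(path: str | Path) -> tuple[Polygon, LineString]:
    """Read tumor polygon + invasive-front polyline from GeoJSON.

    Features are role-tagged via ``properties.role`` as ``"tumor"`` (Polygon)
    and ``"invasive_front"`` (LineString); coordinates in μm.
    """
    gj = json.loads(Path(path).read_text())
    tumor = front = None
    for feat in gj.get("features", []):
        role = (feat.get("properties") or {}).get("role")
        if role == "tumor":
            tumor = shape(feat["geometry"])
        elif role == "invasive_front":
            front = shape(feat["geometry"])
    if tumor is None or front is None:
        raise SchemaError("GeoJSON must contain features with roles 'tumor' and 'invasive_front'")
    tumor = make_valid(tumor)
    if tumor.area == 0:
        raise ValidationError("tumor polygon has zero area")
    if not isinstance(front, LineString) or len(front.coords) < 2:
        raise ValidationError("invasive front must be a LineString with >= 2 vertices")
    return tumor, front


def write_geometry(tumor: Polygon, front: LineString, path: str | Path) -> None:
    gj = {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "properties": {"role": "tumor"}, "geometry": mapping(tumor)},
            {
                "type": "Feature",
                "properties": {"role": "invasive_front"},
                "geometry": mapping(front),
            },
        ],
    }
    Path(path).write_text(json.dumps(gj))


# ---------------------------------------------------------------------------
# survival and feature tables
# ---------------------------------------------------------------------------


def read_survival_table(path: str | Path) -> list[SurvivalRecord]:
    """Read the cohort survival CSV (patient_id, time_months, event, extras)."""
    df = pd.read_csv(path)
    for c in ("patient_id", "time_months", "event"):
        if c not in df.columns:
            raise SchemaError(f"survival table missing column {c!r}")
    ids = df["patient_id"].astype(str)
    if ids.duplicated().any():
        dup = ids[ids.duplicated()].iloc[0]
        raise ValidationError(f"duplicated patient_id {dup!r}")
    extras = [c for c in df.columns if c not in ("patient_id", "time_months", "event")]
    return [
        SurvivalRecord(
            str(r["patient_id"]),
            float(r["time_months"]),
            int(r["event"]),
            {k: r[k] for k in extras},
        )
        for _, r in df.iterrows()
    ]


def write_survival_table(records: Sequence[SurvivalRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append({"patient_id": r.patient_id, "time_months": r.time_months,
                     "event": r.event, **r.covariates})
    pd.DataFrame(rows).to_csv(path, index=False)


def survival_frame(records: Sequence[SurvivalRecord]) -> pd.DataFrame:
    """Survival records as a DataFrame indexed by patient_id."""
    df = pd.DataFrame(
        {
            "time_months": [r.time_months for r in records],
            "event": [r.event for r in records],
        },
        index=pd.Index([r.patient_id for r in records], name="patient_id"),
    )
    return df


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write the patient × feature matrix (index = patient_id) to CSV."""
    table.to_csv(path, index=True, index_label="patient_id")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="patient_id")
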