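"""Marker phenotyping from compartment dye intensities.

Cells are called positive for a channel when their compartment intensities
exceed fixed, cohort-wide thresholds (the same values for every sample).  The
lymphocyte slide reads CD3 on FITC and CD8 on Cy5; the serial macrophage
slide reads CD68 on FITC and CD163 on Cy5 with a higher FITC nuclear cutoff.
Colocalized classes (CD3+CD8+, CD68+CD163+) require both channels positive.

The combination rule across compartments (one exceedance, nucleus required,
or cytoplasm-and-membrane) is configurable; the default calls a channel
positive when any compartment strictly exceeds its threshold.  All
comparisons are strict, so a value exactly at a threshold is negative.
"""

from __future__ import annotations

from dataclasses import dataclass

from shapely.geometry import Point, Polygon
from shapely.ops import unary_union

from .io_core import CellRecord, PipelineConfig, ValidationError

POSITIVITY_RULES = ("any", "nucleus", "cytoplasm_and_membrane")


@dataclass(frozen=True)
class ThresholdSet:
    """Per-compartment positivity thresholds for the two dye channels."""

    nucleus_fitc: float
    nucleus_cy5: float
    cytoplasm_fitc: float
    cytoplasm_cy5: float
    membrane_fitc: float
    membrane_cy5: float

    @classmethod
    def lymphocyte(cls, cfg: PipelineConfig | None = None) -> "ThresholdSet":
        cfg = cfg or PipelineConfig()
        return cls(cfg.lymph_nucleus_fitc, cfg.lymph_nucleus_cy5,
                   cfg.lymph_cytoplasm_fitc, cfg.lymph_cytoplasm_cy5,
                   cfg.lymph_membrane_fitc, cfg.lymph_membrane_cy5)

    @classmethod
    def macrophage(cls, cfg: PipelineConfig | None = None) -> "ThresholdSet":
        cfg = cfg or PipelineConfig()
        return cls(cfg.macro_nucleus_fitc, cfg.macro_nucleus_cy5,
                   cfg.macro_cytoplasm_fitc, cfg.macro_cytoplasm_cy5,
                   cfg.macro_membrane_fitc, cfg.macro_membrane_cy5)


def _channel_positive(cell: CellRecord, channel: str, thresholds: dict[str, float],
                      rule: str) -> bool:
    exceed = {}
    for compartment in ("nucleus", "cytoplasm", "membrane"):
        key = f"{compartment}_{channel}"
        if key not in cell.intensities:
            raise ValidationError(
                f"cell {cell.cell_id}: missing {compartment} intensity for {channel}"
            )
        exceed[compartment] = cell.intensities[key] > thresholds[compartment]
    if rule == "any":
        return any(exceed.values())
    if rule == "nucleus":
        return exceed["nucleus"]
    if rule == "cytoplasm_and_membrane":
        return exceed["cytoplasm"] and exceed["membrane"]
    raise ValueError(f"unknown positivity rule {rule!r}")


def _calls(cell: CellRecord, t: ThresholdSet, rule: str) -> tuple[bool, bool]:
    fitc = _channel_positive(
        cell, "FITC",
        {"nucleus": t.nucleus_fitc, "cytoplasm": t.cytoplasm_fitc,
         "membrane": t.membrane_fitc}, rule)
    cy5 = _channel_positive(
        cell, "Cy5",
        {"nucleus": t.nucleus_cy5, "cytoplasm": t.cytoplasm_cy5,
         "membrane": t.membrane_cy5}, rule)
    return fitc, cy5


def classify_lymphocyte(cell: CellRecord, t: ThresholdSet | None = None,
                        rule: str = "any") -> str:
    """Call a lymphocyte-slide cell: CD3+CD8-, CD3-CD8+, CD3+CD8+ or negative."""
    t = t or ThresholdSet.lymphocyte()
    cd3, cd8 = _calls(cell, t, rule)
    if cd3 and cd8:
        return "CD3+CD8+"
    if cd3:
        return "CD3+CD8-"
    if cd8:
        return "CD3-CD8+"
    return "negative"


def classify_macrophage(cell: CellRecord, t: ThresholdSet | None = None,
                        rule: str = "any") -> str:
    """Call a macrophage-slide cell: CD68+CD163-, CD163+, CD68+CD163+ or negative.

    For reporting, CD68+ totals include CD68+CD163+ cells and CD163+ totals
    include the colocalized class as well (see :func:`reporting_classes`).
    """
    t = t or ThresholdSet.macrophage()
    cd68, cd163 = _calls(cell, t, rule)
    if cd68 and cd163:
        return "CD68+CD163+"
    if cd68:
        return "CD68+CD163-"
    if cd163:
        return "CD163+"
    return "negative"


def reporting_classes(call: str) -> frozenset[str]:
    """Map a macrophage call to the density-reporting classes it counts toward."""
    return {
        "CD68+CD163+": frozenset({"CD68+", "CD163+"}),
        "CD68+CD163-": frozenset({"CD68+", "CD68+CD163-"}),
        "CD163+": frozenset({"CD163+"}),
        "negative": frozenset(),
    }[call]


def dichotomize_pck(mean_slide_pck_intensity: float, threshold: float = 2.16e-2) -> str:
    """Dichotomize whole-slide pancytokeratin intensity into low/high."""
    if mean_slide_pck_intensity < 0:
        raise ValidationError("PCK intensity must be >= 0")
    return "high" if mean_slide_pck_intensity > threshold else "low"


def tumor_mask_from_pck(tumor_polygon: Polygon | None = None,
                        pck_centroids=None, buffer_um: float = 20.0) -> Polygon:
    """Tumor mask: pass a supplied polygon through, or buffer PCK+ centroids.

    The centroid mode returns the union of discs of radius ``buffer_um``
    around PCK-positive cell centroids — a coordinate-level surrogate for
    pixel-based tumor/stroma segmentation.  Zero centroids give an empty mask.
    """
    if tumor_polygon is not None:
        return tumor_polygon
    if pck_centroids is None:
        raise ValidationError("need a tumor polygon or PCK+ centroids")
    discs = [Point(x, y).buffer(buffer_um, quad_segs=64) for x, y in pck_centroids]
    if not discs:
        return Polygon()
    return unary_union(discs)


def phenotype_cells(cells, slide_role: str, cfg: PipelineConfig | None = None):
    """Classify a whole slide; returns new CellRecords with phenotype flags set.

    ``slide_role`` is ``"lymphocyte"`` or ``"macrophage"``.  A cell keeps its
    intensities; its flags encode the marker calls (e.g. {CD3, CD8} for a
    colocalized lymphocyte).  Cells already carrying flags are left untouched.
    """
    cfg = cfg or PipelineConfig()
    rule = cfg.positivity_rule
    out = []
    if slide_role == "lymphocyte":
        t = ThresholdSet.lymphocyte(cfg)
        mapping = {"CD3+CD8-": {"CD3"}, "CD3-CD8+": {"CD8"},
                   "CD3+CD8+": {"CD3", "CD8"}, "negative": set()}
        classify = classify_lymphocyte
    elif slide_role == "macrophage":
        t = ThresholdSet.macrophage(cfg)
        mapping = {"CD68+CD163-": {"CD68"}, "CD163+": {"CD163"},
                   "CD68+CD163+": {"CD68", "CD163"}, "negative": set()}
        classify = classify_macrophage
    else:
        raise ValueError(f"unknown slide role {slide_role!r}")
    for c in cells:
        if c.phenotypes:
            out.append(c)
            continue
        call = classify(c, t, rule)
        flags = frozenset(mapping[call] | ({"TUMOR"} if _is_tumor(c, cfg) else set()))
        out.append(CellRecord(c.cell_id, c.x_um, c.y_um, dict(c.intensities), flags))
    return out


def _is_tumor(cell: CellRecord, cfg: PipelineConfig) -> bool:
    """PCK (epithelial) positivity on the CY3 channel, any compartment."""
    return any(
        cell.intensities.get(f"{comp}_CY3_PCK", 0.0) > cfg.pck_slide_threshold
        for comp in ("nucleus", "cytoplasm", "membrane")
    )
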