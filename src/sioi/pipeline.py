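"""End-to-end orchestration: cells + geometry + survival → SIOI report.

``profile_case`` turns one patient's raw inputs into a :class:`ProfiledCase`
(phenotyped cells in one frame, regions, buds); ``run_pipeline`` maps a
cohort directory through profiling, the feature table, the selection chain
and survival evaluation, and emits a machine-readable report that also logs
every threshold in force.

Cohort directory layout (one patient per prefix):

    <pid>_slide1.csv      lymphocyte-slide cells
    <pid>_slide2.csv      macrophage-slide cells (own frame)
    <pid>_geometry.geojson  tumor polygon + invasive front
    <pid>_transform.json  optional slide2→slide1 transform (identity if absent)
    survival.csv          cohort outcomes
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Polygon

from . import io_core
from .buds import detect_buds
from .coregister import apply_transform
from .features import ProfiledCase, build_feature_table
from .io_core import PipelineConfig, SlidePair, Transform2D, cells_to_frame, coords
from .phenotyping import phenotype_cells
from .regions import build_regions
from .selection import select_sioi, sioi_assign
from .survival import censor_at, cox_univariate, km_curves


def profile_case(
    patient_id: str,
    tumor: Polygon,
    front: LineString,
    slide_pair: SlidePair,
    config: PipelineConfig | None = None,
    tissue_extent: Polygon | None = None,
) -> ProfiledCase:
    """Phenotype, build regions, coregister and detect buds for one patient."""
    cfg = config or PipelineConfig()
    s1 = phenotype_cells(slide_pair.slide1_cells, "lymphocyte", cfg)
    s2 = phenotype_cells(slide_pair.slide2_cells, "macrophage", cfg)
    regions = build_regions(tumor, front, cfg.im_half_width_um,
                            cfg.tbroi_width_um, tissue_extent)

    f1 = cells_to_frame(s1)
    lymph_xy = coords(s1)
    lymph_classes = {
        "CD3+": f1["CD3"].to_numpy(),
        "CD8+": f1["CD8"].to_numpy(),
        "CD3+CD8+": (f1["CD3"] & f1["CD8"]).to_numpy(),
    }
    tumor_mask = f1["TUMOR"].to_numpy()
    tumor_xy = lymph_xy[tumor_mask]
    tumor_ids = [c.cell_id for c, m in zip(s1, tumor_mask) if m]

    f2 = cells_to_frame(s2)
    macro_xy_raw = coords(s2)
    macro_xy = (apply_transform(macro_xy_raw, slide_pair.transform)
                if len(macro_xy_raw) else macro_xy_raw)
    macro_classes = {
        "CD68+": f2["CD68"].to_numpy(),
        "CD163+": f2["CD163"].to_numpy(),
        "CD68+CD163-": (f2["CD68"] & ~f2["CD163"]).to_numpy(),
    }

    buds = detect_buds(tumor_xy, regions.TBROI, cfg.bud_link_distance_um,
                       cell_ids=tumor_ids)
    return ProfiledCase(patient_id, regions, lymph_xy, lymph_classes,
                        macro_xy, macro_classes, buds)


def _load_case(cohort_dir: Path, pid: str) -> tuple[Polygon, LineString, SlidePair]:
    tumor, front = io_core.read_geometry(cohort_dir / f"{pid}_geometry.geojson")
    s1 = io_core.read_cell_table(cohort_dir / f"{pid}_slide1.csv")
    s2 = io_core.read_cell_table(cohort_dir / f"{pid}_slide2.csv")
    tf_path = cohort_dir / f"{pid}_transform.json"
    transform = (Transform2D.from_dict(json.loads(tf_path.read_text()))
                 if tf_path.exists() else Transform2D.identity())
    return tumor, front, SlidePair(s1, s2, transform)


def evaluate_sioi(assignments: pd.DataFrame, survival: pd.DataFrame,
                  horizon_months: float | None = None) -> dict:
    """Cox and KM evaluation of 3-tier and 2-tier index assignments."""
    surv = survival
    if horizon_months is not None:
        surv = censor_at(surv, horizon_months)
    ok = assignments["tier3"].notna().to_numpy()
    surv_ok = surv.iloc[np.flatnonzero(ok)].reset_index(drop=True)
    a = assignments.iloc[np.flatnonzero(ok)]
    out: dict = {"n": int(ok.sum()), "n_events": int(surv_ok["event"].sum()),
                 "horizon_months": horizon_months}
    from .selection import TIER_HIGH, TIER_LOW, TIER_MID

    tier_risk = {TIER_LOW: 0.0, TIER_MID: 1.0, TIER_HIGH: 2.0}
    risk3 = a["tier3"].map(tier_risk).to_numpy(dtype=float)
    try:
        out["cox_tier3"] = cox_univariate(risk3, surv_ok, name="sioi").single("sioi")
    except ValueError as e:
        out["cox_tier3"] = {"error": str(e)}
    km3 = km_curves(a["tier3"], surv_ok)
    out["km_tier3_logrank_p"] = km3["logrank_p"]
    out["km_tier3_survival"] = {
        str(g): float(curve["survival"].iloc[-1]) for g, curve in km3["curves"].items()
    }
    risk2 = (a["tier2"] == "high-risk").astype(float).to_numpy()
    if len(np.unique(risk2)) == 2:
        try:
            out["cox_tier2"] = cox_univariate(risk2, surv_ok, name="high_risk").single("high_risk")
        except ValueError as e:
            out["cox_tier2"] = {"error": str(e)}
    return out


def run_pipeline(config: PipelineConfig, cohort_dir: str | Path,
                 out_dir: str | Path | None = None, seed: int | None = None) -> dict:
    """Run every stage on a cohort directory and return the report dict.

    With ``out_dir`` set, also writes ``features.csv``, ``sioi.csv``,
    ``selection_trace.json`` and ``report.json``.  A fixed seed makes the
    whole run bit-reproducible.
    """
    cohort_dir = Path(cohort_dir)
    seed = config.random_seed if seed is None else seed
    survival_records = io_core.read_survival_table(cohort_dir / "survival.csv")
    survival = io_core.survival_frame(survival_records)
    profiled = []
    for pid in survival.index:
        tumor, front, pair = _load_case(cohort_dir, pid)
        profiled.append(profile_case(pid, tumor, front, pair, config))
    features = build_feature_table(profiled, config.proximity_radii_um)
    surv = survival.reset_index(drop=True)
    if config.censor_horizon_months is not None:
        surv = censor_at(surv, config.censor_horizon_months)
    rules, flags, trace = select_sioi(features, surv, config, seed=seed)
    assignments = sioi_assign(flags)
    evaluation = evaluate_sioi(assignments, surv)
    report = {
        "config": _config_dict(config),
        "n_patients": int(len(survival)),
        "feature_catalog": list(features.columns),
        "n_features": int(features.shape[1]),
        "rules": {f: r.to_dict() for f, r in rules.items()},
        "selection_trace": trace.steps,
        "sioi_counts": assignments["tier3"].value_counts(dropna=True).to_dict(),
        "evaluation": evaluation,
        "seed": seed,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        io_core.write_feature_table(features, out_dir / "features.csv")
        assignments.to_csv(out_dir / "sioi.csv", index_label="patient_id")
        (out_dir / "selection_trace.json").write_text(trace.to_json(indent=2))
        (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True,
                                                        default=_json_default))
    return report


def write_synthetic_cohort(synth_cfg, out_dir: str | Path) -> None:
    """Materialize a synthetic cohort in the cohort-directory layout."""
    from .synthetic import generate_cohort

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cases, features, survival, truths = generate_cohort(synth_cfg)
    for case in cases:
        io_core.write_cell_table(case.slide_pair.slide1_cells,
                                 out_dir / f"{case.patient_id}_slide1.csv")
        io_core.write_cell_table(case.slide_pair.slide2_cells,
                                 out_dir / f"{case.patient_id}_slide2.csv")
        io_core.write_geometry(case.tumor, case.front,
                               out_dir / f"{case.patient_id}_geometry.geojson")
        (out_dir / f"{case.patient_id}_transform.json").write_text(
            json.dumps(case.slide_pair.transform.to_dict()))
    records = [io_core.SurvivalRecord(pid, float(row["time_months"]), int(row["event"]))
               for pid, row in survival.iterrows()]
    io_core.write_survival_table(records, out_dir / "survival.csv")
    (out_dir / "planted_truth.json").write_text(
        json.dumps(truths, indent=2, default=_json_default))


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    d["proximity_radii_um"] = list(d["proximity_radii_um"])
    return d


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
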