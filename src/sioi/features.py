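"""Region-resolved densities, proximity statistics and the feature catalog.

Per patient, the catalog contains:

* densities (cells/mm²) of CD3+, CD8+, CD3+CD8+ lymphocytes and CD68+,
  CD163+, CD68+CD163− macrophages in each of IM, CT and IMCT;
* the tumor-bud count;
* the CD68+/CD163+ density ratio in IM, CT and IMCT;
* mean number of each macrophage class within 0–50 and 0–100 μm of tumor
  buds, CD3+ cells and CD8+ cells;
* mean number of CD3+, CD8+ and CD3+CD8+ lymphocytes within 0–50 μm of
  tumor buds.

Macrophage reporting classes are inclusive: CD68+ and CD163+ totals both
count colocalized CD68+CD163+ cells.  Distance comparisons are inclusive
(≤ radius).  Proximity features are means per target cell/bud; a patient
with no targets of a kind has that feature missing (NaN) — for zero tumor
buds the configurable zero-bud policy decides how the index treats it
downstream.  All cross-slide statistics assume macrophage coordinates have
been mapped into the lymphocyte-slide frame first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import rankdata

from .buds import TumorBud, bud_centroids
from .regions import RegionSet, points_in_region

LYMPHOCYTE_CLASSES = ("CD3+", "CD8+", "CD3+CD8+")
MACROPHAGE_CLASSES = ("CD68+", "CD163+", "CD68+CD163-")
DENSITY_REGIONS = ("IM", "CT", "IMCT")
PROXIMITY_TARGETS = ("TB", "CD3+", "CD8+")


class UndefinedDensityError(ValueError):
    pass


def feature_catalog(radii_um=(50.0, 100.0)) -> list[str]:
    """The fixed, ordered names of the image-based feature catalog."""
    names: list[str] = []
    for cls in LYMPHOCYTE_CLASSES + MACROPHAGE_CLASSES:
        for region in DENSITY_REGIONS:
            names.append(f"{cls} in {region}")
    names.append("TB Number")
    for region in DENSITY_REGIONS:
        names.append(f"CD68+/CD163+ in {region}")
    for cls in MACROPHAGE_CLASSES:
        for target in PROXIMITY_TARGETS:
            for r in radii_um:
                names.append(f"{cls} within 0-{r:g}-um of {target}")
    for cls in LYMPHOCYTE_CLASSES:
        names.append(f"{cls} within 0-{radii_um[0]:g}-um of TB")
    return names


def density(points_xy: np.ndarray, region, area_mm2: float) -> float:
    """Cells per mm²: count of points inside the region over its area."""
    if area_mm2 <= 0:
        raise UndefinedDensityError("region area is zero; density undefined")
    points_xy = np.asarray(points_xy, dtype=float).reshape(-1, 2)
    if len(points_xy) == 0:
        return 0.0
    return float(points_in_region(points_xy, region).sum() / area_mm2)


def proximity_count(sources_xy: np.ndarray, targets_xy: np.ndarray,
                    radius_um: float) -> tuple[np.ndarray, float]:
    """Number of sources within ``radius_um`` (inclusive) of each target.

    Returns per-target counts and their mean; with zero targets the mean is
    NaN (undefined), with zero sources the counts are all zero.
    """
    if radius_um <= 0:
        raise ValueError("radius must be > 0")
    targets_xy = np.asarray(targets_xy, dtype=float).reshape(-1, 2)
    sources_xy = np.asarray(sources_xy, dtype=float).reshape(-1, 2)
    if len(targets_xy) == 0:
        return np.zeros(0, dtype=int), float("nan")
    if len(sources_xy) == 0:
        counts = np.zeros(len(targets_xy), dtype=int)
        return counts, 0.0
    tree = cKDTree(sources_xy)
    counts = tree.query_ball_point(targets_xy, r=radius_um, return_length=True)
    counts = np.asarray(counts, dtype=int)
    return counts, float(counts.mean())


def mean_lymphocytes_near_buds(lymph_xy: np.ndarray, buds: list[TumorBud],
                               radius_um: float = 50.0) -> float:
    """Mean number of lymphocytes of one class within ``radius_um`` of a bud.

    Zero buds gives NaN; the zero-bud policy is applied when the feature is
    binarized into an index component, not here.
    """
    _, mean = proximity_count(lymph_xy, bud_centroids(buds), radius_um)
    return mean


def macrophage_ratio(cd68_density: float, cd163_density: float) -> float:
    """CD68+/CD163+ density ratio; +inf when only CD163 is absent, NaN if both."""
    if cd68_density < 0 or cd163_density < 0:
        raise ValueError("densities must be >= 0")
    if cd163_density == 0:
        return float("inf") if cd68_density > 0 else float("nan")
    return cd68_density / cd163_density


@dataclass
class ProfiledCase:
    """One patient after phenotyping, region building, coregistration, budding.

    ``lymph_xy``/``macro_xy`` are centroids in the lymphocyte-slide frame
    (macrophages already transformed); class masks select rows of them.
    """

    patient_id: str
    regions: RegionSet
    lymph_xy: np.ndarray
    lymph_classes: dict[str, np.ndarray]  # class name -> bool mask
    macro_xy: np.ndarray
    macro_classes: dict[str, np.ndarray]
    buds: list[TumorBud] = field(default_factory=list)

    def class_xy(self, name: str) -> np.ndarray:
        if name in self.lymph_classes:
            return self.lymph_xy[self.lymph_classes[name]]
        return self.macro_xy[self.macro_classes[name]]


def compute_case_features(case: ProfiledCase,
                          radii_um=(50.0, 100.0)) -> dict[str, float]:
    """All catalog features for one profiled case."""
    feats: dict[str, float] = {}
    areas = case.regions.areas_mm2
    dens: dict[tuple[str, str], float] = {}
    for cls in LYMPHOCYTE_CLASSES + MACROPHAGE_CLASSES:
        xy = case.class_xy(cls)
        for region in DENSITY_REGIONS:
            area = areas[region]
            if area <= 0:
                d = float("nan")
            else:
                d = density(xy, case.regions.region(region), area)
            dens[(cls, region)] = d
            feats[f"{cls} in {region}"] = d
    feats["TB Number"] = float(len(case.buds))
    for region in DENSITY_REGIONS:
        d68, d163 = dens[("CD68+", region)], dens[("CD163+", region)]
        if np.isfinite(d68) and np.isfinite(d163):
            feats[f"CD68+/CD163+ in {region}"] = macrophage_ratio(d68, d163)
        else:
            feats[f"CD68+/CD163+ in {region}"] = float("nan")

    target_xy = {
        "TB": bud_centroids(case.buds),
        "CD3+": case.class_xy("CD3+"),
        "CD8+": case.class_xy("CD8+"),
    }
    for cls in MACROPHAGE_CLASSES:
        src = case.class_xy(cls)
        for target in PROXIMITY_TARGETS:
            for r in radii_um:
                _, mean = proximity_count(src, target_xy[target], r)
                feats[f"{cls} within 0-{r:g}-um of {target}"] = mean
    for cls in LYMPHOCYTE_CLASSES:
        feats[f"{cls} within 0-{radii_um[0]:g}-um of TB"] = mean_lymphocytes_near_buds(
            case.class_xy(cls), case.buds, radii_um[0]
        )
    return feats


def build_feature_table(cases: list[ProfiledCase],
                        radii_um=(50.0, 100.0)) -> pd.DataFrame:
    """Patient × feature matrix in fixed catalog column order."""
    ids = [c.patient_id for c in cases]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate patient_id in cohort")
    catalog = feature_catalog(radii_um)
    rows = [compute_case_features(c, radii_um) for c in cases]
    table = pd.DataFrame(rows, index=pd.Index(ids, name="patient_id"))
    return table.reindex(columns=catalog)


def spearman_matrix(table: pd.DataFrame, columns=None) -> pd.DataFrame:
    """Spearman rank correlation matrix (average ranks for ties).

    Pairs involving a constant column are NaN and the constant columns are
    listed in ``result.attrs["constant_columns"]`` rather than failing
    silently.
    """
    cols = list(columns) if columns is not None else list(table.columns)
    X = table[cols].to_numpy(dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("need >= 3 patients for a correlation matrix")
    ranks = np.apply_along_axis(rankdata, 0, X)
    sd = ranks.std(axis=0)
    constant = [c for c, s in zip(cols, sd) if s == 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.atleast_2d(np.corrcoef(ranks, rowvar=False))
    np.fill_diagonal(r, 1.0)
    out = pd.DataFrame(r, index=cols, columns=cols)
    out.attrs["constant_columns"] = constant
    return out
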