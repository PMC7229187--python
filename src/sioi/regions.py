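"""Tumor-microenvironment regions around the invasive front.

From a tumor polygon and the invasive-front polyline (both in μm) four
regions are built:

* IM (invasive margin): a symmetric band 500 μm in and out of the front,
  optionally clipped to a tissue/scan extent;
* CT (tumor core): the tumor polygon minus the IM;
* IMCT: the union of IM and CT;
* TBROI: the 1000-μm border inward from the front — computed as
  tumor ∩ buffer(front, 1000 μm), which enforces "inward" without an
  oriented polyline.

Areas are reported in mm² (μm² / 1e6).  Point-region membership counts the
boundary as inside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LineString, Polygon
from shapely.geometry.base import BaseGeometry
from shapely import points as shapely_points, covers

REGION_NAMES = ("IM", "CT", "IMCT", "TBROI")


class GeometryError(ValueError):
    pass


@dataclass
class RegionSet:
    """The four analysis regions plus their areas in mm²."""

    IM: BaseGeometry
    CT: BaseGeometry
    IMCT: BaseGeometry
    TBROI: BaseGeometry
    areas_mm2: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.areas_mm2:
            self.areas_mm2 = {
                name: round(getattr(self, name).area / 1e6, 6) for name in REGION_NAMES
            }

    def region(self, name: str) -> BaseGeometry:
        return getattr(self, name)


def build_regions(
    tumor_polygon: Polygon,
    front_polyline: LineString,
    im_half_width_um: float = 500.0,
    tbroi_width_um: float = 1000.0,
    tissue_extent: Polygon | None = None,
) -> RegionSet:
    """Construct IM / CT / IMCT / TBROI from tumor polygon and front polyline.

    ``tissue_extent``, when given, clips the outward half of the IM band to
    the scanned tissue; the inward half is always limited by geometry itself.
    """
    if im_half_width_um <= 0 or tbroi_width_um <= 0:
        raise GeometryError("band widths must be > 0")
    if front_polyline.length <= 0:
        raise GeometryError("invasive front has zero length")

    im = front_polyline.buffer(im_half_width_um)
    if tissue_extent is not None:
        im = im.intersection(tissue_extent)
    ct = tumor_polygon.difference(im)
    imct = im.union(ct)
    tbroi = tumor_polygon.intersection(front_polyline.buffer(tbroi_width_um))

    if not tumor_polygon.is_empty and im.intersection(tumor_polygon).area == 0:
        raise GeometryError(
            "invasive front does not touch the tumor: IM ∩ tumor is empty"
        )
    return RegionSet(IM=im, CT=ct, IMCT=imct, TBROI=tbroi)


def points_in_region(xy: np.ndarray, region: BaseGeometry) -> np.ndarray:
    """Boolean mask of points inside (or on the boundary of) a region."""
    xy = np.asarray(xy, dtype=float)
    if xy.size == 0:
        return np.zeros(0, dtype=bool)
    pts = shapely_points(xy)
    # covers = contains or on the boundary
    return np.asarray(covers(region, pts), dtype=bool)


def assign_region(xy: np.ndarray, regions: RegionSet) -> list[frozenset[str]]:
    """Multi-label region membership per point; boundary counts as inside.

    A point carries IMCT iff it carries IM or CT (the union is consistent
    with the set labels by construction).
    """
    xy = np.asarray(xy, dtype=float).reshape(-1, 2)
    masks = {name: points_in_region(xy, regions.region(name)) for name in REGION_NAMES}
    labels = []
    for i in range(len(xy)):
        lab = {name for name in ("IM", "CT", "TBROI") if masks[name][i]}
        if "IM" in lab or "CT" in lab:
            lab.add("IMCT")
        labels.append(frozenset(lab))
    return labels
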