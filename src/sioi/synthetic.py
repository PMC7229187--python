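"""Synthetic cohorts: tissue geometry, marker-typed point patterns, buds,
compartment intensities, and survival with planted prognostic structure.

Each synthetic patient is a rectangular tissue with a straight or sinusoidal
invasive front; the tumor occupies the deep side of the front.  Immune cells
are drawn from homogeneous Poisson or Thomas (Poisson parents, Gaussian
offspring) point processes over the whole tissue; tumor cells fill the tumor
polygon; tumor buds are planted as 1–4-cell clusters inside the TBROI,
separated from the tumor mass so that detection is well-posed.  An optional
attraction term adds lymphocytes in 50-μm discs around bud centroids, which
plants the "lymphocytes near buds" signal.  The macrophage slide is the same
tissue observed through a known similarity transform, so coregistration can
be tested against ground truth.

Survival times are exponential with hazard h0·exp(βᵀz), where z is the
patient's true spatial feature vector standardized across the cohort — β is
therefore a log hazard ratio per standard deviation.  Censoring combines an
administrative horizon with independent uniform censoring.

Two levels of simulation are exposed: the full spatial generator
(:func:`generate_case` / :func:`generate_cohort`) and a feature-level
generator (:func:`simulate_feature_cohort`) that draws the feature table
directly — orders of magnitude faster, for studies that stress the
statistical chain rather than the geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Polygon, box

from .coregister import apply_transform, invert_transform
from .io_core import CellRecord, PipelineConfig, SlidePair, Transform2D
from .regions import RegionSet, build_regions, points_in_region

# exclusive generator classes; reporting classes are unions of these
LYMPH_CLASSES = ("CD3_only", "CD8_only", "CD3_CD8")
MACRO_CLASSES = ("CD68_only", "CD163_only", "CD68_CD163")
CLASS_PHENOTYPES = {
    "CD3_only": frozenset({"CD3"}),
    "CD8_only": frozenset({"CD8"}),
    "CD3_CD8": frozenset({"CD3", "CD8"}),
    "CD68_only": frozenset({"CD68"}),
    "CD163_only": frozenset({"CD163"}),
    "CD68_CD163": frozenset({"CD68", "CD163"}),
    "tumor": frozenset({"TUMOR"}),
}


@dataclass
class SynthConfig:
    """Study conditions for the synthetic cohort.

    Densities are cells/mm²; the defaults describe a 2 × 2 mm tissue with
    lymphocyte and macrophage abundances on the scale of a stage II
    colorectal cohort (CD3 density of a few hundred cells/mm², CD68/CD163
    ratio near 1) and a disease-specific death rate near 13% over an
    11.8-year follow-up.
    """

    extent_um: tuple[float, float] = (2000.0, 2000.0)
    front_shape: str = "straight"  # straight | sinusoidal
    front_depth_um: float = 600.0  # y of the front (tumor lies below, y down)
    front_amplitude_um: float = 150.0
    front_period_um: float = 1000.0
    # intensities (cells/mm²) of the exclusive classes + tumor mass
    densities: dict[str, float] = field(default_factory=lambda: {
        "CD3_only": 250.0, "CD8_only": 120.0, "CD3_CD8": 120.0,
        "CD68_only": 90.0, "CD163_only": 160.0, "CD68_CD163": 70.0,
        "tumor": 400.0,
    })
    # class -> (mean offspring per parent, offspring sigma um); None = uniform.
    # tumor cells default to dense Thomas "glands" so the tumor mass forms
    # connected components far larger than a bud.
    clustering: dict[str, tuple[float, float] | None] = field(
        default_factory=lambda: {"tumor": (30.0, 20.0)})
    density_cv: float = 0.5  # between-patient lognormal CV of each density
    # buds
    bud_rate: float = 12.0  # expected buds per patient (Poisson)
    bud_size_probs: tuple[float, ...] = (0.4, 0.3, 0.2, 0.1)  # sizes 1..4
    bud_spread_um: float = 5.0  # max distance of member cells from bud center
    bud_min_separation_um: float = 40.0  # to tumor mass and other buds
    bud_lymph_attraction: dict[str, float] = field(
        default_factory=lambda: {"CD3_CD8": 2.0})
    # coregistration ground truth (slide2 frame = slide1 seen through T⁻¹)
    transform_rotation_deg: float = 2.0
    transform_scale: float = 1.0
    transform_translation_um: tuple[float, float] = (30.0, -20.0)
    # intensity synthesis
    intensity_margin: float = 0.1
    intensity_noise_sd: float = 0.0
    # survival
    baseline_hazard: float = 0.0012  # events/month
    # planted prognostic structure (log-HR per s.d.): lymphocyte density and
    # bud-proximal lymphocytes protective, CD68/CD163 skew hazardous
    beta: dict[str, float] = field(default_factory=lambda: {
        "CD3+ in IMCT": -0.7,
        "CD3+CD8+ within 0-50-um of TB": -0.7,
        "CD68+/CD163+ in CT": 0.7,
    })
    horizon_months: float = 141.6  # administrative follow-up (11.8 years)
    censor_rate: float = 0.1  # probability of early uniform censoring
    n_patients: int = 113
    seed: int = 0

    def __post_init__(self) -> None:
        if self.extent_um[0] <= 0 or self.extent_um[1] <= 0:
            raise ValueError("tissue extent must be positive")
        if any(v < 0 for v in self.densities.values()):
            raise ValueError("densities must be >= 0")
        if len(self.bud_size_probs) != 4:
            raise ValueError("bud_size_probs must cover sizes 1..4")
        if self.horizon_months <= 0:
            raise ValueError("horizon must be > 0")
        if self.intensity_noise_sd < 0:
            raise ValueError("intensity_noise_sd must be >= 0")


# ---------------------------------------------------------------------------
# geometry + point processes
# ---------------------------------------------------------------------------


def make_geometry(cfg: SynthConfig) -> tuple[Polygon, LineString]:
    """Tissue front and tumor polygon under the configured front shape."""
    W, H = cfg.extent_um
    d = cfg.front_depth_um
    if cfg.front_shape == "straight":
        xs = np.array([0.0, W])
        ys = np.array([d, d])
    elif cfg.front_shape == "sinusoidal":
        xs = np.linspace(0.0, W, max(int(W / 25.0), 8))
        ys = d + cfg.front_amplitude_um * np.sin(2 * np.pi * xs / cfg.front_period_um)
    else:
        raise ValueError(f"unknown front shape {cfg.front_shape!r}")
    front = LineString(np.c_[xs, ys])
    # tumor = region below the front (y down = deeper), closed along the edges
    ring = list(np.c_[xs, ys]) + [(W, H), (0.0, H)]
    tumor = Polygon(ring)
    if not tumor.is_valid:
        tumor = tumor.buffer(0)
    return tumor, front


def sample_poisson_points(rng: np.random.Generator, rate_per_mm2: float,
                          region: Polygon) -> np.ndarray:
    """Homogeneous Poisson process restricted to a polygon."""
    area_mm2 = region.area / 1e6
    n = rng.poisson(rate_per_mm2 * area_mm2)
    return _uniform_in_polygon(rng, n, region)


def _uniform_in_polygon(rng: np.random.Generator, n: int,
                        region: Polygon) -> np.ndarray:
    if n == 0 or region.is_empty:
        return np.empty((0, 2))
    minx, miny, maxx, maxy = region.bounds
    out = []
    need = n
    while need > 0:
        m = max(int(need * max((maxx - minx) * (maxy - miny) / max(region.area, 1e-12), 1.0) * 1.2), 16)
        cand = np.c_[rng.uniform(minx, maxx, m), rng.uniform(miny, maxy, m)]
        keep = cand[points_in_region(cand, region)]
        out.append(keep[:need])
        need -= len(keep[:need])
    return np.vstack(out)


def sample_thomas_points(rng: np.random.Generator, rate_per_mm2: float,
                         region: Polygon, mean_offspring: float,
                         sigma_um: float) -> np.ndarray:
    """Thomas cluster process with target overall intensity ``rate_per_mm2``."""
    if mean_offspring <= 0:
        raise ValueError("mean_offspring must be > 0")
    parent_rate = rate_per_mm2 / mean_offspring
    # dilate the window so edge clusters contribute
    dilated = region.buffer(3 * sigma_um)
    area_mm2 = dilated.area / 1e6
    n_parents = rng.poisson(parent_rate * area_mm2)
    parents = _uniform_in_polygon(rng, n_parents, dilated)
    pts = []
    for p in parents:
        k = rng.poisson(mean_offspring)
        if k:
            pts.append(p + rng.normal(0.0, sigma_um, size=(k, 2)))
    if not pts:
        return np.empty((0, 2))
    xy = np.vstack(pts)
    return xy[points_in_region(xy, region)]


def _sample_class(rng: np.random.Generator, cfg: SynthConfig, cls: str,
                  rate: float, region: Polygon) -> np.ndarray:
    clust = cfg.clustering.get(cls)
    if clust is None:
        return sample_poisson_points(rng, rate, region)
    mean_off, sigma = clust
    return sample_thomas_points(rng, rate, region, mean_off, sigma)


# ---------------------------------------------------------------------------
# case generation
# ---------------------------------------------------------------------------


@dataclass
class SynthCase:
    patient_id: str
    tumor: Polygon
    front: LineString
    slide_pair: SlidePair
    truth: dict


def generate_case(cfg: SynthConfig, seed: int,
                  patient_id: str = "P0") -> SynthCase:
    """One synthetic patient: geometry, typed cells on two slides, buds.

    ``truth`` records the planted buds (centroid, size), the per-class
    per-region counts, the realized per-class densities and the ground-truth
    slide-2 → slide-1 transform.
    """
    rng = np.random.default_rng(seed)
    tumor, front = make_geometry(cfg)
    W, H = cfg.extent_um
    tissue = box(0.0, 0.0, W, H)
    regions = build_regions(tumor, front, tissue_extent=tissue)

    # per-patient density heterogeneity (lognormal, unit mean)
    cv = cfg.density_cv
    sig = math.sqrt(math.log(1 + cv**2)) if cv > 0 else 0.0
    rates = {}
    for cls, lam in cfg.densities.items():
        mult = math.exp(rng.normal(-sig**2 / 2, sig)) if sig > 0 else 1.0
        rates[cls] = lam * mult

    class_xy: dict[str, np.ndarray] = {}
    for cls in LYMPH_CLASSES + MACRO_CLASSES:
        class_xy[cls] = _sample_class(rng, cfg, cls, rates.get(cls, 0.0), tissue)
    mass_xy = _sample_class(rng, cfg, "tumor", rates.get("tumor", 0.0), tumor)

    # plant buds inside the TBROI, separated from the mass and each other
    buds_truth = []
    bud_cells = []
    n_buds = rng.poisson(cfg.bud_rate)
    sizes = rng.choice(np.arange(1, 5), size=n_buds, p=np.asarray(cfg.bud_size_probs) /
                       np.sum(cfg.bud_size_probs))
    tbroi = regions.TBROI
    from scipy.spatial import cKDTree
    mass_tree = cKDTree(mass_xy) if len(mass_xy) else None
    placed_centers: list[np.ndarray] = []
    sep = cfg.bud_min_separation_um
    for size in sizes:
        for _try in range(200):
            cand = _uniform_in_polygon(rng, 1, tbroi)
            if len(cand) == 0:
                break
            c = cand[0]
            if mass_tree is not None and mass_tree.query(c)[0] < sep + cfg.bud_spread_um:
                continue
            if placed_centers and np.min(
                    np.linalg.norm(np.asarray(placed_centers) - c, axis=1)) < 2 * sep:
                continue
            # members within bud_spread of the center (center is a cell)
            members = [c]
            for _ in range(int(size) - 1):
                ang = rng.uniform(0, 2 * np.pi)
                r = rng.uniform(2.0, cfg.bud_spread_um)
                members.append(c + r * np.array([np.cos(ang), np.sin(ang)]))
            members = np.asarray(members)
            bud_cells.append(members)
            placed_centers.append(c)
            buds_truth.append({"centroid": members.mean(axis=0).tolist(),
                               "n_cells": int(size)})
            break
    tumor_xy = np.vstack([mass_xy] + bud_cells) if bud_cells else mass_xy

    # lymphocyte attraction around buds: extra cells in 50-μm discs
    for cls, per_bud in cfg.bud_lymph_attraction.items():
        if per_bud <= 0 or not placed_centers:
            continue
        extra = []
        for c in placed_centers:
            k = rng.poisson(per_bud)
            if k:
                r = 50.0 * np.sqrt(rng.uniform(size=k))
                ang = rng.uniform(0, 2 * np.pi, size=k)
                extra.append(c + np.c_[r * np.cos(ang), r * np.sin(ang)])
        if extra:
            class_xy[cls] = np.vstack([class_xy[cls]] + extra)

    # ground-truth transform: slide2 coordinates = T⁻¹(slide1 coordinates)
    th = math.radians(cfg.transform_rotation_deg)
    s = cfg.transform_scale
    R = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
    transform = Transform2D(s * R, np.asarray(cfg.transform_translation_um),
                            kind="similarity")
    inv = invert_transform(transform)

    slide1: list[CellRecord] = []
    for cls in LYMPH_CLASSES:
        for i, (x, y) in enumerate(class_xy[cls]):
            slide1.append(CellRecord(f"{patient_id}_{cls}_{i}", float(x), float(y),
                                     phenotypes=CLASS_PHENOTYPES[cls]))
    for i, (x, y) in enumerate(tumor_xy):
        slide1.append(CellRecord(f"{patient_id}_tumor_{i}", float(x), float(y),
                                 phenotypes=CLASS_PHENOTYPES["tumor"]))
    slide2: list[CellRecord] = []
    for cls in MACRO_CLASSES:
        mapped = apply_transform(class_xy[cls], inv) if len(class_xy[cls]) else class_xy[cls]
        for i, (x, y) in enumerate(mapped):
            slide2.append(CellRecord(f"{patient_id}_{cls}_{i}", float(x), float(y),
                                     phenotypes=CLASS_PHENOTYPES[cls]))
    # PCK+ cells appear on both serial sections: mirror tumor cells on slide 2
    mapped_tumor = apply_transform(tumor_xy, inv) if len(tumor_xy) else tumor_xy
    for i, (x, y) in enumerate(mapped_tumor):
        slide2.append(CellRecord(f"{patient_id}_tumor2_{i}", float(x), float(y),
                                 phenotypes=CLASS_PHENOTYPES["tumor"]))

    truth = {
        "buds": buds_truth,
        "transform": transform.to_dict(),
        "densities_per_mm2": rates,
        "region_areas_mm2": dict(regions.areas_mm2),
        "region_counts": _region_counts(class_xy, tumor_xy, regions),
    }
    return SynthCase(patient_id, tumor, front,
                     SlidePair(slide1, slide2, transform), truth)


def _region_counts(class_xy: dict[str, np.ndarray], tumor_xy: np.ndarray,
                   regions: RegionSet) -> dict:
    counts: dict = {}
    all_xy = dict(class_xy)
    all_xy["tumor"] = tumor_xy
    for cls, xy in all_xy.items():
        counts[cls] = {
            name: int(points_in_region(xy, regions.region(name)).sum())
            for name in ("IM", "CT", "IMCT", "TBROI")
        }
    return counts


# ---------------------------------------------------------------------------
# intensities (inverse of classification)
# ---------------------------------------------------------------------------

_CHANNEL_OF = {"CD3": "FITC", "CD8": "Cy5", "CD68": "FITC", "CD163": "Cy5"}


def generate_intensities(cells: list[CellRecord], slide_role: str,
                         noise_sd: float = 0.0, margin: float = 0.1,
                         seed: int = 0,
                         config: PipelineConfig | None = None) -> list[CellRecord]:
    """Draw compartment intensities consistent with each cell's phenotypes.

    Markers the cell carries get their nuclear channel ``margin`` above the
    classification threshold; absent markers fall ``margin`` below (clipped
    at zero); cytoplasm/membrane stay below threshold.  Gaussian noise of sd
    ``noise_sd`` is added before truncation at zero, so recovery of the
    phenotypes by the classifier degrades gracefully with noise.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    cfg = config or PipelineConfig()
    rng = np.random.default_rng(seed)
    if slide_role == "lymphocyte":
        thr = {"FITC": cfg.lymph_nucleus_fitc, "Cy5": cfg.lymph_nucleus_cy5}
        markers = ("CD3", "CD8")
    elif slide_role == "macrophage":
        thr = {"FITC": cfg.macro_nucleus_fitc, "Cy5": cfg.macro_nucleus_cy5}
        markers = ("CD68", "CD163")
    else:
        raise ValueError(f"unknown slide role {slide_role!r}")
    out = []
    for c in cells:
        intens: dict[str, float] = {}
        for ch in ("FITC", "Cy5"):
            marker = [m for m in markers if _CHANNEL_OF[m] == ch][0]
            base = thr[ch] + margin if marker in c.phenotypes else thr[ch] - margin
            intens[f"nucleus_{ch}"] = max(base + rng.normal(0.0, noise_sd) if noise_sd else base, 0.0)
            intens[f"cytoplasm_{ch}"] = 0.0
            intens[f"membrane_{ch}"] = 0.0
        pck_thr = cfg.pck_slide_threshold
        pck = pck_thr + margin if "TUMOR" in c.phenotypes else max(pck_thr - margin, 0.0)
        intens["cytoplasm_CY3_PCK"] = max(pck + (rng.normal(0.0, noise_sd) if noise_sd else 0.0), 0.0)
        out.append(CellRecord(c.cell_id, c.x_um, c.y_um, intens, frozenset()))
    return out


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------


def draw_survival(z: pd.DataFrame, beta: dict[str, float], h0: float,
                  horizon_months: float, censor_rate: float,
                  rng: np.random.Generator) -> pd.DataFrame:
    """Exponential proportional-hazards survival from standardized features.

    ``z`` is standardized inside this function (cohort mean/sd), so β is a
    log hazard ratio per standard deviation.  Unknown feature names in β
    raise with the known names listed.
    """
    unknown = [k for k in beta if k not in z.columns]
    if unknown:
        raise ValueError(f"unknown features in beta: {unknown}; "
                         f"known: {list(z.columns)}")
    n = len(z)
    eta = np.zeros(n)
    for name, b in beta.items():
        col = z[name].to_numpy(dtype=float)
        finite = np.isfinite(col)
        if not finite.all():  # +inf ratios / unmeasured: clamp to finite range
            fill = col[finite].max() if finite.any() else 0.0
            col = np.where(finite, col, fill)
        sd = col.std()
        zz = (col - col.mean()) / (sd if sd > 0 else 1.0)
        eta += b * zz
    T = rng.exponential(1.0, size=n) / (h0 * np.exp(eta))
    C = np.full(n, horizon_months)
    early = rng.uniform(size=n) < censor_rate
    C[early] = rng.uniform(0.0, horizon_months, size=early.sum())
    time = np.minimum(T, C)
    event = (T <= C).astype(int)
    time = np.maximum(time, 1e-9)
    return pd.DataFrame({"time_months": time, "event": event})


def generate_cohort(cfg: SynthConfig):
    """Full spatial cohort: cases, survival table and per-patient truth.

    The per-patient true feature vector is computed from the planted
    geometry with the pipeline's own feature definitions (the geometry is
    exact, so these are the ground-truth features), then survival is drawn
    from the proportional-hazards model in :func:`draw_survival`.

    Returns ``(cases, features, survival, truths)``.
    """
    from .pipeline import profile_case  # deferred: pipeline imports us

    root = np.random.SeedSequence(cfg.seed)
    case_seeds = root.spawn(cfg.n_patients)
    cases: list[SynthCase] = []
    truths = []
    profiled = []
    for i, ss in enumerate(case_seeds):
        case = generate_case(cfg, seed=int(ss.generate_state(1)[0] % (2**31)),
                             patient_id=f"P{i:04d}")
        cases.append(case)
        truths.append(case.truth)
        profiled.append(profile_case(case.patient_id, case.tumor, case.front,
                                     case.slide_pair,
                                     tissue_extent=box(0.0, 0.0, *cfg.extent_um)))
    from .features import build_feature_table

    features = build_feature_table(profiled)
    rng = np.random.default_rng(root.generate_state(4)[3] % (2**31))
    survival = draw_survival(features, cfg.beta, cfg.baseline_hazard,
                             cfg.horizon_months, cfg.censor_rate, rng)
    survival.index = features.index
    return cases, features, survival, truths


# ---------------------------------------------------------------------------
# feature-level cohort (fast path for statistical studies)
# ---------------------------------------------------------------------------

#: planted marginal scales for the three index components: median and
#: lognormal sigma on the raw scale (densities in cells/mm², counts, ratio)
COMPONENT_SCALES = {
    "CD3+ in IMCT": (390.0, 0.55),
    "CD3+CD8+ within 0-50-um of TB": (4.0, 0.65),
    "CD68+/CD163+ in CT": (1.1, 0.45),
}


def simulate_feature_cohort(
    n_patients: int,
    beta: dict[str, float],
    n_noise: int = 0,
    h0: float = 0.004,
    horizon_months: float = 141.6,
    censor_rate: float = 0.15,
    seed: int = 0,
    noise_sigma: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a patient × feature table directly, plus matching survival.

    Named features in ``beta`` get the realistic marginal scales from
    :data:`COMPONENT_SCALES` (lognormal) when listed there, otherwise a unit
    lognormal; ``n_noise`` additional independent lognormal features named
    ``noise_00`` … carry no survival signal.  Survival follows the same
    exponential proportional-hazards model as the spatial generator.
    """
    rng = np.random.default_rng(seed)
    cols: dict[str, np.ndarray] = {}
    for name in beta:
        med, sig = COMPONENT_SCALES.get(name, (1.0, noise_sigma))
        cols[name] = med * np.exp(rng.normal(0.0, sig, size=n_patients))
    for j in range(n_noise):
        cols[f"noise_{j:02d}"] = np.exp(rng.normal(0.0, noise_sigma, size=n_patients))
    features = pd.DataFrame(cols,
                            index=pd.Index([f"P{i:04d}" for i in range(n_patients)],
                                           name="patient_id"))
    survival = draw_survival(features, beta, h0, horizon_months, censor_rate, rng)
    survival.index = features.index
    return features, survival
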