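import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from sioi.phenotyping import classify_lymphocyte, phenotype_cells
from sioi.synthetic import (
    SynthConfig,
    draw_survival,
    generate_case,
    generate_cohort,
    generate_intensities,
    sample_poisson_points,
    simulate_feature_cohort,
)


def _quiet_config(**kw):
    base = dict(bud_rate=0.0, density_cv=0.0, clustering={},
                bud_lymph_attraction={})
    base.update(kw)
    return SynthConfig(**base)


def test_zero_rates_give_empty_case():
    cfg = _quiet_config(densities={k: 0.0 for k in SynthConfig().densities})
    case = generate_case(cfg, seed=0)
    assert case.slide_pair.slide1_cells == []
    assert case.slide_pair.slide2_cells == []
    assert case.truth["buds"] == []
    assert all(v == 0 for counts in case.truth["region_counts"].values()
               for v in counts.values())


def test_poisson_count_near_expectation():
    """Uniform 1000 cells/mm^2 on 2x2 mm: count within 4 s.d. of 4000."""
    region = box(0, 0, 2000, 2000)
    counts = [len(sample_poisson_points(np.random.default_rng(s), 1000.0, region))
              for s in range(5)]
    for c in counts:
        assert abs(c - 4000) <= 4 * np.sqrt(4000)


def test_counts_scale_linearly_with_density():
    region = box(0, 0, 2000, 2000)
    lams = [200.0, 400.0, 800.0, 1600.0]
    means = []
    for lam in lams:
        ns = [len(sample_poisson_points(np.random.default_rng(100 + s), lam, region))
              for s in range(8)]
        means.append(np.mean(ns))
    slope = np.polyfit(lams, means, 1)[0]
    assert slope == pytest.approx(4.0, rel=0.05)  # area = 4 mm^2


def test_planted_buds_read_back():
    cfg = _quiet_config(bud_rate=10.0, bud_size_probs=(0.0, 0.0, 1.0, 0.0),
                        densities={**{k: 0.0 for k in SynthConfig().densities}})
    case = generate_case(cfg, seed=5)
    buds = case.truth["buds"]
    assert all(b["n_cells"] == 3 for b in buds)
    assert len(buds) > 0
    # members pairwise within the configured dispersion (2 * bud_spread)
    xy = np.array([[c.x_um, c.y_um] for c in case.slide_pair.slide1_cells])
    assert len(xy) == 3 * len(buds)


def test_bud_recovery_through_detection():
    """With no tumor mass, detection recovers exactly the planted buds."""
    from sioi.pipeline import profile_case

    cfg = _quiet_config(bud_rate=8.0,
                        densities={**{k: 0.0 for k in SynthConfig().densities}})
    case = generate_case(cfg, seed=11)
    pc = profile_case("p", case.tumor, case.front, case.slide_pair,
                      tissue_extent=box(0, 0, *cfg.extent_um))
    assert len(pc.buds) == len(case.truth["buds"])
    assert sorted(b.n_cells for b in pc.buds) == sorted(
        b["n_cells"] for b in case.truth["buds"])


def test_same_seed_bit_identical_case():
    cfg = SynthConfig()
    a = generate_case(cfg, seed=42)
    b = generate_case(cfg, seed=42)
    assert a.slide_pair.slide1_cells == b.slide_pair.slide1_cells
    assert a.slide_pair.slide2_cells == b.slide_pair.slide2_cells
    assert a.truth == b.truth


def test_intensities_noiseless_inverse():
    cfg = _quiet_config()
    case = generate_case(cfg, seed=1)
    cells = case.slide_pair.slide1_cells
    with_int = generate_intensities(cells, "lymphocyte", noise_sd=0.0, seed=0)
    recovered = phenotype_cells(with_int, "lymphocyte")
    for orig, rec in zip(cells, recovered):
        assert orig.phenotypes == rec.phenotypes


def test_intensity_recovery_error_monotone_in_noise():
    cfg = _quiet_config()
    case = generate_case(cfg, seed=2)
    cells = case.slide_pair.slide1_cells
    errors = []
    for sd in (0.0, 0.05, 0.2, 0.8):
        with_int = generate_intensities(cells, "lymphocyte", noise_sd=sd,
                                        margin=0.1, seed=3)
        rec = phenotype_cells(with_int, "lymphocyte")
        errors.append(np.mean([o.phenotypes != r.phenotypes
                               for o, r in zip(cells, rec)]))
    assert errors[0] == 0.0
    assert all(b >= a - 0.02 for a, b in zip(errors, errors[1:]))
    assert errors[-1] > 0


def test_empty_phenotype_cell_below_thresholds():
    from sioi.io_core import CellRecord

    cell = CellRecord("c", 0, 0, phenotypes=frozenset({"CD3"}))
    neg = CellRecord("n", 0, 0, {"nucleus_FITC": 0.0})
    out = generate_intensities([neg], "lymphocyte", noise_sd=0.0)
    assert classify_lymphocyte(out[0]) == "negative"


def test_negative_noise_sd_rejected():
    with pytest.raises(ValueError):
        generate_intensities([], "lymphocyte", noise_sd=-1.0)


# ---------------------------------------------------------------- survival --

def test_null_beta_gives_exponential_hazard():
    """With beta = 0 the Nelson-Aalen slope matches h0 within 10% (n=2000)."""
    rng = np.random.default_rng(0)
    z = pd.DataFrame({"f": rng.normal(size=2000)})
    h0 = 0.01
    surv = draw_survival(z, {}, h0, horizon_months=1e9, censor_rate=0.0, rng=rng)
    from lifelines import NelsonAalenFitter

    naf = NelsonAalenFitter()
    naf.fit(surv["time_months"], surv["event"])
    t = np.quantile(surv["time_months"], 0.8)
    slope = naf.predict(t) / t
    assert slope == pytest.approx(h0, rel=0.10)


def test_single_strong_feature_hr_coverage():
    """Univariate Cox CI covers the planted HR in >=93% of replicates."""
    from sioi.survival import cox_univariate

    beta = 0.7
    covered = 0
    n_rep = 100
    for seed in range(n_rep):
        rng = np.random.default_rng(seed)
        z = pd.DataFrame({"f": rng.normal(size=400)})
        surv = draw_survival(z, {"f": beta}, 0.01, 120.0, 0.1, rng)
        zstd = (z["f"] - z["f"].mean()) / z["f"].std(ddof=0)
        fit = cox_univariate(zstd.to_numpy(), surv, name="f")
        if fit.ci_low["f"] <= np.exp(beta) <= fit.ci_high["f"]:
            covered += 1
    assert covered >= 0.93 * n_rep


def test_tiny_horizon_censors_everyone():
    rng = np.random.default_rng(1)
    z = pd.DataFrame({"f": rng.normal(size=50)})
    surv = draw_survival(z, {}, 0.01, horizon_months=0.001, censor_rate=0.0,
                         rng=rng)
    assert surv["event"].sum() == 0


def test_unknown_beta_feature_errors():
    z = pd.DataFrame({"known": [1.0, 2.0]})
    with pytest.raises(ValueError, match="known"):
        draw_survival(z, {"mystery": 1.0}, 0.01, 100.0, 0.0,
                      np.random.default_rng(0))


def test_lymph_bud_attraction_zero_matches_csr():
    """Attraction 0: mean lymphocytes within 50 um of buds ~ lam*pi*50^2/1e6."""
    from sioi.features import mean_lymphocytes_near_buds
    from sioi.pipeline import profile_case

    lam = 400.0
    means = []
    for seed in range(6):
        cfg = _quiet_config(
            bud_rate=10.0,
            densities={**{k: 0.0 for k in SynthConfig().densities},
                       "CD3_CD8": lam})
        case = generate_case(cfg, seed=seed)
        pc = profile_case("p", case.tumor, case.front, case.slide_pair,
                          tissue_extent=box(0, 0, *cfg.extent_um))
        if pc.buds:
            means.append(mean_lymphocytes_near_buds(pc.class_xy("CD3+CD8+"), pc.buds))
    expected = lam * np.pi * 50.0**2 / 1e6
    assert np.mean(means) == pytest.approx(expected, rel=0.25)


def test_cohort_determinism_and_shapes():
    cfg = SynthConfig(n_patients=4, seed=9)
    _, f1, s1, t1 = generate_cohort(cfg)
    _, f2, s2, t2 = generate_cohort(cfg)
    pd.testing.assert_frame_equal(f1, f2)
    pd.testing.assert_frame_equal(s1, s2)
    assert t1 == t2
    assert len(f1) == 4 and (s1["time_months"] > 0).all()


def test_feature_cohort_shapes_and_determinism():
    beta = {"CD3+ in IMCT": -0.7}
    f1, s1 = simulate_feature_cohort(50, beta, n_noise=5, seed=4)
    f2, s2 = simulate_feature_cohort(50, beta, n_noise=5, seed=4)
    pd.testing.assert_frame_equal(f1, f2)
    pd.testing.assert_frame_equal(s1, s2)
    assert f1.shape == (50, 6)
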