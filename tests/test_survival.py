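import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test

from sioi.survival import (
    CutpointRule,
    binarize,
    censor_at,
    cox_multivariate_forward,
    cox_univariate,
    km_curves,
    logrank_z,
    optimal_cutpoint,
)


# ---------------------------------------------------------------------- KM --

def test_km_hand_product_limit(toy_survival):
    """S = (4/5)(3/4)(1/2) = 0.3 after the third event-bearing time."""
    res = km_curves(pd.Series(["all"] * 5), toy_survival)
    curve = res["curves"]["all"]
    s_after_4 = curve.loc[curve["time"] >= 4.0, "survival"].iloc[0]
    assert s_after_4 == pytest.approx(0.3)


def test_km_no_events_flat():
    surv = pd.DataFrame({"time_months": [1.0, 2, 3], "event": [0, 0, 0]})
    res = km_curves(pd.Series(["g"] * 3), surv)
    assert (res["curves"]["g"]["survival"] == 1.0).all()


def test_km_identical_groups_logrank_near_one(rng):
    t = rng.exponential(50, size=200)
    e = (rng.uniform(size=200) < 0.7).astype(int)
    surv = pd.DataFrame({"time_months": np.tile(t, 2), "event": np.tile(e, 2)})
    groups = pd.Series(["a"] * 200 + ["b"] * 200)
    res = km_curves(groups, surv)
    assert res["logrank_p"] > 0.99


# ---------------------------------------------------------------- log-rank --

def test_logrank_z_matches_lifelines(rng):
    for _ in range(20):
        n = 60
        time = rng.exponential(30, size=n)
        event = (rng.uniform(size=n) < 0.7).astype(int)
        group = rng.uniform(size=n) < 0.5
        if event[group].sum() == 0 or event[~group].sum() == 0:
            continue
        z = logrank_z(time, event, group)
        ll = logrank_test(time[group], time[~group], event[group], event[~group])
        assert z**2 == pytest.approx(ll.test_statistic, rel=1e-8)


# ---------------------------------------------------------------- cutpoint --

def exhaustive_cutpoint_oracle(values, surv, min_group_prop=0.1):
    """Evaluate every admissible split's log-rank statistic with lifelines."""
    time = surv["time_months"].to_numpy()
    event = surv["event"].to_numpy()
    uniq = np.unique(values)
    n = len(values)
    best = None
    for lo, hi in zip(uniq[:-1], uniq[1:]):
        cut = (lo + hi) / 2
        above = values > cut
        if above.sum() < min_group_prop * n or (~above).sum() < min_group_prop * n:
            continue
        res = logrank_test(time[above], time[~above], event[above], event[~above])
        stat = np.sqrt(res.test_statistic)
        if best is None or stat > best[0] + 1e-12:
            best = (stat, cut)
    return best


def test_cutpoint_perfect_separation():
    rngl = np.random.default_rng(0)
    n = 40
    event = np.r_[np.ones(20), np.zeros(20)].astype(int)
    values = np.r_[rngl.uniform(10, 15, 20), rngl.uniform(0, 5, 20)]
    time = np.r_[rngl.uniform(5, 20, 20), np.full(20, 60.0)]
    surv = pd.DataFrame({"time_months": time, "event": event})
    rule = optimal_cutpoint(values, surv)
    assert 5.0 < rule.cutoff < 10.0
    assert rule.favorable_direction == "below"


@pytest.mark.parametrize("seed", range(10))
def test_cutpoint_matches_exhaustive_oracle(seed):
    rngl = np.random.default_rng(seed)
    n = 60
    values = rngl.normal(size=n)
    time = rngl.exponential(30 * np.exp(-0.5 * values))
    event = (rngl.uniform(size=n) < 0.8).astype(int)
    surv = pd.DataFrame({"time_months": time, "event": event})
    rule = optimal_cutpoint(values, surv)
    stat, cut = exhaustive_cutpoint_oracle(values, surv)
    assert rule.cutoff == pytest.approx(cut)
    assert abs(rule.statistic) == pytest.approx(stat, rel=1e-8)


def test_cutpoint_tie_goes_to_smallest():
    # symmetric data: splits at +/-0.5 have identical |z|; smallest wins
    values = np.array([0.0, 1.0, 2.0, 3.0])
    surv = pd.DataFrame({"time_months": [10, 10, 10, 10.0], "event": [1, 1, 1, 1]})
    rule = optimal_cutpoint(values, surv, min_group_prop=0.2)
    assert rule.cutoff == 0.5


def test_cutpoint_errors():
    surv = pd.DataFrame({"time_months": [1.0, 2, 3], "event": [1, 0, 1]})
    with pytest.raises(ValueError, match="constant"):
        optimal_cutpoint(np.ones(3), surv)
    with pytest.raises(ValueError, match="events"):
        optimal_cutpoint(np.array([1.0, 2, 3]),
                         pd.DataFrame({"time_months": [1.0, 2, 3], "event": [0, 0, 0]}))


def test_binarize_strict_inequalities():
    rule = CutpointRule("CD3+ in IMCT", 389.6, "above")
    flags = binarize(np.array([400.0, 389.6, 100.0, np.nan]), rule)
    assert flags[0] == True and flags[1] == False and flags[2] == False
    assert flags[3] is pd.NA
    ratio_rule = CutpointRule("ratio", 1.096, "below")
    rflags = binarize(np.array([1.096, 1.0, np.inf]), ratio_rule)
    assert rflags[0] == False and rflags[1] == True and rflags[2] == False


# --------------------------------------------------------------------- Cox --

def newton_efron_cox(x, time, event, n_iter=50):
    """Independent Newton iteration on the Efron partial likelihood (1 cov)."""
    x = np.asarray(x, float)
    beta = 0.0
    for _ in range(n_iter):
        U = 0.0
        I = 0.0
        r = np.exp(beta * x)
        for t in np.unique(time[event == 1]):
            risk = time >= t
            dead = (time == t) & (event == 1)
            d = dead.sum()
            s0, s1, s2 = (r[risk]).sum(), (r * x)[risk].sum(), (r * x**2)[risk].sum()
            d0, d1, d2 = (r[dead]).sum(), (r * x)[dead].sum(), (r * x**2)[dead].sum()
            for l in range(d):
                f = l / d
                z0 = s0 - f * d0
                z1 = s1 - f * d1
                z2 = s2 - f * d2
                U += (x[dead].sum() / d) - z1 / z0
                I += z2 / z0 - (z1 / z0) ** 2
        U = U  # score accumulated per event-time tie group
        beta += U / I
        if abs(U / I) < 1e-14:
            break
    return beta


def test_cox_matches_newton_oracle():
    time = np.array([2.0, 3.0, 4.0, 6.0, 8.0, 10.0])
    event = np.array([1, 1, 0, 1, 1, 0])
    x = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 0.0])
    surv = pd.DataFrame({"time_months": time, "event": event})
    fit = cox_univariate(x, surv, name="x")
    beta_oracle = newton_efron_cox(x, time, event)
    assert fit.coef["x"] == pytest.approx(beta_oracle, abs=1e-8)


def test_cox_identical_groups_hr_one():
    t = np.array([1.0, 2, 3, 4, 5, 6, 7, 8])
    e = np.array([1, 0, 1, 0, 1, 0, 1, 0])
    surv = pd.DataFrame({"time_months": np.tile(t, 2), "event": np.tile(e, 2)})
    x = np.r_[np.zeros(8), np.ones(8)]
    fit = cox_univariate(x, surv)
    assert fit.hr["x"] == pytest.approx(1.0, abs=1e-6)
    assert fit.p["x"] == pytest.approx(1.0, abs=0.01)


def test_cox_two_group_hr_recovery():
    rngl = np.random.default_rng(42)
    n = 1000
    x = (rngl.uniform(size=n) < 0.5).astype(float)
    time = rngl.exponential(1.0 / (0.01 * np.exp(np.log(2.0) * x)))
    event = np.ones(n, dtype=int)
    cens = rngl.uniform(0, 200, size=n)
    obs = np.minimum(time, cens)
    event = (time <= cens).astype(int)
    surv = pd.DataFrame({"time_months": obs, "event": event})
    fit = cox_univariate(x, surv)
    assert 1.7 <= fit.hr["x"] <= 2.35


def test_cox_separation_flagged():
    time = np.array([1.0, 2, 3, 10, 11, 12])
    event = np.array([1, 1, 1, 0, 0, 0])
    x = np.array([1.0, 1, 1, 0, 0, 0])
    surv = pd.DataFrame({"time_months": time, "event": event})
    fit = cox_univariate(x, surv)
    assert fit.flags  # monotone likelihood must be surfaced, not silent


# ----------------------------------------------------------------- forward --

def test_forward_selection_picks_real_predictor(rng):
    n = 300
    real = rng.normal(size=n)
    noise = rng.normal(size=(n, 3))
    time = rng.exponential(1.0 / (0.02 * np.exp(0.9 * real)))
    event = np.ones(n, dtype=int)
    surv = pd.DataFrame({"time_months": time, "event": event})
    X = pd.DataFrame(np.c_[real, noise], columns=["real", "n1", "n2", "n3"])
    fit, entered = cox_multivariate_forward(X, surv, entry_p=0.01)
    assert entered[0] == "real"


def test_forward_selection_entry_p_zero_empty(rng):
    n = 100
    X = pd.DataFrame({"a": rng.normal(size=n)})
    surv = pd.DataFrame({"time_months": rng.exponential(10, n),
                         "event": np.ones(n, dtype=int)})
    fit, entered = cox_multivariate_forward(X, surv, entry_p=0.0)
    assert fit is None and entered == []


def test_forward_selection_skips_collinear_duplicate(rng):
    n = 200
    real = rng.normal(size=n)
    time = rng.exponential(1.0 / (0.02 * np.exp(1.0 * real)))
    surv = pd.DataFrame({"time_months": time, "event": np.ones(n, dtype=int)})
    X = pd.DataFrame({"real": real, "dup": real.copy()})
    fit, entered = cox_multivariate_forward(X, surv, entry_p=0.05)
    assert len(entered) == 1


# ------------------------------------------------------------------ censor --

def test_censor_at():
    surv = pd.DataFrame({"time_months": [72.0, 30.0, 60.0], "event": [1, 1, 1]})
    out = censor_at(surv, 60.0)
    assert out["time_months"].tolist() == [60.0, 30.0, 60.0]
    assert out["event"].tolist() == [0, 1, 1]
    assert out["event"].sum() <= surv["event"].sum()
    unchanged = censor_at(surv, 100.0)
    pd.testing.assert_frame_equal(unchanged, surv)
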