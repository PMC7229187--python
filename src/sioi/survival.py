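"""Survival statistics: Cox regression, Kaplan–Meier, and optimal cutpoints.

Cox models maximize the partial likelihood with Efron tie handling (the
lifelines default).  Feature dichotomization uses the maximally selected
rank statistic: every admissible split of a continuous feature (midpoints of
sorted unique values, both groups at least a minimum fraction of the cohort)
is scored by the standardized two-group log-rank statistic, and the split
with the largest absolute statistic becomes the cutoff.  Ties in the
statistic resolve to the smallest cutoff.  The favorable side of a cutoff is
the group with fewer deaths than expected under the log-rank null — the side
with the higher Kaplan–Meier curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats


@dataclass
class CoxFit:
    """A fitted Cox proportional-hazards model (per-covariate summaries)."""

    coef: dict[str, float]
    hr: dict[str, float]
    ci_low: dict[str, float]
    ci_high: dict[str, float]
    p: dict[str, float]
    log_likelihood: float
    n_events: int
    flags: list[str] = field(default_factory=list)

    def single(self, name: str | None = None) -> dict[str, float]:
        name = name or next(iter(self.coef))
        return {
            "coef": self.coef[name], "hr": self.hr[name],
            "ci_low": self.ci_low[name], "ci_high": self.ci_high[name],
            "p": self.p[name],
        }


@dataclass
class CutpointRule:
    feature: str
    cutoff: float
    favorable_direction: str  # "above" | "below"
    statistic: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "feature": self.feature, "cutoff": float(self.cutoff),
            "favorable_direction": self.favorable_direction,
            "statistic": float(self.statistic),
        }


def censor_at(survival: pd.DataFrame, horizon_months: float) -> pd.DataFrame:
    """Administratively censor follow-up at a horizon (months)."""
    if horizon_months <= 0:
        raise ValueError("horizon must be > 0")
    out = survival.copy()
    late = out["time_months"] > horizon_months
    out.loc[late, "time_months"] = horizon_months
    out.loc[late, "event"] = 0
    return out


def logrank_z(time: np.ndarray, event: np.ndarray, group: np.ndarray) -> float:
    """Standardized two-group log-rank statistic (O − E)/√V for ``group``.

    Positive values mean the group has more deaths than expected.  Returns
    0.0 when the variance is degenerate (no events or one-sided risk sets).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group, dtype=bool)
    order = np.argsort(time, kind="stable")
    time, event, group = time[order], event[order], group[order]
    n = len(time)
    event_times = np.unique(time[event == 1])
    O = E = V = 0.0
    for t in event_times:
        at_risk = time >= t
        n_j = at_risk.sum()
        n1j = (at_risk & group).sum()
        here = (time == t) & (event == 1)
        d_j = here.sum()
        d1j = (here & group).sum()
        O += d1j
        E += d_j * n1j / n_j
        if n_j > 1:
            V += d_j * (n1j / n_j) * (1 - n1j / n_j) * (n_j - d_j) / (n_j - 1)
    if V <= 0:
        return 0.0
    return float((O - E) / np.sqrt(V))


def optimal_cutpoint(values: np.ndarray, survival: pd.DataFrame,
                     feature_name: str = "feature",
                     min_group_prop: float = 0.1) -> CutpointRule:
    """Maximally selected log-rank cutpoint for one continuous feature.

    Candidate cutoffs are midpoints of consecutive sorted unique values with
    both resulting groups at least ``min_group_prop`` of the cohort; the
    chosen cutoff maximizes |standardized log-rank statistic|, ties to the
    smallest cutoff.
    """
    values = np.asarray(values, dtype=float)
    time = survival["time_months"].to_numpy(dtype=float)
    event = survival["event"].to_numpy(dtype=int)
    if len(values) != len(time):
        raise ValueError("feature and survival lengths differ")
    uniq = np.unique(values[np.isfinite(values)])
    if len(uniq) < 2:
        raise ValueError(f"{feature_name}: constant feature, no cutpoint")
    if event.sum() < 1:
        raise ValueError("no events: cutpoint undefined")
    n = len(values)
    min_n = min_group_prop * n
    best: tuple[float, float] | None = None  # (|z|, cutoff)
    best_z = 0.0
    for lo, hi in zip(uniq[:-1], uniq[1:]):
        cut = (lo + hi) / 2.0
        above = values > cut
        if above.sum() < min_n or (~above).sum() < min_n:
            continue
        z = logrank_z(time, event, above)
        if best is None or abs(z) > best[0] + 1e-12:
            best = (abs(z), cut)
            best_z = z
    if best is None:
        raise ValueError(f"{feature_name}: no admissible cutoff under "
                         f"min_group_prop={min_group_prop}")
    # z > 0: the above-cutoff group dies more than expected -> below favorable
    direction = "below" if best_z > 0 else "above"
    return CutpointRule(feature_name, best[1], direction, statistic=best_z)


def binarize(values: pd.Series | np.ndarray, rule: CutpointRule) -> pd.Series:
    """Favorable flag per patient under a cutpoint rule (strict inequalities).

    Equality with the cutoff is unfavorable; missing values stay missing
    (the index stage decides how missingness is handled, e.g. the zero-bud
    policy).
    """
    s = pd.Series(values, dtype=float)
    if rule.favorable_direction == "above":
        flag = s > rule.cutoff
    elif rule.favorable_direction == "below":
        flag = s < rule.cutoff
    else:
        raise ValueError(f"bad direction {rule.favorable_direction!r}")
    flag = flag.astype("boolean")
    flag[s.isna()] = pd.NA
    return flag


def _frame(time, event, X: pd.DataFrame) -> pd.DataFrame:
    df = X.copy()
    df["_time"] = np.asarray(time, dtype=float)
    df["_event"] = np.asarray(event, dtype=int)
    return df


def cox_fit(X: pd.DataFrame, survival: pd.DataFrame) -> CoxFit:
    """Cox PH fit (Efron ties) of one or more covariates via lifelines."""
    time = survival["time_months"]
    event = survival["event"]
    if int(event.sum()) < 1:
        raise ValueError("no events: Cox model undefined")
    flags: list[str] = []
    df = _frame(time, event, X.reset_index(drop=True))
    cph = CoxPHFitter()
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        cph.fit(df, duration_col="_time", event_col="_event")
        for w in caught:
            msg = str(w.message)
            if "convergence" in msg.lower() or "complete separation" in msg.lower():
                flags.append("monotone-likelihood or separation: HR may be infinite")
                break
    summ = cph.summary
    return CoxFit(
        coef=summ["coef"].to_dict(),
        hr=summ["exp(coef)"].to_dict(),
        ci_low=summ["exp(coef) lower 95%"].to_dict(),
        ci_high=summ["exp(coef) upper 95%"].to_dict(),
        p=summ["p"].to_dict(),
        log_likelihood=float(cph.log_likelihood_),
        n_events=int(event.sum()),
        flags=flags,
    )


def cox_univariate(values, survival: pd.DataFrame,
                   name: str = "x") -> CoxFit:
    """Univariate Cox PH regression of one predictor."""
    x = np.asarray(values, dtype=float)
    if len(np.unique(x[np.isfinite(x)])) < 2:
        raise ValueError("predictor is constant")
    return cox_fit(pd.DataFrame({name: x}), survival)


def cox_multivariate_forward(X: pd.DataFrame, survival: pd.DataFrame,
                             entry_p: float = 0.05) -> tuple[CoxFit | None, list[str]]:
    """Forward-stepwise Cox regression with likelihood-ratio entry.

    At each step the candidate with the smallest LR p against the current
    model enters if p < ``entry_p``; the order of entry is returned.  With
    no entrants the model is empty (None).
    """
    entered: list[str] = []
    current_llf: float | None = None  # None = null model
    null_llf: float | None = None
    candidates = [c for c in X.columns]
    while True:
        best: tuple[float, str, CoxFit, float] | None = None
        for cand in candidates:
            if cand in entered:
                continue
            cols = entered + [cand]
            sub = X[cols]
            # skip candidates collinear with what has entered
            if len(cols) > 1 and np.linalg.matrix_rank(np.c_[sub.to_numpy(), np.ones(len(sub))]) <= len(entered) + 1:
                continue
            try:
                fit = cox_fit(sub, survival)
            except Exception:
                continue
            if null_llf is None:
                null_llf = _null_loglik(survival)
            base = current_llf if current_llf is not None else null_llf
            lr = 2 * (fit.log_likelihood - base)
            p = float(stats.chi2.sf(max(lr, 0.0), df=1))
            if best is None or p < best[0]:
                best = (p, cand, fit, fit.log_likelihood)
        if best is None or best[0] >= entry_p:
            break
        p, cand, fit, llf = best
        entered.append(cand)
        current_llf = llf
        final = fit
    if not entered:
        return None, []
    return final, entered


def _null_loglik(survival: pd.DataFrame) -> float:
    """Efron partial log-likelihood at β = 0 (all risks equal)."""
    time = survival["time_months"].to_numpy(dtype=float)
    event = survival["event"].to_numpy(dtype=int)
    ll = 0.0
    for t in np.unique(time[event == 1]):
        n_risk = int((time >= t).sum())
        d = int(((time == t) & (event == 1)).sum())
        # with all scores equal, Efron reduces to -Σ_l log(n_risk - l)
        for l in range(d):
            ll -= np.log(n_risk - l)
    return ll


def km_curves(groups: pd.Series, survival: pd.DataFrame) -> dict:
    """Kaplan–Meier curve per group plus the log-rank test across groups.

    Returns ``{"curves": {group: DataFrame(time, survival)},
    "logrank_p": float, "survival_at": callable}``; empty groups are dropped.
    """
    groups = pd.Series(np.asarray(groups, dtype=object))
    time = survival["time_months"].to_numpy(dtype=float)
    event = survival["event"].to_numpy(dtype=int)
    curves: dict = {}
    fitters: dict = {}
    for g in pd.unique(groups):
        mask = (groups == g).to_numpy()
        if mask.sum() == 0:
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event[mask])
        sf = kmf.survival_function_
        curves[g] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
        )
        fitters[g] = kmf
    if len(curves) >= 2:
        res = multivariate_logrank_test(time, groups.to_numpy(), event)
        logrank_p = float(res.p_value)
    else:
        logrank_p = float("nan")

    def survival_at(group, t: float) -> float:
        return float(fitters[group].predict(t))

    return {"curves": curves, "logrank_p": logrank_p, "survival_at": survival_at}
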