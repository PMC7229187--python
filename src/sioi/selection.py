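"""The prognostic feature-selection chain and the combinatorial index.

The chain mirrors a fixed recipe:

1. LASSO-penalized Cox regression over the standardized feature table, with
   the penalty chosen by k-fold cross-validated partial-likelihood deviance
   (Verweij–van Houwelingen), keeps the features with nonzero coefficients.
2. A classification random forest on the binary disease-specific-death label
   ranks the survivors by mean decrease Gini (sum over trees of the Gini
   impurity decrease at splits on the feature, divided by the number of
   trees — the classic forest importance).
3. Features with mean decrease Gini > 3 pass; among highly correlated pairs
   only the higher-Gini feature is kept (greedy by descending Gini against
   a Spearman |r| threshold).
4. Each survivor is dichotomized at its maximally selected log-rank cutpoint
   on the raw scale.
5. Iterative refinement: the component whose single-feature Cox p is largest
   is tentatively removed; if the combined index's criterion (Wald p of its
   univariate Cox fit by default) worsens, the removal is undone and the
   loop stops.

The final components form the index: patients with all components favorable
are "+/+/+" (low risk), exactly two "+/+/−", one or none "+/−/− or −/−/−".
Every step is recorded in a :class:`SelectionTrace` for audit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import KFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from .io_core import PipelineConfig
from .survival import CutpointRule, binarize, cox_univariate, optimal_cutpoint

TIER_LOW = "+/+/+"
TIER_MID = "+/+/-"
TIER_HIGH = "+/-/- or -/-/-"


@dataclass
class SelectionTrace:
    """Ordered, machine-readable record of every screening step."""

    steps: list[dict] = field(default_factory=list)

    def add(self, name: str, **payload) -> None:
        self.steps.append({"step": name, **payload})

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.steps, sort_keys=True, **kwargs)


def _clean_matrix(X: pd.DataFrame, trace: SelectionTrace | None = None) -> pd.DataFrame:
    """Make the matrix finite: cap +inf at the column's finite max, impute
    NaN with the column median, and drop constant columns (all logged)."""
    X = X.copy().astype(float)
    imputed, dropped = [], []
    for c in X.columns:
        col = X[c]
        if np.isinf(col).any():
            finite_max = col[np.isfinite(col)].max()
            X.loc[np.isinf(col), c] = finite_max if np.isfinite(finite_max) else 0.0
            imputed.append(c)
        if col.isna().any():
            med = X[c].median()
            X[c] = X[c].fillna(0.0 if np.isnan(med) else med)
            imputed.append(c)
    for c in list(X.columns):
        if X[c].nunique() <= 1:
            dropped.append(c)
            X = X.drop(columns=c)
    if trace is not None and (imputed or dropped):
        trace.add("clean_matrix", imputed=sorted(set(imputed)), dropped_constant=dropped)
    return X


def standardize(X: pd.DataFrame) -> pd.DataFrame:
    """Z-score columns (ddof=0); assumes a finite matrix."""
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0).replace(0.0, 1.0)
    return (X - mu) / sd


def _breslow_loglik(X: np.ndarray, time: np.ndarray, event: np.ndarray,
                    beta: np.ndarray) -> float:
    """Breslow partial log-likelihood at a fixed coefficient vector."""
    eta = X @ beta
    order = np.argsort(-time, kind="stable")  # decreasing time
    eta_o, time_o, event_o = eta[order], time[order], event[order]
    log_cum = np.logaddexp.accumulate(eta_o)  # log Σ_{T_i >= t} exp(η_i)
    ll = 0.0
    # risk set for an event at t = all with time >= t; map via searchsorted
    sorted_desc = time_o  # descending
    for i in np.flatnonzero(event_o == 1):
        t = time_o[i]
        # last index with time >= t in the descending array
        k = np.searchsorted(-sorted_desc, -t, side="right") - 1
        ll += eta_o[i] - log_cum[k]
    return float(ll)


def lasso_cox_select(
    features: pd.DataFrame,
    survival: pd.DataFrame,
    folds: int = 10,
    seed: int = 0,
    lambda_rule: str = "min",
    alphas=None,
    trace: SelectionTrace | None = None,
) -> tuple[list[str], dict[str, float], float]:
    """LASSO Cox screening with cross-validated penalty choice.

    ``features`` should be standardized.  Returns the nonzero feature set at
    the chosen penalty, their coefficients, and the penalty itself.
    ``lambda_rule`` is ``"min"`` (minimum CV deviance) or ``"1se"``.
    """
    time = survival["time_months"].to_numpy(dtype=float)
    event = survival["event"].to_numpy(dtype=int)
    if event.sum() == 0:
        raise ValueError("no events: LASSO Cox undefined")
    X = _clean_matrix(features, trace)
    y = Surv.from_arrays(event=event.astype(bool), time=time)
    Xv = X.to_numpy(dtype=float)

    path = CoxnetSurvivalAnalysis(l1_ratio=1.0, n_alphas=100,
                                  alpha_min_ratio=0.01, fit_baseline_model=False)
    if alphas is not None:
        path.set_params(alphas=list(alphas))
    path.fit(Xv, y)
    alphas_path = np.asarray(path.alphas_)

    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    dev = np.zeros((folds, len(alphas_path)))
    for k, (tr, _te) in enumerate(kf.split(Xv)):
        model = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=list(alphas_path),
                                       fit_baseline_model=False)
        model.fit(Xv[tr], y[tr])
        fitted = np.asarray(model.alphas_)
        for j, a in enumerate(alphas_path):
            jj = int(np.argmin(np.abs(fitted - a)))
            beta = model.coef_[:, jj]
            ll_full = _breslow_loglik(Xv, time, event, beta)
            ll_train = _breslow_loglik(Xv[tr], time[tr], event[tr], beta)
            dev[k, j] = -2.0 * (ll_full - ll_train)
    cv_mean = dev.mean(axis=0)
    cv_se = dev.std(axis=0, ddof=1) / np.sqrt(folds)
    j_min = int(np.argmin(cv_mean))
    if lambda_rule == "1se":
        ok = np.flatnonzero(cv_mean <= cv_mean[j_min] + cv_se[j_min])
        j_sel = int(ok[np.argmax(alphas_path[ok])])
    elif lambda_rule == "min":
        j_sel = j_min
    else:
        raise ValueError(f"unknown lambda rule {lambda_rule!r}")
    lam = float(alphas_path[j_sel])
    beta = path.coef_[:, j_sel]
    nonzero = np.flatnonzero(beta != 0.0)
    selected = [X.columns[i] for i in nonzero]
    coefs = {X.columns[i]: float(beta[i]) for i in nonzero}
    if trace is not None:
        trace.add("lasso_cox", lambda_=lam, lambda_rule=lambda_rule,
                  selected=selected, coefficients=coefs, folds=folds)
    return selected, coefs, lam


def rf_gini_rank(
    features: pd.DataFrame,
    event_labels: np.ndarray,
    n_trees: int = 500,
    seed: int = 0,
    trace: SelectionTrace | None = None,
) -> list[tuple[str, float]]:
    """Rank features by random-forest mean decrease Gini on the death label.

    The importance is the forest-classic definition: for each tree, sum the
    (bootstrap-weighted) Gini impurity decreases over the nodes splitting on
    the feature; average over trees.  Censoring is not modelled at this
    step — the response is the binary disease-specific-death label.
    """
    y = np.asarray(event_labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("single-class labels: random forest undefined")
    X = _clean_matrix(features)
    rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed,
                                oob_score=True, n_jobs=1)
    rf.fit(X.to_numpy(dtype=float), y)
    imp = np.zeros(X.shape[1])
    for est in rf.estimators_:
        t = est.tree_
        left, right = t.children_left, t.children_right
        w, g = t.weighted_n_node_samples, t.impurity
        for node in range(t.node_count):
            if left[node] == -1:
                continue
            decrease = (w[node] * g[node]
                        - w[left[node]] * g[left[node]]
                        - w[right[node]] * g[right[node]])
            imp[t.feature[node]] += decrease
    imp /= n_trees
    ranked = sorted(zip(X.columns, imp), key=lambda kv: -kv[1])
    if trace is not None:
        trace.add("rf_gini", n_trees=n_trees, oob_error=float(1 - rf.oob_score_),
                  ranking=[[f, float(v)] for f, v in ranked])
    return [(f, float(v)) for f, v in ranked]


def gini_filter(ranked: list[tuple[str, float]], threshold: float = 3.0,
                trace: SelectionTrace | None = None) -> list[tuple[str, float]]:
    """Keep features with mean decrease Gini strictly above the threshold."""
    kept = [(f, g) for f, g in ranked if g > threshold]
    if trace is not None:
        trace.add("gini_filter", threshold=threshold, kept=[f for f, _ in kept])
    return kept


def prune_correlated(ranked: list[tuple[str, float]], spearman: pd.DataFrame,
                     prune_threshold: float = 0.8,
                     trace: SelectionTrace | None = None) -> list[tuple[str, float]]:
    """Among highly correlated features keep only the highest-Gini one.

    Greedy in descending Gini order: a feature survives iff its |Spearman r|
    with every already-kept feature is below the threshold.
    """
    kept: list[tuple[str, float]] = []
    pruned: list[list] = []
    for f, g in sorted(ranked, key=lambda kv: -kv[1]):
        clash = [k for k, _ in kept
                 if abs(float(spearman.loc[f, k])) >= prune_threshold]
        if clash:
            pruned.append([f, clash])
        else:
            kept.append((f, g))
    if trace is not None:
        trace.add("prune_correlated", threshold=prune_threshold,
                  kept=[f for f, _ in kept], pruned=pruned)
    return kept


def iterative_refine(
    rules: dict[str, CutpointRule],
    flags: pd.DataFrame,
    survival: pd.DataFrame,
    criterion: str = "wald_p",
    trace: SelectionTrace | None = None,
) -> dict[str, CutpointRule]:
    """Drop the least significant component while the index improves.

    The combined index is the count of favorable component flags (ordinal).
    Each round, the component with the largest single-feature univariate Cox
    p is tentatively removed; if the index criterion worsens (Wald p rises,
    or LR χ² falls for ``criterion="lr_chi2"``), the removal is undone and
    refinement stops.  Deterministic: no randomness in the loop.
    """

    def crit(cols: list[str]) -> float:
        idx = flags[cols].sum(axis=1).astype(float)
        fit = cox_univariate(idx.to_numpy(), survival, name="index")
        if criterion == "wald_p":
            return fit.single("index")["p"]
        if criterion == "lr_chi2":
            return -2.0 * fit.log_likelihood  # lower is better either way
        raise ValueError(f"unknown criterion {criterion!r}")

    current = list(rules)
    removals: list[dict] = []
    cur_val = crit(current)
    while len(current) > 1:
        worst, worst_p = None, -np.inf
        for f in current:
            p = cox_univariate(flags[f].astype(float).to_numpy(), survival,
                               name=f).single(f)["p"]
            if p > worst_p:
                worst, worst_p = f, p
        tentative = [f for f in current if f != worst]
        try:
            new_val = crit(tentative)
        except ValueError:
            break
        if new_val > cur_val:
            removals.append({"feature": worst, "component_p": worst_p,
                             "criterion_after": new_val, "kept": True})
            break
        removals.append({"feature": worst, "component_p": worst_p,
                         "criterion_after": new_val, "kept": False})
        current, cur_val = tentative, new_val
    if trace is not None:
        trace.add("iterative_refine", criterion=criterion,
                  removal_sequence=removals, final=current)
    return {f: rules[f] for f in current}


def sioi_assign(flags: pd.DataFrame) -> pd.DataFrame:
    """Tier patients by their count of favorable component flags.

    Three favorable components → "+/+/+" (tier2 low-risk); exactly two →
    "+/+/−"; one or none → "+/−/− or −/−/−".  Patients with a missing flag
    are excluded (NaN tiers) and listed in ``result.attrs["excluded"]``.
    """
    n_comp = flags.shape[1]
    counts = flags.sum(axis=1, skipna=False)
    tier3 = pd.Series(index=flags.index, dtype=object)
    missing = counts.isna()
    tier3[~missing & (counts == n_comp)] = TIER_LOW
    tier3[~missing & (counts == n_comp - 1)] = TIER_MID
    tier3[~missing & (counts <= n_comp - 2)] = TIER_HIGH
    tier2 = pd.Series(index=flags.index, dtype=object)
    tier2[~missing] = np.where(tier3[~missing] == TIER_LOW, "low-risk", "high-risk")
    out = pd.DataFrame({"n_favorable": counts, "tier3": tier3, "tier2": tier2})
    out.attrs["excluded"] = list(flags.index[missing])
    return out


def apply_zero_bud_policy(flags: pd.DataFrame, features: pd.DataFrame,
                          policy: str = "favorable") -> pd.DataFrame:
    """Resolve bud-proximity component flags for patients without buds.

    A patient with zero tumor buds has no bud-proximity measurement.  Policy
    ``favorable`` (default) grants the favorable flag — absent budding is the
    prognostically good state; ``zero`` treats the measurement as 0 (the flag
    follows the rule applied to 0 — callers should instead fill the feature
    before cutpointing); ``missing`` leaves the flag missing, excluding the
    patient.
    """
    if policy not in ("favorable", "missing", "zero"):
        raise ValueError(f"unknown zero-bud policy {policy!r}")
    out = flags.copy()
    if "TB Number" not in features.columns or policy == "missing":
        return out
    zero_bud = features["TB Number"] == 0
    for col in out.columns:
        if "of TB" in col:
            if policy == "favorable":
                out.loc[zero_bud, col] = True
            elif policy == "zero":
                out.loc[zero_bud & out[col].isna(), col] = False
    return out


def select_sioi(
    features: pd.DataFrame,
    survival: pd.DataFrame,
    config: PipelineConfig | None = None,
    seed: int | None = None,
    spearman: pd.DataFrame | None = None,
) -> tuple[dict[str, CutpointRule], pd.DataFrame, SelectionTrace]:
    """Run the full selection chain; returns (rules, flags, trace).

    ``features`` is the raw-scale patient × feature table; standardization
    for the LASSO happens internally, cutpoints are computed on raw values.
    """
    from .features import spearman_matrix  # local import to avoid cycle

    cfg = config or PipelineConfig()
    seed = cfg.random_seed if seed is None else seed
    trace = SelectionTrace()
    clean = _clean_matrix(features, trace)
    Xstd = standardize(clean)
    selected, coefs, lam = lasso_cox_select(
        Xstd, survival, folds=cfg.lasso_folds, seed=seed,
        lambda_rule=cfg.lasso_lambda_rule, trace=trace)
    if not selected:
        raise ValueError("LASSO selected no features; nothing to rank")
    ranked = rf_gini_rank(clean[selected], survival["event"].to_numpy(),
                          n_trees=cfg.rf_trees, seed=seed, trace=trace)
    kept = gini_filter(ranked, cfg.gini_threshold, trace=trace)
    if not kept:
        raise ValueError(
            f"no feature exceeds the Gini threshold {cfg.gini_threshold}; "
            "lower the threshold or revisit the feature set")
    if len(kept) > 1:
        if spearman is None:
            spearman = spearman_matrix(clean, [f for f, _ in kept])
        kept = prune_correlated(kept, spearman, cfg.correlation_prune_threshold,
                                trace=trace)
    rules: dict[str, CutpointRule] = {}
    flags = pd.DataFrame(index=features.index)
    for f, _g in kept:
        vals = features[f].to_numpy(dtype=float)
        use = ~np.isnan(vals)  # inf ratios stay in; NaN (unmeasured) drop out
        surv_use = survival if use.all() else survival.iloc[np.flatnonzero(use)].reset_index(drop=True)
        rule = optimal_cutpoint(vals[use], surv_use, feature_name=f,
                                min_group_prop=cfg.cutpoint_min_group_prop)
        rules[f] = rule
        flags[f] = binarize(features[f].to_numpy(), rule).to_numpy()
    flags = flags.astype("boolean")
    flags = apply_zero_bud_policy(flags, features, cfg.zero_bud_policy)
    trace.add("cutpoints", rules={f: r.to_dict() for f, r in rules.items()},
              zero_bud_policy=cfg.zero_bud_policy)
    rules = iterative_refine(rules, flags, survival,
                             criterion=cfg.refine_criterion, trace=trace)
    flags = flags[list(rules)]
    return rules, flags, trace


def score_sioi(features: pd.DataFrame, rules: dict[str, CutpointRule],
               zero_bud_policy: str = "favorable") -> pd.DataFrame:
    """Apply learned cutpoint rules (e.g. from a training cohort) to a cohort."""
    flags = pd.DataFrame(index=features.index)
    for f, rule in rules.items():
        flags[f] = binarize(features[f].to_numpy(), rule).to_numpy()
    flags = flags.astype("boolean")
    flags = apply_zero_bud_policy(flags, features, zero_bud_policy)
    return sioi_assign(flags)
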