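"""Differential item functioning (DIF) by gender and age group.

Two detectors are provided, mirroring standard Rasch survey practice:

* :func:`hybrid_olr_dif` — iterative hybrid ordinal logistic regression
  (lordif-style): for each item, proportional-odds models of the response on
  the latent ability (M0), plus group (M1), plus an ability x group
  interaction (M2) are compared through McFadden's pseudo R-squared; an item
  is flagged when the R² gain of M2 over M0 exceeds the criterion (default
  0.02).  The matching ability is purified iteratively by re-estimating it
  on the currently DIF-free anchor items.
* :func:`anova_residual_dif` — two-way ANOVA of the standardized Rasch
  residuals on group and ability class interval: a group main effect
  signals uniform DIF, the group x interval interaction non-uniform DIF.

Detected DIF is reported, not adjusted for: for disability surveys an age
gradient is substantively expected and flags serve interpretation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm

DEFAULT_AGE_EDGES = (17.5, 39.5, 59.5, 100.0)


@dataclass
class DifConfig:
    """DIF settings: the McFadden ΔR² criterion (0.02), purification budget,
    class-interval count for the residual ANOVA, and the age bands
    (left-exclusive, right-inclusive)."""

    criterion: float = 0.02
    max_purification: int = 10
    n_intervals: int = 5
    age_edges: tuple = DEFAULT_AGE_EDGES
    delta_scope: str = "total"  # "total": M2-M0; "each": either nested change

    def __post_init__(self):
        if self.criterion <= 0:
            raise ValueError("criterion must be positive")
        if any(b <= a for a, b in zip(self.age_edges, self.age_edges[1:])):
            raise ValueError("age band edges must be strictly increasing")


@dataclass
class DifResult:
    """Per item: McFadden R² of the nested models, ΔR² decomposition, ANOVA
    F/p, and flags.  ``table`` has one row per item."""

    table: pd.DataFrame
    covariate: str
    method: str
    n_iterations: int = 1
    notes: list = field(default_factory=list)

    @property
    def flagged(self):
        return list(self.table.index[self.table["flagged"]])


def assign_age_groups(ages, edges=DEFAULT_AGE_EDGES):
    """Three age bands, left-exclusive / right-inclusive.

    Returns (labels, n_excluded); ages at or below the first edge or above
    the last are excluded (label NaN).
    """
    s = pd.Series(ages, dtype=float)
    if ((s <= 0) | (s > 120)).any():
        raise ValueError("ages must lie in (0, 120)")
    labels = [f"({edges[i]}, {edges[i + 1]}]" for i in range(len(edges) - 1)]
    out = pd.cut(s, bins=list(edges), right=True, labels=labels)
    return out, int(out.isna().sum())


# ---------------------------------------------------------------------------
# Ordinal logistic (lordif-style)
# ---------------------------------------------------------------------------

def _null_loglik(y):
    """Intercepts-only ordinal log-likelihood: category proportions."""
    _, counts = np.unique(y, return_counts=True)
    n = counts.sum()
    return float((counts * np.log(counts / n)).sum())

def fit_proportional_odds(y, exog):
    """Proportional-odds (cumulative logit) maximum likelihood.

    P(Y <= j | x) = logistic(alpha_j - x'beta) with increasing cutpoints
    alpha (enforced by a log-spacing parametrisation).  Analytic gradient;
    categories of ``y`` must be coded 0..J-1 with every level observed.

    Returns (loglik, params) where params = (beta, alpha); raises
    ValueError when y is degenerate, returns (None, None) on optimizer
    failure.
    """
    y = np.asarray(y, dtype=int)
    X = np.atleast_2d(np.asarray(exog, dtype=float))
    if X.shape[0] != y.size:
        X = X.T
    n, p = X.shape
    cats = np.unique(y)
    J = cats.size
    if J < 2:
        raise ValueError("response needs >= 2 observed categories")
    # re-index categories densely
    yi = np.searchsorted(cats, y)

    cum = np.cumsum(np.bincount(yi, minlength=J)) / n
    alpha0 = np.log(cum[:-1] / (1 - cum[:-1]))
    t0 = np.concatenate([[alpha0[0]], np.log(np.maximum(np.diff(alpha0), 1e-3))])
    x0 = np.concatenate([np.zeros(p), t0])

    def unpack(par):
        beta = par[:p]
        a1 = par[p]
        steps = np.exp(np.clip(par[p + 1:], -30, 30))
        alpha = a1 + np.concatenate([[0.0], np.cumsum(steps)])
        return beta, alpha, steps

    def negll_grad(par):
        beta, alpha, steps = unpack(par)
        xb = X @ beta
        eta_u = np.where(yi == J - 1, np.inf, alpha[np.minimum(yi, J - 2)] - xb)
        eta_l = np.where(yi == 0, -np.inf, alpha[np.maximum(yi - 1, 0)] - xb)
        Fu = expit(eta_u)
        Fl = expit(eta_l)
        prob = np.maximum(Fu - Fl, 1e-12)
        nll = -np.log(prob).sum()
        fu = np.where(np.isfinite(eta_u), Fu * (1 - Fu), 0.0)
        fl = np.where(np.isfinite(eta_l), Fl * (1 - Fl), 0.0)
        du = fu / prob
        dl = -fl / prob
        # d ll / d beta = sum (du + dl) * (-x)
        gll_beta = -X.T @ (du + dl)
        gll_alpha = np.zeros(J - 1)
        sel_u = yi < J - 1
        np.add.at(gll_alpha, yi[sel_u], du[sel_u])
        sel_l = yi > 0
        np.add.at(gll_alpha, yi[sel_l] - 1, dl[sel_l])
        gll_a1 = gll_alpha.sum()
        gll_t = np.array([gll_alpha[k:].sum() * steps[k - 1]
                          for k in range(1, J - 1)])
        grad = -np.concatenate([gll_beta, [gll_a1], gll_t])
        return nll, grad

    res = minimize(negll_grad, x0, jac=True, method="L-BFGS-B",
                   options={"maxiter": 500})
    if not np.isfinite(res.fun):
        return None, None
    beta, alpha, _ = unpack(res.x)
    return float(-res.fun), {"beta": beta, "alpha": alpha}


def _fit_olr(y, exog):
    """Proportional-odds loglik or None on failure."""
    try:
        ll, _ = fit_proportional_odds(y, exog)
        return ll
    except Exception:
        return None


def mcfadden_r2(loglik, null_loglik):
    return 1.0 - loglik / null_loglik


def _olr_pass(df, items, theta, group_col, criterion, delta_scope):
    """One DIF screening pass; returns the per-item results table."""
    rows = []
    for lab in items:
        sub = pd.DataFrame({
            "y": df[lab], "theta": theta, "g": df[group_col]}).dropna()
        y = sub["y"].to_numpy(dtype=int)
        if np.unique(y).size < 2:
            rows.append({"item": lab, "status": "indeterminate",
                         "flagged": False})
            continue
        gdum = pd.get_dummies(sub["g"], drop_first=True, dtype=float)
        th = sub["theta"].to_numpy(dtype=float)[:, None]
        x0 = th
        x1 = np.column_stack([th, gdum.to_numpy()])
        x2 = np.column_stack([th, gdum.to_numpy(), th * gdum.to_numpy()])
        ll_null = _null_loglik(y)
        ll = [_fit_olr(y, x) for x in (x0, x1, x2)]
        if any(v is None for v in ll):
            rows.append({"item": lab, "status": "indeterminate",
                         "flagged": False})
            continue
        # guard against optimizer noise violating nesting
        ll[1] = max(ll[1], ll[0])
        ll[2] = max(ll[2], ll[1])
        r2 = [mcfadden_r2(v, ll_null) for v in ll]
        d_total = r2[2] - r2[0]
        d_unif = r2[1] - r2[0]
        d_nonunif = r2[2] - r2[1]
        if delta_scope == "total":
            flag = d_total > criterion
        else:
            flag = (d_unif > criterion) or (d_nonunif > criterion)
        rows.append({
            "item": lab, "status": "ok",
            "r2_m0": r2[0], "r2_m1": r2[1], "r2_m2": r2[2],
            "delta_r2_total": d_total, "delta_r2_uniform": d_unif,
            "delta_r2_nonuniform": d_nonunif, "n": len(sub),
            "flagged": bool(flag),
        })
    return pd.DataFrame(rows).set_index("item")


def hybrid_olr_dif(matrix, abilities, group, config=None, items=None) -> DifResult:
    """Iterative hybrid ordinal logistic regression DIF detection.

    Parameters
    ----------
    matrix : response frame (raw or recoded categories).
    abilities : AbilityTable from the calibration.
    group : Series of group labels aligned to persons (>= 2 levels).
    config : DifConfig.
    items : ItemParameters, optional.  When given, purification re-estimates
        the matching ability on the currently DIF-free anchor items between
        passes; without it a single pass is run.
    """
    cfg = config or DifConfig()
    df = pd.DataFrame(matrix).astype(float)
    group = pd.Series(group).reindex(df.index)
    levels = group.dropna().unique()
    if len(levels) < 2:
        raise ValueError("group needs >= 2 levels")
    counts = group.value_counts()
    if (counts < 30).any():
        warnings.warn("some group levels have < 30 persons; DIF models may be unstable")
    work = df.copy()
    work["_group"] = group
    item_labels = [c for c in df.columns]
    theta = abilities.persons["theta"].reindex(df.index)

    notes = []
    flagged_prev = None
    table = None
    for it in range(max(cfg.max_purification, 1)):
        table = _olr_pass(work, item_labels, theta, "_group",
                          cfg.criterion, cfg.delta_scope)
        flagged = frozenset(table.index[table["flagged"]])
        if items is None or flagged == flagged_prev:
            if items is None and flagged:
                notes.append("no item parameters supplied: single-pass screen")
            break
        flagged_prev = flagged
        anchors = [lab for lab in item_labels if lab not in flagged]
        if len(anchors) < 2:
            notes.append("fewer than 2 anchor items; purification stopped")
            break
        # purified matching variable: ability from anchor items only
        from .pcm import ItemParameters, PartialCreditModel
        anchor_params = ItemParameters(
            anchors, {a: items.thresholds[a] for a in anchors})
        sub_model = PartialCreditModel.from_parameters(
            anchor_params, ability_estimator=abilities.estimator)
        theta = sub_model.estimate_abilities(
            df[anchors]).persons["theta"].reindex(df.index)
    n_iter = it + 1
    status = table["status"] if "status" in table else None
    if status is not None and (status == "indeterminate").any():
        notes.append(f"indeterminate items: {list(table.index[status == 'indeterminate'])}")
    return DifResult(table=table, covariate=str(group.name or "group"),
                     method="hybrid_olr", n_iterations=n_iter, notes=notes)


# ---------------------------------------------------------------------------
# ANOVA of standardized residuals
# ---------------------------------------------------------------------------

def anova_residual_dif(residuals, abilities, group, config=None) -> DifResult:
    """Two-way ANOVA of standardized residuals on group and ability class
    interval (RUMM-style): group main effect = uniform DIF, group x interval
    interaction = non-uniform DIF.  p-values Bonferroni-adjusted across
    items; flag = adjusted main-effect or interaction p < 0.05.
    """
    cfg = config or DifConfig()
    z = residuals.values if hasattr(residuals, "values") and not isinstance(
        residuals, pd.DataFrame) else pd.DataFrame(residuals)
    theta = abilities.persons["theta"].reindex(z.index)
    group = pd.Series(group).reindex(z.index)
    notes = []

    rows = []
    for lab in z.columns:
        sub = pd.DataFrame({"z": z[lab], "theta": theta, "g": group}).dropna()
        if len(sub) < 10 or np.allclose(sub["z"].var(ddof=1), 0):
            rows.append({"item": lab, "status": "no-evidence", "flagged": False})
            continue
        n_int = cfg.n_intervals
        while n_int >= 2:
            try:
                sub["interval"] = pd.qcut(sub["theta"], n_int,
                                          labels=False, duplicates="drop")
            except ValueError:
                n_int -= 1
                continue
            cell = sub.groupby(["g", "interval"], observed=True).size()
            full = sub["g"].nunique() * sub["interval"].nunique()
            if len(cell) == full and (cell > 1).all() and sub["interval"].nunique() >= 2:
                break
            n_int -= 1
        if n_int < 2:
            rows.append({"item": lab, "status": "no-evidence", "flagged": False})
            notes.append(f"{lab}: intervals collapsed below 2; skipped")
            continue
        if n_int != cfg.n_intervals:
            notes.append(f"{lab}: class intervals merged to {n_int}")
        try:
            fit = ols("z ~ C(g) * C(interval)", data=sub).fit()
            an = anova_lm(fit, typ=2)
        except Exception:
            rows.append({"item": lab, "status": "no-evidence", "flagged": False})
            continue
        f_main = float(an.loc["C(g)", "F"])
        p_main = float(an.loc["C(g)", "PR(>F)"])
        f_int = float(an.loc["C(g):C(interval)", "F"])
        p_int = float(an.loc["C(g):C(interval)", "PR(>F)"])
        rows.append({"item": lab, "status": "ok", "f_group": f_main,
                     "p_group": p_main, "f_interaction": f_int,
                     "p_interaction": p_int, "n": len(sub)})
    table = pd.DataFrame(rows).set_index("item")
    n_items = int((table.get("status") == "ok").sum()) or 1
    if "p_group" in table:
        table["p_group_adj"] = np.minimum(table["p_group"] * n_items, 1.0)
        table["p_interaction_adj"] = np.minimum(table["p_interaction"] * n_items, 1.0)
        table["flagged"] = ((table["p_group_adj"] < 0.05)
                            | (table["p_interaction_adj"] < 0.05)).fillna(False)
    else:
        table["flagged"] = False
    return DifResult(table=table, covariate=str(group.name or "group"),
                     method="residual_anova", notes=notes)
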