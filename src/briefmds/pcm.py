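"""Partial credit model (PCM) calibration and person measurement.

The PCM is the Rasch-family model for ordered polytomous items: the
probability that person *n* with ability ``theta`` (logits) responds in
category ``x`` of an item with thresholds ``delta_1 .. delta_m`` is

    P(X = x | theta) = exp( sum_{k<=x} (theta - delta_k) )
                       / sum_h exp( sum_{k<=h} (theta - delta_k) ),

with the empty sum equal to 0 for ``x = 0``.  Thresholds are the abilities
at which adjacent categories are equally probable; the item *location* is
their arithmetic mean.  All items share a common discrimination, which is
what gives the model raw-score sufficiency: every raw score on a fixed item
set maps to exactly one ability estimate.

Item calibration uses marginal maximum likelihood via an EM algorithm with
Gauss–Hermite quadrature over a normal latent ability distribution
(identification: latent mean fixed at 0, latent SD free).  Person abilities
default to Warm's weighted likelihood estimator (WLE), which yields finite
estimates at the extreme raw scores 0 and maximum — required so that the
0–100 rescaling can anchor those scores exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.hermite_e import hermegauss
from scipy.optimize import brentq, minimize
from scipy.special import logsumexp
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted


class ConvergenceError(RuntimeError):
    """EM failed to converge within the iteration budget."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace


# ---------------------------------------------------------------------------
# PCM primitives
# ---------------------------------------------------------------------------

def category_probabilities(thresholds, theta):
    """PCM category probabilities at ability ``theta``.

    Parameters
    ----------
    thresholds : array-like of float, shape (m,)
        Item thresholds in logits (ordering not assumed).
    theta : float or array-like of float
        Ability in logits.

    Returns
    -------
    ndarray
        Shape ``(m + 1,)`` for scalar theta, else ``(len(theta), m + 1)``;
        nonnegative, rows sum to 1.  Computed with log-sum-exp stabilisation.
    """
    delta = np.asarray(thresholds, dtype=float)
    if delta.ndim != 1 or delta.size == 0:
        raise ValueError("thresholds must be a non-empty 1-d vector")
    th = np.asarray(theta, dtype=float)
    if not (np.all(np.isfinite(delta)) and np.all(np.isfinite(th))):
        raise ValueError("thresholds and theta must be finite")
    scalar = th.ndim == 0
    th = np.atleast_1d(th)
    m = delta.size
    # cumulative linear predictors S_x = x*theta - sum_{k<=x} delta_k, S_0 = 0
    csum = np.concatenate([[0.0], np.cumsum(delta)])
    scores = np.arange(m + 1)
    s = th[:, None] * scores[None, :] - csum[None, :]
    logp = s - logsumexp(s, axis=1, keepdims=True)
    p = np.exp(logp)
    return p[0] if scalar else p


def expected_score_and_information(thresholds, theta):
    """Expected score E, conditional variance W and item information at theta.

    For a Rasch-family polytomous item the Fisher information equals the
    conditional score variance W, so the third element duplicates the second;
    both are returned because downstream code names them differently
    (residual standardisation uses W, measurement SEs use information).
    """
    p = category_probabilities(thresholds, theta)
    scalar = p.ndim == 1
    p2 = np.atleast_2d(p)
    k = np.arange(p2.shape[1])
    e = p2 @ k
    w = (p2 * (k[None, :] - e[:, None]) ** 2).sum(axis=1)
    if scalar:
        return float(e[0]), float(w[0]), float(w[0])
    return e, w, w


def _third_central_moment(thresholds, theta):
    p = np.atleast_2d(category_probabilities(thresholds, theta))
    k = np.arange(p.shape[1])
    e = p @ k
    return (p * (k[None, :] - e[:, None]) ** 3).sum(axis=1)


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class ItemParameters:
    """Calibrated item parameters for one scale.

    ``thresholds[label]`` is the threshold vector delta_1..delta_m; the
    location is always the arithmetic mean of the thresholds.  ``recoding``
    carries the strategy digit string under which the item was calibrated
    (identity, e.g. ``"01234"``, when no collapsing was applied).
    """

    labels: list
    thresholds: dict
    recoding: dict = field(default_factory=dict)

    def __post_init__(self):
        for lab in self.labels:
            d = np.asarray(self.thresholds[lab], dtype=float)
            if d.ndim != 1 or d.size == 0:
                raise ValueError(f"item {lab!r}: thresholds must be a non-empty vector")
            self.thresholds[lab] = d
            self.recoding.setdefault(lab, "".join(str(c) for c in range(d.size + 1)))

    def location(self, label):
        return float(np.mean(self.thresholds[label]))

    @property
    def locations(self):
        return pd.Series({lab: self.location(lab) for lab in self.labels}, name="location")

    def n_categories(self, label):
        return self.thresholds[label].size + 1

    def max_score(self):
        return int(sum(self.thresholds[lab].size for lab in self.labels))

    def to_frame(self, fit_stats=None):
        """Tabular export: item, recoding strategy, outfit, infit, location,
        thresholds 1..k-1 (the published calibration-table column layout)."""
        m = max(self.thresholds[lab].size for lab in self.labels)
        rows = []
        for lab in self.labels:
            d = self.thresholds[lab]
            row = {"item": lab, "recoding_strategy": self.recoding[lab]}
            if fit_stats is not None:
                row["outfit"] = fit_stats.outfit.get(lab, np.nan)
                row["infit"] = fit_stats.infit.get(lab, np.nan)
            row["location"] = self.location(lab)
            for k in range(m):
                row[f"threshold_{k + 1}"] = d[k] if k < d.size else np.nan
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class AbilityTable:
    """Raw-score-to-ability conversion plus per-person estimates.

    ``score_table`` maps each raw score on the complete item set to a unique
    ability (score sufficiency); ``persons`` holds per-person theta/SE on the
    person's own completed item set, so incomplete responders get estimates
    too.  ``excluded`` lists persons with no scorable responses.
    """

    score_table: pd.DataFrame
    persons: pd.DataFrame
    excluded: list = field(default_factory=list)
    estimator: str = "wle"

    @property
    def theta(self):
        return self.persons["theta"]

    @property
    def se(self):
        return self.persons["se"]


# ---------------------------------------------------------------------------
# Input validation
# ---------------------------------------------------------------------------

def validate_responses(matrix, n_categories=None):
    """Validate a person x item response matrix.

    Returns a float DataFrame (NaN = missing) and the per-item top category
    m_i.  Raises on constant columns and on null (never-observed) middle
    categories, which make the PCM thresholds unidentified — the error tells
    the caller to recode first.
    """
    df = pd.DataFrame(matrix).astype(float)
    if df.shape[1] < 2:
        raise ValueError("a response matrix needs at least 2 items")
    if df.index.has_duplicates:
        raise ValueError("duplicate person identifiers in response matrix")
    vals = df.to_numpy()
    obs = vals[~np.isnan(vals)]
    if obs.size and (np.any(obs < 0) or np.any(obs != np.round(obs))):
        raise ValueError("responses must be nonnegative integer categories")
    m = {}
    for col in df.columns:
        x = df[col].dropna().to_numpy()
        if x.size == 0:
            raise ValueError(f"item {col!r} has no observed responses")
        cats = np.unique(x).astype(int)
        if cats.size < 2:
            raise ValueError(f"item {col!r} is constant (single observed category)")
        top = int(n_categories[col] - 1) if n_categories else int(cats.max())
        expected = np.arange(cats.max() + 1)
        if not np.array_equal(np.intersect1d(expected, cats), expected):
            missing = sorted(set(expected) - set(cats))
            raise ValueError(
                f"item {col!r} has null categories {missing}: collapse/recode "
                f"response options before calibration"
            )
        m[col] = top
    return df, m


# ---------------------------------------------------------------------------
# Estimator
# ---------------------------------------------------------------------------

class PartialCreditModel(BaseEstimator, TransformerMixin):
    """Partial credit model fitted by marginal maximum likelihood (EM).

    Parameters
    ----------
    n_quadrature : int, default 49
        Gauss–Hermite nodes for the latent normal ability density (>= 15).
    tol : float, default 1e-4
        EM convergence tolerance on the largest threshold change (logits).
    max_iter : int, default 500
        Maximum EM iterations.
    ability_estimator : {"wle", "mle"}, default "wle"
        Person estimator used by :meth:`estimate_abilities`.  ``"wle"`` is
        Warm's weighted likelihood estimate (finite at extreme scores);
        ``"mle"`` is maximum likelihood with extreme raw scores pulled in by
        ``extreme_adjustment`` score points.
    extreme_adjustment : float, default 0.3
        Score-point adjustment applied to raw scores 0 and max in MLE mode.

    Attributes
    ----------
    item_labels_ : list of item labels in fitting order.
    thresholds_ : dict label -> ndarray of estimated thresholds (logits).
    item_parameters_ : :class:`ItemParameters`.
    latent_sd_ : estimated SD of the latent ability distribution.
    loglik_ : final marginal log-likelihood.
    n_iter_, converged_ : EM bookkeeping.
    """

    def __init__(self, n_quadrature=49, tol=1e-4, max_iter=500,
                 ability_estimator="wle", extreme_adjustment=0.3):
        self.n_quadrature = n_quadrature
        self.tol = tol
        self.max_iter = max_iter
        self.ability_estimator = ability_estimator
        self.extreme_adjustment = extreme_adjustment

    @classmethod
    def from_parameters(cls, items, **kwargs):
        """Build a fitted-state model from known item parameters (no data),
        e.g. to score persons on an anchor subset or on generating truth."""
        model = cls(**kwargs)
        model.item_labels_ = list(items.labels)
        model.thresholds_ = {lab: np.asarray(items.thresholds[lab], dtype=float)
                             for lab in items.labels}
        model.item_parameters_ = items
        return model

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y=None):
        if self.n_quadrature < 15:
            raise ValueError("n_quadrature must be >= 15")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.ability_estimator not in ("wle", "mle"):
            raise ValueError("ability_estimator must be 'wle' or 'mle'")
        df, mtop = validate_responses(X)
        labels = list(df.columns)
        vals = df.to_numpy()
        n, n_items = vals.shape
        m = np.array([mtop[lab] for lab in labels])

        # responses as int with -1 for missing
        xi = np.where(np.isnan(vals), -1, vals).astype(int)

        nodes, wts = hermegauss(self.n_quadrature)  # weight exp(-x^2/2)
        logw_base = np.log(wts) - 0.5 * np.log(2 * np.pi)

        delta = [np.zeros(mi) for mi in m]
        # moment start: thresholds spread around a logit of the observed mean
        for i, lab in enumerate(labels):
            x = df[lab].dropna().to_numpy()
            pbar = np.clip(x.mean() / m[i], 0.02, 0.98)
            loc = -np.log(pbar / (1 - pbar))
            delta[i] = loc + np.linspace(-0.5, 0.5, m[i]) * max(m[i] - 1, 1)
        sigma = 1.0
        loglik = -np.inf
        trace = []

        for it in range(self.max_iter):
            theta_q = sigma * nodes
            # log P per item, node, category
            logp = np.full((n_items, self.n_quadrature, m.max() + 1), -np.inf)
            for i in range(n_items):
                csum = np.concatenate([[0.0], np.cumsum(delta[i])])
                s = theta_q[:, None] * np.arange(m[i] + 1)[None, :] - csum[None, :]
                logp[i, :, : m[i] + 1] = s - logsumexp(s, axis=1, keepdims=True)
            # person x node log-likelihood
            ll = np.zeros((n, self.n_quadrature))
            for i in range(n_items):
                ok = xi[:, i] >= 0
                ll[ok] += logp[i][:, xi[ok, i]].T
            joint = ll + logw_base[None, :]
            norm = logsumexp(joint, axis=1)
            post = np.exp(joint - norm[:, None])
            new_loglik = float(norm.sum())

            # expected category counts per item/node
            new_delta = []
            for i in range(n_items):
                ok = xi[:, i] >= 0
                nqk = np.zeros((self.n_quadrature, m[i] + 1))
                for k in range(m[i] + 1):
                    sel = ok & (xi[:, i] == k)
                    if sel.any():
                        nqk[:, k] = post[sel].sum(axis=0)
                new_delta.append(self._mstep_item(delta[i], theta_q, nqk))
            # latent SD from posterior second moment (mean anchored at 0)
            sigma_new = float(np.sqrt((post * (theta_q[None, :] ** 2)).sum() / n))
            sigma_new = min(max(sigma_new, 1e-3), 10.0)

            change = max(
                float(np.max(np.abs(new_delta[i] - delta[i]))) for i in range(n_items)
            )
            change = max(change, abs(sigma_new - sigma))
            delta, sigma, loglik = new_delta, sigma_new, new_loglik
            trace.append({"iter": it, "loglik": loglik, "change": change})
            if change < self.tol:
                self.converged_ = True
                break
        else:
            raise ConvergenceError(
                f"PCM EM did not converge in {self.max_iter} iterations "
                f"(last change {change:.3g})", trace=trace)

        self.item_labels_ = labels
        self.thresholds_ = {lab: delta[i] for i, lab in enumerate(labels)}
        self.item_parameters_ = ItemParameters(labels, dict(self.thresholds_))
        self.latent_sd_ = sigma
        self.loglik_ = loglik
        self.n_iter_ = it + 1
        self.trace_ = trace
        return self

    @staticmethod
    def _mstep_item(delta0, theta_q, nqk):
        """Maximise sum_{q,k} n_qk log P_k(theta_q; delta) over delta."""
        mi = delta0.size
        scores = np.arange(mi + 1)
        nq = nqk.sum(axis=1)
        # r_qj = expected count with X >= j, j = 1..m
        rq = np.cumsum(nqk[:, ::-1], axis=1)[:, ::-1][:, 1:]

        def negll_grad(d):
            csum = np.concatenate([[0.0], np.cumsum(d)])
            s = theta_q[:, None] * scores[None, :] - csum[None, :]
            lse = logsumexp(s, axis=1)
            nll = -(np.sum(nqk * s) - np.sum(nq * lse))
            p = np.exp(s - lse[:, None])
            pge = np.cumsum(p[:, ::-1], axis=1)[:, ::-1][:, 1:]  # P(X>=j)
            # d logL / d delta_j = sum_q (-r_qj + n_q * pge_qj)
            grad = (rq - nq[:, None] * pge).sum(axis=0)
            return nll, grad

        res = minimize(negll_grad, delta0, jac=True, method="L-BFGS-B")
        return res.x

    # -- marginal likelihood (used by tests as a direct objective) ---------

    def marginal_loglik(self, X, thresholds, sigma):
        """Marginal log-likelihood of data under given thresholds/latent SD."""
        df, mtop = validate_responses(X)
        labels = list(df.columns)
        vals = df.to_numpy()
        xi = np.where(np.isnan(vals), -1, vals).astype(int)
        nodes, wts = hermegauss(self.n_quadrature)
        theta_q = sigma * nodes
        logw = np.log(wts) - 0.5 * np.log(2 * np.pi)
        ll = np.zeros((vals.shape[0], self.n_quadrature))
        for i, lab in enumerate(labels):
            d = np.asarray(thresholds[lab], dtype=float)
            csum = np.concatenate([[0.0], np.cumsum(d)])
            s = theta_q[:, None] * np.arange(d.size + 1)[None, :] - csum[None, :]
            logp = s - logsumexp(s, axis=1, keepdims=True)
            ok = xi[:, i] >= 0
            ll[ok] += logp[:, xi[ok, i]].T
        return float(logsumexp(ll + logw[None, :], axis=1).sum())

    # -- person measurement ------------------------------------------------

    def _solve_score(self, thresholds_list, r, mode):
        """Ability for raw score r on the given item set."""
        total = sum(d.size for d in thresholds_list)

        if mode == "mle":
            r_adj = float(np.clip(r, self.extreme_adjustment,
                                  total - self.extreme_adjustment))

            def f(th):
                return r_adj - sum(
                    expected_score_and_information(d, th)[0] for d in thresholds_list)
        else:
            def f(th):
                e = w = j3 = 0.0
                for d in thresholds_list:
                    ei, wi, _ = expected_score_and_information(d, th)
                    e += ei
                    w += wi
                    j3 += float(_third_central_moment(d, np.atleast_1d(th))[0])
                return (r - e) + j3 / (2.0 * w)

        lo, hi = -15.0, 15.0
        flo, fhi = f(lo), f(hi)
        while flo < 0 and lo > -40:
            lo -= 10
            flo = f(lo)
        while fhi > 0 and hi < 40:
            hi += 10
            fhi = f(hi)
        theta = brentq(f, lo, hi, xtol=1e-8)
        info = sum(expected_score_and_information(d, theta)[1] for d in thresholds_list)
        return float(theta), float(1.0 / np.sqrt(info))

    def estimate_abilities(self, X):
        """Person abilities and the raw-score conversion table.

        Complete responders share one score table (raw-score sufficiency);
        incomplete responders are measured on their own completed item set.
        Persons with no responses are excluded and listed.
        """
        check_is_fitted(self, "thresholds_")
        df = pd.DataFrame(X).astype(float)
        missing_cols = [c for c in self.item_labels_ if c not in df.columns]
        if missing_cols:
            raise ValueError(f"matrix lacks calibrated items: {missing_cols}")
        df = df[self.item_labels_]
        mode = self.ability_estimator

        full_set = tuple(self.item_labels_)
        cache = {}

        def theta_for(itemset, r):
            key = (itemset, int(r))
            if key not in cache:
                dl = [self.thresholds_[lab] for lab in itemset]
                cache[key] = self._solve_score(dl, r, mode)
            return cache[key]

        max_r = self.item_parameters_.max_score()
        table = []
        for r in range(max_r + 1):
            th, se = theta_for(full_set, r)
            table.append({"raw_score": r, "theta": th, "se": se})
        score_table = pd.DataFrame(table)

        rows, excluded = [], []
        for pid, row in df.iterrows():
            answered = tuple(lab for lab in self.item_labels_ if not np.isnan(row[lab]))
            if not answered:
                excluded.append(pid)
                continue
            r = int(sum(row[lab] for lab in answered))
            th, se = theta_for(answered, r)
            rows.append({"person": pid, "theta": th, "se": se,
                         "raw_score": r, "n_items": len(answered)})
        persons = pd.DataFrame(rows).set_index("person") if rows else pd.DataFrame(
            columns=["theta", "se", "raw_score", "n_items"])
        return AbilityTable(score_table=score_table, persons=persons,
                            excluded=excluded, estimator=mode)

    def transform(self, X):
        """Ability estimates as a column vector (sklearn transformer surface)."""
        at = self.estimate_abilities(X)
        df = pd.DataFrame(X)
        out = at.persons["theta"].reindex(df.index)
        return out.to_numpy()[:, None]


# ---------------------------------------------------------------------------
# Thin functional wrappers (spec-level operations)
# ---------------------------------------------------------------------------

@dataclass
class FitConfig:
    """Calibration settings: quadrature density, EM tolerance/budget and the
    person-ability estimator ('wle' or 'mle' with extreme-score adjustment)."""
    n_quadrature: int = 49
    tol: float = 1e-4
    max_iter: int = 500
    ability_estimator: str = "wle"
    extreme_adjustment: float = 0.3


def fit_pcm(matrix, config=None):
    cfg = config or FitConfig()
    model = PartialCreditModel(
        n_quadrature=cfg.n_quadrature, tol=cfg.tol, max_iter=cfg.max_iter,
        ability_estimator=cfg.ability_estimator,
        extreme_adjustment=cfg.extreme_adjustment).fit(matrix)
    return model


def estimate_abilities(matrix, model):
    return model.estimate_abilities(matrix)
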