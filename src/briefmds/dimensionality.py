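"""Unidimensionality testing: polychoric correlations and bifactor analysis.

A Rasch metric presumes one dominant latent dimension.  The check used here
estimates the polychoric correlation matrix of the ordinal items (two-step:
thresholds from inverse-normal cumulative marginals, then per-pair ML over
the bivariate-normal correlation), fits an exploratory bifactor solution via
Schmid–Leiman orthogonalization of an oblique group-factor solution, and
declares unidimensionality when (1) every item loads high on the general
factor and (2) every item's general loading exceeds its group loading.

"High" is operationalised by a configurable cutoff (default 0.4), reported
alongside the verdict.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import multivariate_normal, norm
from sklearn.base import BaseEstimator

RHO_BOUND = 0.999


# ---------------------------------------------------------------------------
# Polychoric correlation
# ---------------------------------------------------------------------------

@dataclass
class PolychoricMatrix:
    matrix: pd.DataFrame
    thresholds: dict
    clamped_pairs: list = field(default_factory=list)


def _marginal_thresholds(x):
    """Normal quantiles of the cumulative category proportions (upper cut
    excluded); x is a 1-d array without NaN."""
    cats, counts = np.unique(x, return_counts=True)
    cum = np.cumsum(counts) / counts.sum()
    return norm.ppf(cum[:-1]), cats


def _pair_loglik(rho, table, a_cuts, b_cuts):
    a = np.concatenate([[-np.inf], a_cuts, [np.inf]])
    b = np.concatenate([[-np.inf], b_cuts, [np.inf]])
    mvn = multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]])
    # CDF at every grid corner, then rectangle probabilities by differencing
    aa, bb = np.meshgrid(a, b, indexing="ij")
    pts = np.column_stack([aa.ravel(), bb.ravel()])
    finite = np.where(np.isfinite(pts), pts, np.sign(pts) * 30.0)
    cdf = mvn.cdf(finite).reshape(aa.shape)
    cell = cdf[1:, 1:] - cdf[:-1, 1:] - cdf[1:, :-1] + cdf[:-1, :-1]
    cell = np.clip(cell, 1e-12, None)
    return float((table * np.log(cell)).sum())


def polychoric_pair(x, y):
    """Two-step polychoric correlation of two ordinal vectors (no NaN).

    Returns (rho, clamped): clamped is True when the ML estimate ran into
    the +/-1 boundary (empty-cell degeneracy) and was clipped to +/-0.999.
    """
    a_cuts, a_cats = _marginal_thresholds(x)
    b_cuts, b_cats = _marginal_thresholds(y)
    table = np.zeros((a_cats.size, b_cats.size))
    ai = np.searchsorted(a_cats, x)
    bi = np.searchsorted(b_cats, y)
    np.add.at(table, (ai, bi), 1)

    res = minimize_scalar(lambda r: -_pair_loglik(r, table, a_cuts, b_cuts),
                          bounds=(-RHO_BOUND, RHO_BOUND), method="bounded",
                          options={"xatol": 1e-4})
    rho = float(res.x)
    clamped = abs(rho) > RHO_BOUND - 2e-3
    if clamped:
        rho = float(np.sign(rho) * RHO_BOUND)
    return rho, clamped


def polychoric_matrix(matrix) -> PolychoricMatrix:
    """Polychoric correlation matrix over pairwise-complete observations."""
    df = pd.DataFrame(matrix).astype(float)
    cols = list(df.columns)
    thresholds = {}
    for c in cols:
        x = df[c].dropna().to_numpy()
        if np.unique(x).size < 2:
            raise ValueError(f"item {c!r} needs >= 2 observed categories")
        thresholds[c] = _marginal_thresholds(x)[0]
    mat = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    clamped_pairs = []
    for a, b in itertools.combinations(cols, 2):
        sub = df[[a, b]].dropna()
        rho, clamped = polychoric_pair(sub[a].to_numpy(), sub[b].to_numpy())
        mat.loc[a, b] = mat.loc[b, a] = rho
        if clamped:
            clamped_pairs.append((a, b))
    return PolychoricMatrix(matrix=mat, thresholds=thresholds,
                            clamped_pairs=clamped_pairs)


# ---------------------------------------------------------------------------
# Factor machinery
# ---------------------------------------------------------------------------

def smooth_to_psd(corr, eps=1e-6):
    """Eigenvalue-clip a correlation matrix to positive semidefiniteness,
    restoring the unit diagonal.  Returns (smoothed, was_smoothed)."""
    c = np.asarray(corr, dtype=float)
    vals, vecs = np.linalg.eigh(c)
    if vals.min() >= eps:
        return c, False
    vals = np.clip(vals, eps, None)
    out = vecs @ np.diag(vals) @ vecs.T
    d = np.sqrt(np.diag(out))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return out, True


def _principal_axis(corr, n_factors, max_iter=200, tol=1e-6):
    """Principal-axis factoring with iterated communalities."""
    r = np.asarray(corr, dtype=float).copy()
    p = r.shape[0]
    try:
        inv = np.linalg.inv(r)
        h2 = 1.0 - 1.0 / np.diag(inv)  # squared multiple correlations
    except np.linalg.LinAlgError:
        h2 = np.full(p, 0.5)
    h2 = np.clip(h2, 0.05, 0.98)
    for _ in range(max_iter):
        rr = r.copy()
        np.fill_diagonal(rr, h2)
        vals, vecs = np.linalg.eigh(rr)
        order = np.argsort(vals)[::-1][:n_factors]
        lam = vecs[:, order] * np.sqrt(np.clip(vals[order], 0, None))
        h2_new = np.clip((lam ** 2).sum(axis=1), 0.0, 1.0)
        if np.max(np.abs(h2_new - h2)) < tol:
            h2 = h2_new
            break
        h2 = h2_new
    # sign convention: dominant direction positive per factor
    for j in range(lam.shape[1]):
        if lam[:, j].sum() < 0:
            lam[:, j] = -lam[:, j]
    return lam


def _oblique_rotate(loadings):
    """Quartimin (oblique) rotation; returns rotated loadings and the factor
    correlation matrix."""
    from statsmodels.multivariate.factor_rotation import rotate_factors
    if loadings.shape[1] == 1:
        return loadings, np.ones((1, 1))
    L, T = rotate_factors(loadings, "quartimin")
    phi = T.T @ T
    # normalise phi to a correlation matrix (guard against scaling drift)
    d = np.sqrt(np.diag(phi))
    phi = phi / np.outer(d, d)
    for j in range(L.shape[1]):
        if L[:, j].sum() < 0:
            L[:, j] = -L[:, j]
            phi[j, :] *= -1
            phi[:, j] *= -1
    return L, phi


# ---------------------------------------------------------------------------
# Bifactor estimator
# ---------------------------------------------------------------------------

@dataclass
class BifactorSolution:
    """Schmid–Leiman bifactor loadings: one general factor, one group factor
    per item (the item's assigned group).  ``specific_loadings_full`` keeps
    the whole item x group-factor matrix for inspection."""

    general_loadings: pd.Series
    group_loadings: pd.Series
    group_of: dict
    specific_loadings_full: pd.DataFrame
    heywood_items: list = field(default_factory=list)
    smoothed: bool = False

    def to_frame(self):
        return pd.DataFrame({
            "lambda_general": self.general_loadings,
            "lambda_group": self.group_loadings,
            "group": pd.Series(self.group_of),
        })


class PolychoricBifactor(BaseEstimator):
    """Exploratory bifactor analysis of ordinal items.

    fit(X) computes the polychoric matrix of the ordinal response frame X,
    extracts ``n_factors`` oblique group factors (principal axis +
    quartimin), fits a single higher-order factor to their correlation
    matrix and Schmid–Leiman-orthogonalizes into a general factor plus
    orthogonal group factors.

    Parameters
    ----------
    group_assignment : dict item -> group label; group count fixes the
        number of extracted factors.
    high_cutoff : float, default 0.4
        "Loads high" threshold for the unidimensionality verdict.
    """

    def __init__(self, group_assignment=None, high_cutoff=0.4):
        self.group_assignment = group_assignment
        self.high_cutoff = high_cutoff

    def fit(self, X, y=None):
        pc = X if isinstance(X, PolychoricMatrix) else polychoric_matrix(X)
        self.polychoric_ = pc
        corr = pc.matrix.to_numpy()
        items = list(pc.matrix.columns)
        if self.group_assignment:
            groups = sorted(set(self.group_assignment.values()))
            if len(groups) < 2:
                raise ValueError("need >= 2 groups for a bifactor structure")
        else:
            # fallback: split items into two halves
            half = len(items) // 2
            self.group_assignment = {it: ("g1" if i < half else "g2")
                                     for i, it in enumerate(items)}
            groups = ["g1", "g2"]
        k = len(groups)

        corr_s, smoothed = smooth_to_psd(corr)
        lam = _principal_axis(corr_s, k)

        # Null-factor screen BEFORE rotation: an extracted factor that has
        # no salient unrotated loading or negligible shared variance (sum of
        # squared loadings) is sampling noise — the data have lower rank
        # than k.  Rotating it anyway smears the general factor across
        # columns; with a single substantive factor left, that factor IS the
        # general dimension and rotation is skipped entirely.
        salient = ((np.abs(lam).max(axis=0) >= 0.25)
                   & ((lam ** 2).sum(axis=0) >= 0.25))
        if salient.sum() <= 1:
            L = lam
            phi = np.eye(k)
            gamma = np.where(salient, 1.0, 0.0)
            if not salient.any():
                gamma = np.zeros(k)
        else:
            L, phi = _oblique_rotate(lam)
            if k == 2:
                # one correlation, two loadings: equal-loading convention
                gamma = np.full(2, np.sqrt(np.clip(phi[0, 1], 0.0, 1.0)))
            else:
                gamma = _principal_axis(phi, 1)[:, 0]
        gamma = np.clip(np.abs(gamma), 0.0, 1.0)  # general factor direction

        lam_g = L @ gamma
        lam_s_full = L * np.sqrt(np.clip(1.0 - gamma**2, 0.0, None))[None, :]

        # match rotated factors to the named groups by mean absolute loading
        assign_idx = {}
        taken = set()
        for g in groups:
            members = [i for i, it in enumerate(items)
                       if self.group_assignment.get(it) == g]
            means = [np.mean(np.abs(lam_s_full[members, j]))
                     if j not in taken else -np.inf for j in range(k)]
            j = int(np.argmax(means))
            assign_idx[g] = j
            taken.add(j)

        heywood = []
        comm = lam_g**2 + (lam_s_full**2).sum(axis=1)
        for i, it in enumerate(items):
            if comm[i] > 1.0 + 1e-8:
                heywood.append(it)
        if heywood:
            warnings.warn(f"Heywood cases clipped: {heywood}")
        lam_g = np.clip(lam_g, -1.0, 1.0)
        lam_s_full = np.clip(lam_s_full, -1.0, 1.0)

        group_of = {it: self.group_assignment.get(it, "g1") for it in items}
        group_load = pd.Series(
            {it: float(np.abs(lam_s_full[i, assign_idx[group_of[it]]]))
             for i, it in enumerate(items)})
        self.solution_ = BifactorSolution(
            general_loadings=pd.Series(lam_g, index=items),
            group_loadings=group_load,
            group_of=group_of,
            specific_loadings_full=pd.DataFrame(
                lam_s_full, index=items,
                columns=[f"factor_{j + 1}" for j in range(k)]),
            heywood_items=heywood,
            smoothed=smoothed,
        )
        return self


def fit_bifactor(pc, group_assignment) -> BifactorSolution:
    return PolychoricBifactor(group_assignment=group_assignment).fit(pc).solution_


@dataclass
class UnidimensionalityVerdict:
    passed: bool
    high_cutoff: float
    detail: pd.DataFrame
    failing_items: list


def unidimensionality_check(sol: BifactorSolution, high_cutoff=0.4):
    """Both conditions must hold item-wise: lambda_general >= cutoff and
    lambda_general > lambda_group."""
    detail = sol.to_frame()
    detail["loads_high"] = detail["lambda_general"] >= high_cutoff
    detail["general_exceeds_group"] = (
        detail["lambda_general"] > detail["lambda_group"])
    ok = detail["loads_high"] & detail["general_exceeds_group"]
    return UnidimensionalityVerdict(
        passed=bool(ok.all()), high_cutoff=high_cutoff, detail=detail,
        failing_items=list(detail.index[~ok]))
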