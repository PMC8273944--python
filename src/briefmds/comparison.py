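"""Brief-vs-full version precision.

Quantifies how faithfully a brief scale reproduces the full scale it was
drawn from: (a) Pearson correlation between the two ability estimates, and
(b) the explained variance (R²) of an ordinary least squares regression of
the full-version score on the brief version's item responses, entered as
numeric category codes (dummy coding available by flag).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm


@dataclass
class ComparisonResult:
    r: float
    r_squared: float
    n: int
    coefficients: pd.Series = None


def ability_correlation(full_scores, brief_scores):
    """Pearson correlation of paired full/brief ability estimates."""
    pair = pd.DataFrame({"full": pd.Series(full_scores),
                         "brief": pd.Series(brief_scores)}).dropna()
    if len(pair) < 3:
        raise ValueError("need >= 3 complete pairs")
    if pair["full"].var(ddof=1) == 0 or pair["brief"].var(ddof=1) == 0:
        raise ValueError("correlation undefined: zero variance")
    return float(np.corrcoef(pair["full"], pair["brief"])[0, 1])


def save_paired_scores(full_scores, brief_scores, path):
    """Write the paired full/brief scores as a two-column CSV."""
    pd.DataFrame({"full": pd.Series(full_scores),
                  "brief": pd.Series(brief_scores)}).to_csv(
        path, index_label="person")


def regress_full_on_brief_items(full_scores, brief_matrix,
                                dummy_coding=False) -> ComparisonResult:
    """OLS of the full-version score on the brief item responses.

    Complete-case rows only; requires at least 10 rows per predictor.
    Collinear predictors are handled by the pseudo-inverse with a warning.
    """
    X = pd.DataFrame(brief_matrix).astype(float)
    y = pd.Series(full_scores).reindex(X.index)
    data = X.copy()
    data["_y"] = y
    data = data.dropna()
    if dummy_coding:
        Xd = pd.get_dummies(data.drop(columns="_y").astype(int).astype("category"),
                            drop_first=True, dtype=float)
    else:
        Xd = data.drop(columns="_y")
    if len(data) < 10 * Xd.shape[1]:
        raise ValueError(
            f"need >= {10 * Xd.shape[1]} complete rows for {Xd.shape[1]} predictors")
    exog = sm.add_constant(Xd, has_constant="add")
    if np.linalg.matrix_rank(exog.to_numpy()) < exog.shape[1]:
        warnings.warn("collinear predictors: rank-deficient design, using pinv")
    res = sm.OLS(data["_y"], exog).fit()
    yv = data["_y"]
    r = float(np.corrcoef(yv, res.fittedvalues)[0, 1]) if yv.var(ddof=1) > 0 else np.nan
    return ComparisonResult(r=r, r_squared=float(res.rsquared), n=len(data),
                            coefficients=res.params)
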