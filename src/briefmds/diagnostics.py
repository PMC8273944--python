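"""Rasch diagnostics: threshold ordering, category recoding, standardized
residuals, local dependence, testlets, infit/outfit and targeting.

These are the checks of the iterative calibration loop used for survey
metrics: fit the partial credit model, flag disordered thresholds and
collapse response categories (strategies written as digit strings, e.g.
``"01112"`` collapses the three middle categories of a five-option item),
flag residual correlations above 0.2 as local dependence and absorb flagged
pairs into summed testlet super-items, then judge item fit by infit/outfit
mean squares against the (0.8, 1.2) band and targeting by the offset between
the person-ability and item-threshold distributions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pcm import expected_score_and_information

FIT_BAND = (0.8, 1.2)
LD_CUTOFF = 0.2


# ---------------------------------------------------------------------------
# Threshold ordering and recoding
# ---------------------------------------------------------------------------

def check_threshold_ordering(items):
    """Flag items whose thresholds are not strictly increasing.

    Returns a list of ``(label, disordered)``; a single-threshold item is
    vacuously ordered.
    """
    out = []
    for lab in items.labels:
        d = items.thresholds[lab]
        out.append((lab, bool(np.any(np.diff(d) <= 0))))
    return out


@dataclass
class RecodingStrategy:
    """Category-collapsing strategy as a digit string, one digit per original
    category: ``"00122"`` maps categories (0,1,2,3,4) to (0,0,1,2,2)."""

    item: str
    strategy: str

    def __post_init__(self):
        digits = [int(c) for c in self.strategy]
        if not digits:
            raise ValueError("empty strategy")
        if digits[0] != 0:
            raise ValueError(f"{self.item}: strategy must start at 0")
        if any(b < a for a, b in zip(digits, digits[1:])):
            raise ValueError(f"{self.item}: strategy digits must be non-decreasing")
        if sorted(set(digits)) != list(range(max(digits) + 1)):
            raise ValueError(f"{self.item}: recoded categories must be contiguous from 0")
        self.mapping = digits

    @property
    def is_identity(self):
        return self.mapping == list(range(len(self.mapping)))

    def apply(self, values):
        arr = pd.Series(values).astype(float)
        out = arr.map(lambda v: float(self.mapping[int(v)]) if not np.isnan(v) else np.nan)
        return out.to_numpy()


def apply_recoding(matrix, strategies):
    """Apply collapsing strategies to a response matrix (missing preserved)."""
    df = pd.DataFrame(matrix).copy()
    for st in strategies:
        if st.item not in df.columns:
            raise KeyError(f"unknown item {st.item!r}")
        observed_max = int(df[st.item].max())
        if observed_max + 1 > len(st.strategy):
            raise ValueError(
                f"{st.item}: strategy length {len(st.strategy)} shorter than "
                f"observed categories 0..{observed_max}")
        df[st.item] = st.apply(df[st.item])
    return df


def propose_recoding(current_strategy, thresholds):
    """Propose a one-step collapse for a disordered item.

    At the first boundary where ``delta_{k+1} <= delta_k``, category *k* (the
    category squeezed between the two disordered thresholds) is merged into
    category *k - 1*.  Returns the composed strategy string relative to the
    ORIGINAL categories, or None if the thresholds are ordered or the item is
    already binary.
    """
    d = np.asarray(thresholds, dtype=float)
    if d.size <= 1 or np.all(np.diff(d) > 0):
        return None
    k = int(np.argmax(np.diff(d) <= 0)) + 1  # category between delta_k, delta_{k+1}
    current = [int(c) for c in current_strategy]
    n_new = max(current) + 1
    if n_new <= 2:
        return None
    # merge recoded category k into k-1, shift the ones above down
    merge = [c - 1 if c >= k else c for c in range(n_new)]
    composed = [merge[c] for c in current]
    return "".join(str(c) for c in composed)


# ---------------------------------------------------------------------------
# Residuals and local dependence
# ---------------------------------------------------------------------------

@dataclass
class ResidualMatrix:
    """Standardized Rasch residuals z = (x - E)/sqrt(W), aligned to the
    response matrix; ``n_excluded`` counts cells dropped for W ~ 0."""

    values: pd.DataFrame
    n_excluded: int = 0


def standardized_residuals(matrix, items, abilities) -> ResidualMatrix:
    """z_ni = (x_ni - E_ni)/sqrt(W_ni) with E, W at the person's ability."""
    df = pd.DataFrame(matrix).astype(float)
    theta = abilities.persons["theta"].reindex(df.index)
    z = pd.DataFrame(np.nan, index=df.index, columns=df.columns)
    excluded = 0
    th = theta.to_numpy(dtype=float)
    ok_person = ~np.isnan(th)
    for lab in items.labels:
        if lab not in df.columns:
            continue
        x = df[lab].to_numpy(dtype=float)
        e, w, _ = expected_score_and_information(items.thresholds[lab],
                                                 np.where(ok_person, th, 0.0))
        valid = ok_person & ~np.isnan(x)
        tiny = valid & (w < 1e-10)
        excluded += int(tiny.sum())
        use = valid & ~tiny
        zi = np.full(len(df), np.nan)
        zi[use] = (x[use] - e[use]) / np.sqrt(w[use])
        z[lab] = zi
    return ResidualMatrix(values=z, n_excluded=excluded)


def residual_correlations(res: ResidualMatrix, cutoff=LD_CUTOFF):
    """Pairwise-complete Pearson correlations of residuals for every item
    pair; a pair is flagged as locally dependent iff r > cutoff (strict).

    Returns a DataFrame (item_a, item_b, r, n, flagged); pairs with fewer
    than 3 complete observations are listed with r = NaN and not flagged.
    """
    z = res.values
    rows = []
    for a, b in itertools.combinations(z.columns, 2):
        sub = z[[a, b]].dropna()
        if len(sub) < 3:
            rows.append({"item_a": a, "item_b": b, "r": np.nan,
                         "n": len(sub), "flagged": False})
            continue
        r = float(np.corrcoef(sub[a], sub[b])[0, 1])
        rows.append({"item_a": a, "item_b": b, "r": r, "n": len(sub),
                     "flagged": bool(r > cutoff)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Testlets
# ---------------------------------------------------------------------------

@dataclass
class TestletSpec:
    """Aggregate locally dependent items into one summed super-item."""

    __test__ = False  # keep pytest from collecting the 'Test' prefix

    members: tuple
    label: str

    def __post_init__(self):
        self.members = tuple(self.members)
        if len(self.members) < 2:
            raise ValueError("a testlet needs >= 2 member items")


def build_testlet(matrix, spec: TestletSpec):
    """Replace member items by their summed super-item.

    A person's testlet score is the sum of member scores and is missing if
    ANY member is missing (all-or-missing rule, preserving score
    sufficiency of the aggregate).
    """
    df = pd.DataFrame(matrix).copy()
    for lab in spec.members:
        if lab not in df.columns:
            raise KeyError(f"testlet member {lab!r} not in matrix")
    total = df[list(spec.members)].sum(axis=1, skipna=False)
    df = df.drop(columns=list(spec.members))
    df[spec.label] = total
    return df


def build_testlets(matrix, specs):
    """Apply several testlets, rejecting overlapping membership."""
    seen = set()
    for spec in specs:
        dup = seen.intersection(spec.members)
        if dup:
            raise ValueError(f"overlapping testlets share items {sorted(dup)}")
        seen.update(spec.members)
    df = matrix
    for spec in specs:
        df = build_testlet(df, spec)
    return df


# ---------------------------------------------------------------------------
# Item fit
# ---------------------------------------------------------------------------

@dataclass
class FitStatistics:
    """Per-item infit/outfit mean squares with flags against (0.8, 1.2)."""

    outfit: dict
    infit: dict
    flags: dict = field(default_factory=dict)
    excluded_items: list = field(default_factory=list)

    def to_frame(self):
        return pd.DataFrame({
            "outfit": pd.Series(self.outfit),
            "infit": pd.Series(self.infit),
            "flag": pd.Series(self.flags),
        })


def infit_outfit(matrix, items, abilities, band=FIT_BAND,
                 bias_correction=True) -> FitStatistics:
    """Outfit = mean squared standardized residual; infit = information-
    weighted mean square, sum (x-E)^2 / sum W.  Values near 1 indicate fit;
    > 1.2 misfit (outlier influence), < 0.8 overfit/redundancy.

    With ``bias_correction`` (default) the denominator W is deflated by the
    item's leverage on the person's ability estimate, W(1 - W/I_person):
    expectations computed at an ability estimated from the same responses
    shrink the residuals by one degree of freedom per person, which with a
    short scale pulls the classical (uncorrected, Wright-style) statistics
    visibly below 1 even when the model holds.  Set it to False for the
    classical form.
    """
    df = pd.DataFrame(matrix).astype(float)
    theta = abilities.persons["theta"].reindex(df.index).to_numpy(dtype=float)
    ok_person = ~np.isnan(theta)
    e_all, w_all = {}, {}
    for lab in items.labels:
        e, w, _ = expected_score_and_information(items.thresholds[lab],
                                                 np.where(ok_person, theta, 0.0))
        e_all[lab], w_all[lab] = e, w
    info_person = np.sum([w_all[lab] for lab in items.labels], axis=0)
    outfit, infit, flags, excluded = {}, {}, {}, []
    for lab in items.labels:
        x = df[lab].to_numpy(dtype=float)
        e, w = e_all[lab], w_all[lab]
        use = ok_person & ~np.isnan(x) & (w > 1e-10)
        if not use.any():
            excluded.append(lab)
            continue
        weff = w[use]
        if bias_correction:
            weff = weff * (1.0 - w[use] / np.maximum(info_person[use], w[use]))
            weff = np.maximum(weff, 1e-10)
        sq = (x[use] - e[use]) ** 2
        outfit[lab] = float(np.mean(sq / weff))
        infit[lab] = float(sq.sum() / weff.sum())
        lo, hi = band
        if infit[lab] > hi:
            flags[lab] = "misfit"
        elif infit[lab] < lo:
            flags[lab] = "overfit"
        else:
            flags[lab] = "ok"
    return FitStatistics(outfit=outfit, infit=infit, flags=flags,
                         excluded_items=excluded)


# ---------------------------------------------------------------------------
# Targeting
# ---------------------------------------------------------------------------

def targeting_summary(items, abilities):
    """Mean/SD of item threshold difficulties vs person abilities.

    A well-targeted metric has both means near zero; the offset (ability
    mean minus difficulty mean) quantifies how far the population sits from
    the scale's working range.
    """
    th = np.concatenate([items.thresholds[lab] for lab in items.labels])
    ab = abilities.persons["theta"].to_numpy(dtype=float)
    ab = ab[~np.isnan(ab)]
    out = {
        "difficulty": {"mean": float(np.mean(th)), "sd": float(np.std(th, ddof=1))},
        "ability": {"mean": float(np.mean(ab)), "sd": float(np.std(ab, ddof=1))},
    }
    out["offset"] = out["ability"]["mean"] - out["difficulty"]["mean"]
    return out
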