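"""Reliability, 0–100 rescaling and severity cutoffs.

The Person Separation Index (PSI) is the Rasch analogue of Cronbach's
alpha: the share of observed ability variance not attributable to
measurement error, (Var(theta) - mean(SE^2)) / Var(theta).  Values above
0.7 suffice for population-level surveys, above 0.85 for individual
(clinical) use.

Logit abilities are rescaled to an anchored 0–100 metric — 0 at the ability
of the minimum raw score (no problems on any item), 100 at the maximum
(extreme problems on all items) — and the performance-score distribution is
partitioned into severity levels: the severe cutoff is its mean plus one
standard deviation; the mild and moderate cutoffs default to mean minus one
SD and the mean (package defaults, configurable).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PSI_POPULATION = 0.7
PSI_CLINICAL = 0.85


@dataclass
class PsiResult:
    psi: float
    band: str
    n: int


def person_separation_index(abilities) -> PsiResult:
    """PSI = (Var(theta) - mean(SE^2)) / Var(theta), floored at 0."""
    persons = abilities.persons.dropna(subset=["theta", "se"])
    if len(persons) < 2:
        raise ValueError("PSI needs >= 2 persons with ability estimates")
    var = float(persons["theta"].var(ddof=1))
    if var == 0:
        raise ValueError("PSI undefined: zero ability variance")
    mse = float((persons["se"] ** 2).mean())
    psi = max(0.0, (var - mse) / var)
    if psi > PSI_CLINICAL:
        band = "clinical-grade"
    elif psi > PSI_POPULATION:
        band = "population-sufficient"
    else:
        band = "insufficient"
    return PsiResult(psi=psi, band=band, n=len(persons))


@dataclass
class ScaledScore:
    """Per-person 0–100 scores with the logit anchors used."""

    scores: pd.Series
    theta_min: float
    theta_max: float

    def rescale(self, theta):
        s = 100.0 * (np.asarray(theta, dtype=float) - self.theta_min) / (
            self.theta_max - self.theta_min)
        return np.clip(s, 0.0, 100.0)


def rescale_0_100(abilities) -> ScaledScore:
    """Map logit abilities to [0, 100], anchored at the abilities of raw
    score 0 and the maximum raw score on the complete item set."""
    st = abilities.score_table
    theta_min = float(st.loc[st["raw_score"].idxmin(), "theta"])
    theta_max = float(st.loc[st["raw_score"].idxmax(), "theta"])
    if not (np.isfinite(theta_min) and np.isfinite(theta_max)):
        raise ValueError("anchor abilities must be finite (use WLE or "
                         "extreme-score adjustment)")
    if theta_max <= theta_min:
        raise ValueError("theta_max must exceed theta_min")
    sc = 100.0 * (abilities.persons["theta"] - theta_min) / (theta_max - theta_min)
    return ScaledScore(scores=sc.clip(0.0, 100.0), theta_min=theta_min,
                       theta_max=theta_max)


@dataclass
class SeverityCutoffs:
    """Cutoffs on the 0–100 scale partitioning none/mild/moderate/severe."""

    mild: float
    moderate: float
    severe: float
    rule: str
    labels: pd.Series = None
    percentages: dict = field(default_factory=dict)


def severity_cutoffs(scores: ScaledScore, rule_config=None) -> SeverityCutoffs:
    """Severity levels from the score distribution.

    severe = mean + 1 SD (the cross-country disaggregation rule); mild and
    moderate default to mean - 1 SD and the mean, overridable via
    ``rule_config={'mild': ..., 'moderate': ...}``.
    """
    s = scores.scores.dropna()
    if len(s) < 2:
        raise ValueError("need >= 2 scored persons")
    mu, sd = float(s.mean()), float(s.std(ddof=1))
    if sd == 0:
        raise ValueError("degenerate score distribution (zero variance)")
    cfg = rule_config or {}
    severe = float(cfg.get("severe", mu + sd))
    moderate = float(cfg.get("moderate", mu))
    mild = float(cfg.get("mild", mu - sd))
    if not mild < moderate < severe:
        raise ValueError("cutoffs must be strictly increasing")
    bins = [-np.inf, mild, moderate, severe, np.inf]
    names = ["none", "mild", "moderate", "severe"]
    labels = pd.cut(scores.scores, bins=bins, labels=names, right=True)
    pct = (labels.value_counts(normalize=True).reindex(names).fillna(0.0)
           * 100.0).to_dict()
    return SeverityCutoffs(mild=mild, moderate=moderate, severe=severe,
                           rule="severe = mean + 1·SD of the score distribution",
                           labels=labels, percentages=pct)
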