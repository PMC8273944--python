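"""Synthetic Brief-MDS-style survey data with known generating parameters.

Generates person x item matrices of ordinal responses (categories 0 = no
problem .. 4 = extreme problem) under the partial credit model, so that every
downstream stage — calibration, diagnostics, DIF, reliability, scoring — can
be exercised against a known truth.  Supports group DIF (uniform threshold
shifts or non-uniform discrimination multipliers for a focal group), locally
dependent item pairs, and MCAR missingness.

The default population is deliberately off-target, abilities ~ N(-1.5, 1.3)
logits against item locations near zero: in general-population disability
surveys most respondents report no problems, producing the strongly
right-skewed category distributions these scales show in the field.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pcm import category_probabilities

#: Brief MDS item inventories: 12 performance items (module 4000) and
#: 11 capacity items (module 5000), five ordered categories each.
PERFORMANCE_ITEMS = [f"B40{i:02d}" for i in range(1, 13)]
CAPACITY_ITEMS = [f"B50{i:02d}" for i in range(2, 13)]

AGE_BANDS = ((17.5, 39.5), (39.5, 59.5), (59.5, 100.0))
AGE_BAND_LABELS = ["(17.5, 39.5]", "(39.5, 59.5]", "(59.5, 100.0]"]


@dataclass
class TrueItemSpec:
    """Generating parameters for one item.

    thresholds: delta_1..delta_m in logits (m = category count - 1).
    dif_shift: logits added for the focal group — a constant threshold shift
        for uniform DIF, or a slope multiplier offset (discrimination
        1 + dif_shift for the focal group) for non-uniform DIF.
    ld_partner: label of an item this one will copy with the configured
        local-dependence strength.
    """

    item_id: str
    thresholds: tuple
    dif_shift: float = 0.0
    dif_type: str = "uniform"
    ld_partner: str | None = None

    def __post_init__(self):
        self.thresholds = tuple(float(t) for t in self.thresholds)
        if len(self.thresholds) == 0:
            raise ValueError(f"item {self.item_id!r}: thresholds must be non-empty")
        if not np.all(np.isfinite(self.thresholds)) or not np.isfinite(self.dif_shift):
            raise ValueError(f"item {self.item_id!r}: non-finite parameters")
        if self.dif_type not in ("uniform", "non-uniform"):
            raise ValueError("dif_type must be 'uniform' or 'non-uniform'")

    @property
    def n_categories(self):
        return len(self.thresholds) + 1


@dataclass
class PersonSpec:
    """Population to draw: size, latent ability distribution (logits) and
    grouping covariates (gender, three adult age bands)."""

    n: int
    ability_mean: float = -1.5
    ability_sd: float = 1.3
    female_share: float = 0.5

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.ability_sd <= 0:
            raise ValueError("ability_sd must be positive")


@dataclass
class SimulationConfig:
    """Seeded simulation settings.  Identical configs give identical output."""

    seed: int = 0
    missing_rate: float = 0.0
    ld_strength: float = 0.0
    focal_level: str = "female"

    def __post_init__(self):
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if not 0 <= self.ld_strength <= 1:
            raise ValueError("ld_strength must be in [0, 1]")


def draw_persons(persons: PersonSpec, seed: int) -> pd.DataFrame:
    """Draw abilities and covariates; returns one row per person."""
    rng = np.random.default_rng(seed)
    n = persons.n
    theta = rng.normal(persons.ability_mean, persons.ability_sd, size=n)
    gender = np.where(rng.random(n) < persons.female_share, "female", "male")
    band_idx = rng.integers(0, 3, size=n)
    lo = np.array([b[0] for b in AGE_BANDS])[band_idx]
    hi = np.array([b[1] for b in AGE_BANDS])[band_idx]
    age = lo + (hi - lo) * rng.random(n)
    return pd.DataFrame({
        "ability": theta,
        "gender": gender,
        "age": np.round(age, 1),
        "age_group": np.array(AGE_BAND_LABELS)[band_idx],
    }, index=pd.RangeIndex(n, name="person"))


def _item_probabilities(item: TrueItemSpec, theta: np.ndarray, focal: np.ndarray):
    """Category probabilities per person, honouring the item's DIF spec."""
    delta = np.asarray(item.thresholds)
    if item.dif_shift == 0.0 or not focal.any():
        return category_probabilities(delta, theta)
    p = np.empty((theta.size, delta.size + 1))
    ref = ~focal
    if ref.any():
        p[ref] = category_probabilities(delta, theta[ref])
    if item.dif_type == "uniform":
        p[focal] = category_probabilities(delta + item.dif_shift, theta[focal])
    else:
        # group-specific discrimination a on (theta - delta): equivalent to
        # evaluating the PCM at (a*theta, a*delta)
        a = 1.0 + item.dif_shift
        p[focal] = category_probabilities(a * delta, a * theta[focal])
    return p


def generate_pcm_responses(items, persons, config: SimulationConfig) -> pd.DataFrame:
    """Draw a response matrix from the PCM at each person's ability.

    ``persons`` is either a :class:`PersonSpec` (drawn internally from
    ``config.seed``) or a pre-drawn covariates frame from
    :func:`draw_persons` (columns ability, gender, age_group), so one person
    draw can feed several scales.
    """
    items = list(items)
    if len({it.item_id for it in items}) != len(items):
        raise ValueError("duplicate item_id in item specs")
    if isinstance(persons, PersonSpec):
        persons = draw_persons(persons, config.seed)
    theta = persons["ability"].to_numpy(dtype=float)
    focal = persons["gender"].to_numpy() == config.focal_level
    rng = np.random.default_rng([config.seed, 1])

    cols = {}
    for item in items:
        p = _item_probabilities(item, theta, focal)
        u = rng.random(theta.size)
        cols[item.item_id] = (u[:, None] > np.cumsum(p, axis=1)).sum(axis=1)
    df = pd.DataFrame(cols, index=persons.index, dtype=float)

    for j, item in enumerate(items):
        if item.ld_partner is not None and config.ld_strength > 0:
            sub = int(np.random.default_rng([config.seed, 2, j]).integers(2**31))
            df = inject_local_dependence(
                df, (item.ld_partner, item.item_id), config.ld_strength, seed=sub)

    if config.missing_rate > 0:
        mask = np.random.default_rng([config.seed, 3]).random(df.shape) < config.missing_rate
        df = df.mask(mask)
    return df


def inject_local_dependence(matrix, pair, strength, seed):
    """Make the second item of ``pair`` copy the first with given probability.

    With probability ``strength`` a person's response on the second item is
    replaced by their response on the first (clipped to the second item's
    category range); the first item's marginal distribution is untouched.
    """
    if not 0 <= strength <= 1:
        raise ValueError("strength must be in [0, 1]")
    src, dst = pair
    df = pd.DataFrame(matrix).copy()
    for lab in (src, dst):
        if lab not in df.columns:
            raise KeyError(f"unknown item label {lab!r}")
    if strength == 0:
        return df
    rng = np.random.default_rng(seed)
    copy = rng.random(len(df)) < strength
    dst_max = df[dst].max()
    both = copy & df[src].notna().to_numpy() & df[dst].notna().to_numpy()
    df.loc[both, dst] = np.minimum(df.loc[both, src], dst_max)
    return df


def default_item_bank(scale="capacity"):
    """Default generating item banks for the two Brief MDS scales.

    Five ordered categories per item; locations follow the published Chile
    calibration spread.  Threshold offsets around each location are evenly
    spaced but asymmetric (-1.0 .. +2.0): with the off-target default
    population this keeps category 0 the majority response overall while
    still making the top categories reachable, matching the strongly
    right-skewed marginals of general-population disability surveys.
    """
    if scale == "capacity":
        labels = CAPACITY_ITEMS
        locations = [-1.33, 0.88, 0.06, 0.51, 1.75, -0.08, 0.55, 0.47, -0.64, 1.55, -1.18]
    elif scale == "performance":
        labels = PERFORMANCE_ITEMS
        locations = [-0.48, -0.45, 0.59, 0.62, 0.53, -0.46, 0.59, 0.37, 0.15, 0.08, 1.2, -0.04]
    else:
        raise ValueError("scale must be 'capacity' or 'performance'")
    offsets = np.array([-1.0, 0.0, 1.0, 2.0])
    return [TrueItemSpec(lab, tuple(loc + offsets)) for lab, loc in zip(labels, locations)]


def save_item_bank(items, path):
    """Write generating item specs to YAML (the truth file of a simulation)."""
    import yaml
    payload = [{
        "item_id": it.item_id,
        "thresholds": [float(t) for t in it.thresholds],
        "dif_shift": float(it.dif_shift),
        "dif_type": it.dif_type,
        "ld_partner": it.ld_partner,
    } for it in items]
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def load_item_bank(path):
    import yaml
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return [TrueItemSpec(d["item_id"], tuple(d["thresholds"]),
                         dif_shift=d.get("dif_shift", 0.0),
                         dif_type=d.get("dif_type", "uniform"),
                         ld_partner=d.get("ld_partner"))
            for d in payload]


def generate_brief_mds_dataset(config: SimulationConfig, n_persons=1000,
                               persons: PersonSpec | None = None,
                               capacity_items=None, performance_items=None):
    """Generate a full Brief-MDS-like dataset.

    Returns ``(capacity, performance, covariates)``: an 11-item capacity
    matrix, a 12-item performance matrix (5 categories each, right-skewed
    marginals from the off-target default population) and a covariates frame
    with gender, age and age group.
    """
    spec = persons or PersonSpec(n=n_persons)
    cov = draw_persons(spec, config.seed)
    cap_items = capacity_items or default_item_bank("capacity")
    perf_items = performance_items or default_item_bank("performance")
    cap = generate_pcm_responses(cap_items, cov, config)
    # distinct stream for the second scale, still fully seed-determined
    perf_cfg = SimulationConfig(seed=config.seed + 104729,
                                missing_rate=config.missing_rate,
                                ld_strength=config.ld_strength,
                                focal_level=config.focal_level)
    perf = generate_pcm_responses(perf_items, cov, perf_cfg)
    return cap, perf, cov[["gender", "age", "age_group"]]
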