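import numpy as np
import pytest

from briefmds.pcm import fit_pcm
from briefmds.simulate import (
    PersonSpec,
    SimulationConfig,
    TrueItemSpec,
    draw_persons,
    generate_pcm_responses,
)


def small_item_bank(n_items=6, n_categories=5, spread=1.8, location_step=0.3):
    """Ordered-threshold generating items centred near zero."""
    offsets = np.linspace(-spread, spread, n_categories - 1)
    return [
        TrueItemSpec(f"i{k}", tuple(offsets + location_step * (k - (n_items - 1) / 2)))
        for k in range(n_items)
    ]


@pytest.fixture(scope="session")
def conforming_data():
    """On-target PCM-conforming responses: 6 items, n = 2000, theta ~ N(0,1)."""
    items = small_item_bank()
    persons = draw_persons(PersonSpec(n=2000, ability_mean=0.0, ability_sd=1.0), 42)
    X = generate_pcm_responses(items, persons, SimulationConfig(seed=42))
    return items, persons, X


@pytest.fixture(scope="session")
def calibrated(conforming_data):
    """Fitted model + abilities for the conforming dataset (shared; computing
    this once keeps the suite fast)."""
    items, persons, X = conforming_data
    model = fit_pcm(X)
    abilities = model.estimate_abilities(X)
    return items, persons, X, model, abilities
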