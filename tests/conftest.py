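import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import seedlink as sl

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_community() -> sl.Community:
    """The default 50-plant x 60-bird synthetic community (fixed seed)."""
    return sl.generate_community(sl.TraitGenConfig(seed=1))


@pytest.fixture(scope="session")
def default_matrix(default_community) -> sl.InteractionMatrix:
    return sl.interaction_probabilities(default_community, sl.NicheConfig(s=5.0))


@pytest.fixture()
def tiny_community() -> sl.Community:
    """Hand-built 2-plant x 2-bird community with clean round numbers.

    Heights {5, 10} and wing pointedness {20, 30} z-score to -1/+1, so each
    plant matches exactly one bird on both trait axes.
    """
    plants = pd.DataFrame(
        {
            "id": ["p1", "p2"],
            "fruit_diameter_mm": [10.0, 20.0],
            "fruit_mass_g": [0.524, 4.192],
            "plant_height_m": [5.0, 10.0],
            "fruit_abundance": [2.0, 1.0],
        }
    )
    birds = pd.DataFrame(
        {
            "id": ["b1", "b2"],
            "gape_width_mm": [10.0, 20.0],
            "wing_pointedness": [20.0, 30.0],
            "body_mass_g": [10.0, 80.0],
            "abundance": [3.0, 1.0],
        }
    )
    return sl.Community(plants, birds)
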