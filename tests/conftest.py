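import numpy as np
import pandas as pd
import pytest

import flocknbda as fn
from flocknbda.networks import FollowingNetwork


@pytest.fixture(scope="session")
def small_scenario() -> fn.SyntheticScenario:
    return fn.SyntheticScenario(
        n_flocks=3, flock_size=6, n_informed_per_flock=2,
        beta_true={"sex": 0.4}, seed=42,
    )


@pytest.fixture(scope="session")
def small_dataset(small_scenario):
    return fn.generate_dataset(small_scenario)


@pytest.fixture(scope="session")
def default_dataset():
    """One full-size synthetic dataset (10 flocks x 10 birds)."""
    return fn.generate_dataset(fn.SyntheticScenario(beta_true={"sex": 0.4}, seed=7))

from oracles import enumeration_negloglik, random_instance  # noqa: F401,E402
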