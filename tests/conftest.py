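import numpy as np
import pandas as pd
import pytest

from ecozone.niche import ResourceStates
from ecozone.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """The default planted survey (26 sites, zones 5/6/15, seed 1)."""
    return generate_dataset(SyntheticConfig(seed=1))


@pytest.fixture
def toy_community():
    """Two sites, two taxa: the hand-worked dominance example."""
    return pd.DataFrame({"A": [10.0, 10.0], "B": [0.0, 20.0]}, index=["s1", "s2"])


def make_states(site_states: dict[str, list[int]], R: int = 5) -> ResourceStates:
    """Build a ResourceStates object directly from per-gradient state lists."""
    df = pd.DataFrame(site_states)
    df.index = [f"s{i+1}" for i in range(len(df))]
    return ResourceStates(edges={g: np.array([]) for g in df}, states=df, R=R)


def random_profile_inputs(rng: np.random.Generator, max_species: int = 12,
                          n_sites: int = 10, R: int = 5):
    """A random community matrix and state assignment for oracle checks."""
    n_sp = int(rng.integers(2, max_species + 1))
    abund = rng.integers(0, 50, size=(n_sites, n_sp)).astype(float)
    abund[rng.random((n_sites, n_sp)) < 0.3] = 0.0
    abund[0, :] += 1.0  # guarantee every species occurs somewhere
    community = pd.DataFrame(
        abund, index=[f"s{i+1}" for i in range(n_sites)],
        columns=[f"sp{i+1}" for i in range(n_sp)],
    )
    states = make_states(
        {"g1": list(rng.integers(1, R + 1, n_sites)),
         "g2": list(rng.integers(1, R + 1, n_sites))}, R=R
    )
    return community, states
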