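import numpy as np
import pandas as pd
import pytest

from isofate.model import TracerExperiment
from isofate.simulate import get_scenario, simulate_bottles


@pytest.fixture(scope="session")
def humic_leaf_results():
    """One fitted humic-water leaf experiment (fixed seed)."""
    sim = simulate_bottles(get_scenario("humic_leaf"), seed=11)
    return TracerExperiment.from_simulation(sim).fit()


@pytest.fixture(scope="session")
def two_cluster_dissimilarity():
    """Bray-Curtis matrix of two well-separated 4-sample clusters."""
    from isofate.community import bray_curtis

    rng = np.random.default_rng(3)
    a = np.abs(rng.normal(10, 1, size=(4, 6)))
    b = np.abs(rng.normal(10, 1, size=(4, 6)))
    b[:, :3] += 40
    x = np.vstack([a, b])
    return bray_curtis(x), ["a"] * 4 + ["b"] * 4
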