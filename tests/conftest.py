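import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tfatlas.simulate import SimulationConfig, simulate_species_timetree
from tfatlas.treeio import GeneTree, TimeTree

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def stree3() -> TimeTree:
    """((A,B),C) with node ages 0/1/2 (My)."""
    return TimeTree.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def stree16() -> TimeTree:
    """The 16-taxon, 170-My fixture tree used across recovery tests."""
    return simulate_species_timetree(16, 170.0, seed=1)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def gtree(newick: str) -> GeneTree:
    return GeneTree.from_newick(newick)
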