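import numpy as np
import pytest

from midra.config import RunConfig
from midra.fixtures import FixtureSpec, generate_associations, generate_hierarchy
from midra.gcn import TrainConfig
from midra.semantics import DiseaseHierarchy, combined_ssd


@pytest.fixture(scope="session")
def spec():
    return FixtureSpec()  # the standard desk-scale study conditions


@pytest.fixture(scope="session")
def assoc_fixture(spec):
    return generate_associations(spec)


@pytest.fixture(scope="session")
def hierarchy(spec):
    return generate_hierarchy(spec)


@pytest.fixture(scope="session")
def ssd(hierarchy, assoc_fixture):
    return combined_ssd(hierarchy, assoc_fixture.assoc.disease_names)


@pytest.fixture
def fast_config():
    """A short-epoch training config for unit-level end-to-end checks."""
    return RunConfig(train=TrainConfig(epochs=60, seed=3))


def random_dag(rng: np.random.Generator, n_nodes: int) -> DiseaseHierarchy:
    """Random acyclic hierarchy on <= n_nodes nodes: each node may take 1-2
    parents among earlier nodes (node 0 is the root)."""
    names = [f"n{i}" for i in range(n_nodes)]
    parents: dict[str, set[str]] = {names[0]: set()}
    for i in range(1, n_nodes):
        k = 1 + (rng.random() < 0.3)
        ps = rng.choice(i, size=min(k, i), replace=False)
        parents[names[i]] = {names[int(p)] for p in ps}
    return DiseaseHierarchy(parents)
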