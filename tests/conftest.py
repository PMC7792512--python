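import numpy as np
import pytest

import habnet as hn


@pytest.fixture
def toy22() -> hn.AbundanceMatrix:
    """2 sites x 2 species, counts [[1,0],[0,2]]."""
    return hn.AbundanceMatrix(
        site_ids=("A", "B"),
        habitat_of={"A": "grass", "B": "meadow"},
        species_ids=("s1", "s2"),
        counts=np.array([[1, 0], [0, 2]]),
    )


@pytest.fixture(scope="session")
def landscape():
    """Default study-shaped synthetic landscape (44 sites x 74 species)."""
    return hn.generate_landscape(hn.LandscapeSpec(), seed=1)


@pytest.fixture(scope="session")
def bipnet(landscape) -> hn.BipartiteNetwork:
    return hn.build_bipartite(landscape[0])


@pytest.fixture(scope="session")
def uninet(bipnet) -> hn.UnipartiteNetwork:
    return hn.project_unipartite(bipnet)


def small_spec(**overrides) -> hn.LandscapeSpec:
    """A 12-site, 18-species landscape for fast sweeps."""
    kwargs = dict(
        habitats=("a", "b", "c"),
        sites_per_habitat=(4, 4, 4),
        specialists_per_habitat=4,
        n_generalists=6,
    )
    kwargs.update(overrides)
    return hn.LandscapeSpec(**kwargs)


def random_matrix(rng: np.random.Generator, max_rows=6, max_cols=6, high=6):
    """Random integer matrix without empty rows or columns."""
    n = int(rng.integers(2, max_rows + 1))
    m = int(rng.integers(2, max_cols + 1))
    for _ in range(100):
        w = rng.integers(0, high, size=(n, m))
        if (w.sum(axis=1) > 0).all() and (w.sum(axis=0) > 0).all():
            return w
    raise AssertionError("unreachable")
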