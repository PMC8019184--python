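import numpy as np
import pytest

from migconn import (
    MigrationParams,
    PairedPopulation,
    Rect,
    apply_migration,
    simulate_breeding_uniform,
)


@pytest.fixture(scope="session")
def unit_rect() -> Rect:
    return Rect(0.0, 0.0, 1.0, 1.0)


@pytest.fixture(scope="session")
def small_population() -> PairedPopulation:
    """A 500-individual population on a compact geometry, medium connectivity."""
    pop = simulate_breeding_uniform(500, Rect(0, 0, 1000, 1000), seed=11)
    return apply_migration(pop, MigrationParams(2000.0, 5.0, 1.0, seed=12))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
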