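import numpy as np
import pytest

import divermap as dm


@pytest.fixture(scope="session")
def tiny_world():
    return dm.make_fixture("tiny-4x5")


@pytest.fixture(scope="session")
def two_zone_world():
    return dm.make_fixture("two-zone-opposite-signs")


@pytest.fixture(scope="session")
def overlap_fixture():
    return dm.make_fixture("hotspot-known-overlap")


@pytest.fixture(scope="session")
def small_world():
    """A modest correlated world reused across read-only tests."""
    cfg = dm.WorldConfig(nrows=80, ncols=80, n_biomes=4, ecoregions_per_biome=4,
                         rho=0.8, autocorr_length=2.0, noise_cv=0.2, seed=11)
    return dm.make_world(cfg)


@pytest.fixture(scope="session")
def harmonized_small(small_world):
    b = small_world
    pairs = {}
    for guild in b.config.fungal_guilds:
        pairs[f"plant-{guild}"] = dm.harmonize_pair(
            b.studies["plant"], b.studies[guild],
            b.uncertainty["plant"], b.uncertainty[guild],
            pair=f"plant-{guild}", zones=b.zones)
    return pairs


def full_mask(shape) -> dm.CellMask:
    return dm.CellMask(np.ones(shape, dtype=bool))
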