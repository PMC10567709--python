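"""Shared fixtures: a coarse synthetic world and its driver bundles."""

import numpy as np
import pytest

from termiteflux import (
    WorldConfig,
    EFGeneratorConfig,
    GridSpec,
    assemble_drivers,
    gen_ef_sample,
)


@pytest.fixture(scope="session")
def world() -> WorldConfig:
    """Default 5-degree world, a short baseline period."""
    return WorldConfig(year_start=2001, year_end=2005, seed=11)


@pytest.fixture(scope="session")
def drivers(world):
    """One year's aligned driver bundle on the coarse grid."""
    return assemble_drivers(world, 2001)


@pytest.fixture(scope="session")
def ef_dataset():
    return gen_ef_sample(EFGeneratorConfig(n=5000, seed=19))


@pytest.fixture(scope="session")
def coarse_spec() -> GridSpec:
    return GridSpec.coarse()
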