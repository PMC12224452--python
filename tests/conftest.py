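"""Shared fixtures: small meshes, masks and searchlights reused across tests."""

import numpy as np
import pytest

from crossgen.geometry import (
    assign_regions,
    build_icosphere,
    default_region_spec,
    make_language_mask,
    searchlight_neighborhoods,
    DEFAULT_REGIONS,
)


@pytest.fixture(scope="session")
def mesh0():
    mesh = build_icosphere(0)
    return assign_regions(mesh, default_region_spec(mesh))


@pytest.fixture(scope="session")
def mesh1():
    mesh = build_icosphere(1)
    return assign_regions(mesh, default_region_spec(mesh))


@pytest.fixture(scope="session")
def mesh2():
    mesh = build_icosphere(2)
    return assign_regions(mesh, default_region_spec(mesh))


@pytest.fixture(scope="session")
def mask1(mesh1):
    return make_language_mask(mesh1, list(DEFAULT_REGIONS))


@pytest.fixture(scope="session")
def mask2(mesh2):
    return make_language_mask(mesh2, list(DEFAULT_REGIONS))


@pytest.fixture(scope="session")
def nbr1(mesh1, mask1):
    return searchlight_neighborhoods(mesh1, mask1, k=10)


@pytest.fixture()
def rng():
    # fresh, fixed-seed generator per test: deterministic and order-independent
    return np.random.default_rng(20240917)
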