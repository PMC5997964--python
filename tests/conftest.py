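"""Shared fixtures: a small synthetic census and the pipeline artifacts
derived from it, built once per session."""

from __future__ import annotations

import numpy as np
import pytest

from popsynth.model import HouseholdSynthesis
from popsynth.synthetic_census import (
    draw_micro_sample,
    make_ground_truth,
    make_zone_geometries,
    simulate_full_population,
)


@pytest.fixture(scope="session")
def small_gt():
    return make_ground_truth("small", seed=1)


@pytest.fixture(scope="session")
def small_fixture(small_gt):
    """Full population (5 zones x 2000 households), exact control table,
    and a 10% micro-sample."""
    pop, controls = simulate_full_population(small_gt, zones=5, households_per_zone=2000)
    records = draw_micro_sample(pop, 0.1, np.random.default_rng(11))
    return {"population": pop, "controls": controls, "records": records}


@pytest.fixture(scope="session")
def fitted(small_fixture):
    model = HouseholdSynthesis(small_fixture["records"])
    return model.fit()


@pytest.fixture(scope="session")
def small_pool(fitted):
    return fitted.generate_pool(pool_size=8000, seed=21)


@pytest.fixture(scope="session")
def zone_weights(fitted, small_pool, small_fixture):
    return fitted.calibrate(small_pool, small_fixture["controls"])


@pytest.fixture(scope="session")
def geometries(small_fixture):
    return make_zone_geometries(small_fixture["controls"].zones)


@pytest.fixture(scope="session")
def population(fitted, small_pool, zone_weights, small_fixture, geometries):
    return fitted.assemble(
        small_pool, zone_weights, small_fixture["controls"], geometries, seed=5
    )
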