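"""Shared fixtures: packaged scenarios and fitted forests.

Session scope keeps the expensive surrogate-forest fits to one per
test run; all fixtures are seeded and deterministic.
"""

import pytest

from nmrforest.forest import SurrogateForest, default_params
from nmrforest.simulate import truffle_like_scenario, two_group_scenario


@pytest.fixture(scope="session")
def truffle_fixture():
    """Packaged truffle-like data set (seed 1): (table, truth)."""
    return truffle_like_scenario(seed=1)


@pytest.fixture(scope="session")
def truffle_forest(truffle_fixture):
    """Surrogate forest fitted on the truffle-like table (ntree=500)."""
    table, _ = truffle_fixture
    params = default_params(table.n_buckets, table.class_counts(), ntree=500, seed=1)
    return SurrogateForest.from_bucket_table(table, params).fit(seed=1)


@pytest.fixture(scope="session")
def two_group_fixture():
    """Small two-metabolite-group scenario: (table, truth, groups)."""
    return two_group_scenario(seed=0)


@pytest.fixture(scope="session")
def two_group_forest(two_group_fixture):
    table, _, _ = two_group_fixture
    params = default_params(table.n_buckets, table.class_counts(), ntree=300, seed=0)
    return SurrogateForest.from_bucket_table(table, params).fit(seed=0)
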