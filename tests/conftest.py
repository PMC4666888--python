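"""Shared fixtures: base-case parameters, life table, and full-size runs.

The full base-case and scenario runs are session-scoped so the acceptance
tests share one simulation (8 strategies x 100,000 patients, common random
numbers, seed fixed at the package default of 0).
"""

import numpy as np
import pytest

import odxcea as ox

FULL_N = 100_000
SEED = 0


@pytest.fixture(scope="session")
def params() -> ox.ParameterSet:
    return ox.default_parameters()


@pytest.fixture(scope="session")
def life_table() -> ox.LifeTable:
    return ox.default_life_table()


@pytest.fixture(scope="session")
def base_results(params, life_table):
    return ox.run_all_strategies(params, life_table, n=FULL_N, seed=SEED)


@pytest.fixture(scope="session")
def base_by_name(base_results):
    return {r.strategy.name: r for r in base_results}


@pytest.fixture(scope="session")
def t2_results(params, life_table):
    return ox.run_all_strategies(
        params.with_pattern("T2"), life_table, n=FULL_N, seed=SEED
    )


class FixedUniforms(np.random.Generator):
    """A stand-in RNG that returns one prescribed column of uniforms.

    Stream order: group, chemo, visit, cause, fatal, recurrence,
    other-cause death, post-recurrence death.
    """

    def __init__(self, values):
        super().__init__(np.random.PCG64(0))
        self._values = np.asarray(values, dtype=float).reshape(-1, 1)

    def random(self, size=None):  # noqa: A003 - mirrors Generator API
        assert size == self._values.shape
        return self._values


@pytest.fixture
def fixed_uniforms():
    return FixedUniforms
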