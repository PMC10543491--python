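"""Shared fixtures: the reference baseline and sampled parameter regimes."""

import numpy as np
import pytest

from fraudgame import (
    GameParameters,
    ScenarioSpec,
    baseline_params,
    sample_scenarios,
)


@pytest.fixture(scope="session")
def baseline() -> GameParameters:
    return baseline_params()


def _case_samples(case: str, seed: int, n: int) -> list[GameParameters]:
    return [s.params for s in sample_scenarios(ScenarioSpec(case=case, seed=seed), n)]


@pytest.fixture(scope="session")
def case1_samples() -> list[GameParameters]:
    return _case_samples("case1", seed=11, n=200)


@pytest.fixture(scope="session")
def case2_samples() -> list[GameParameters]:
    return _case_samples("case2", seed=22, n=200)


@pytest.fixture(scope="session")
def case3_samples() -> list[GameParameters]:
    return _case_samples("case3", seed=33, n=200)


@pytest.fixture(scope="session")
def any_samples() -> list[GameParameters]:
    """Unconstrained random parameter sets (all regimes mixed)."""
    return _case_samples("any", seed=44, n=200)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
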