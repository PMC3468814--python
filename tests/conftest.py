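import numpy as np
import pytest

from rewardgrid import ExperimentSpec, FoodType, LearnerParams, SimulationConfig


@pytest.fixture
def food_h() -> FoodType:
    return FoodType("H", 0.9)


@pytest.fixture
def food_l() -> FoodType:
    return FoodType("L", 0.6)


@pytest.fixture
def base_params() -> LearnerParams:
    return LearnerParams(alpha=0.4)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2027)


def small_spec(scenario: str, seed: int = 11, **kw) -> ExperimentSpec:
    """A scaled-down experiment spec for fast unit tests."""
    cfg = dict(
        scenario=scenario, width=24, height=24, n_agents=48,
        max_steps=2000, seed=seed,
    )
    cfg.update(kw)
    n_replicates = cfg.pop("n_replicates", 3)
    ttl = cfg.pop("time_to_learn_tol", 0.01)
    return ExperimentSpec(
        name=scenario, n_replicates=n_replicates,
        config=SimulationConfig(**cfg), time_to_learn_tol=ttl,
    )
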