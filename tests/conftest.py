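import numpy as np
import pytest

from rotometry import (
    ModelSpec,
    SimulationPlan,
    extract_feature_table,
    fit,
    simulate,
    split,
)


@pytest.fixture(scope="session")
def default_features():
    """Feature table for the default study-design simulation (seed 42)."""
    return extract_feature_table(simulate(SimulationPlan(seed=42)))


@pytest.fixture(scope="session")
def default_split(default_features):
    """Frame-level 80/20 split with seed 7."""
    return split(default_features, fraction_test=0.2, seed=7, unit="frame")


@pytest.fixture(scope="session")
def gbt_model(default_split):
    return fit(ModelSpec(algorithm="gradient_boosted_trees", seed=0), default_split.train)


@pytest.fixture(scope="session")
def ols_model(default_split):
    return fit(ModelSpec(algorithm="ordinary_least_squares", seed=0), default_split.train)


@pytest.fixture(scope="session")
def tiny_plan():
    """A seconds-scale plan for plumbing tests."""
    return SimulationPlan(
        n_subjects=2,
        angles_deg=(-40.0, 0.0, 40.0),
        frames_per_clip=8,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_table(tiny_plan):
    return simulate(tiny_plan)


@pytest.fixture(scope="session")
def tiny_features(tiny_table):
    return extract_feature_table(tiny_table)
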