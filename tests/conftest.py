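"""Shared fixtures: parameter sets and (expensive) reference simulations."""

import numpy as np
import pytest

from gravirod import (
    GrowthParams,
    MechanicalParams,
    simulate,
    straight_rod,
)


@pytest.fixture(scope="session")
def default_mp() -> MechanicalParams:
    return MechanicalParams()


@pytest.fixture(scope="session")
def wt_gp() -> GrowthParams:
    """Wild-type-like growth parameters (S = 1.6, G = 1)."""
    return GrowthParams()


@pytest.fixture(scope="session")
def mut_gp() -> GrowthParams:
    """Mutant-like: gravitropic sensitivity halved, all else equal."""
    return GrowthParams(gravitropic_sensitivity=1.0e-3)


@pytest.fixture(scope="session")
def wt_traj(default_mp, wt_gp):
    """Full 140-min wild-type-like run on the default 41-vertex rod."""
    return simulate(straight_rod(40.0, 41), default_mp, wt_gp)


@pytest.fixture(scope="session")
def mut_traj(default_mp, mut_gp):
    return simulate(straight_rod(40.0, 41), default_mp, mut_gp)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def soft_mp() -> MechanicalParams:
    """Small, softly-scaled parameter set for fast unit-level relaxations."""
    return MechanicalParams(
        stretch_stiffness=200.0,
        bending_modulus=20.0,
        linear_density=0.05,
        gravity=1.0,
        force_tol=1e-8,
    )
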