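"""Shared fixtures: small deterministic networks and parameter sets."""

import numpy as np
import pytest

from fibernet import (
    BoxSpec,
    CrosslinkerParams,
    EquilibriumCriterion,
    FiberSpec,
    build_network,
    generate_fibers,
    place_crosslinkers,
)
from fibernet.fixtures import MINI_BOX, MINI_FIBER, make_fixture


@pytest.fixture(scope="session")
def fiber_spec():
    return FiberSpec()


@pytest.fixture(scope="session")
def box():
    return BoxSpec()


@pytest.fixture(scope="session")
def xl_best_fit():
    """Best-fit crosslinker parameters from the shear calibration."""
    return CrosslinkerParams()


@pytest.fixture(scope="session")
def mini_box():
    return MINI_BOX


@pytest.fixture(scope="session")
def mini_fiber():
    return MINI_FIBER


@pytest.fixture(scope="session")
def mini_xl():
    return CrosslinkerParams(
        strength=400e3, density_multiplier=8.0, max_binding_distance=20.0
    )


@pytest.fixture
def mini_network(mini_box, mini_fiber, mini_xl):
    """Seeded ~20-fiber network, small enough for exhaustive checks."""
    state = generate_fibers(20, mini_box, mini_fiber, "random", seed=7)
    return place_crosslinkers(state, mini_xl, mini_fiber, seed=8)


@pytest.fixture
def dense_network(mini_box):
    """50-fiber, 12N network: rigid enough for a well-defined minimum."""
    fiber = FiberSpec(length=30.0)
    xl = CrosslinkerParams(
        strength=400e3, density_multiplier=12.0, max_binding_distance=20.0
    )
    state = generate_fibers(50, mini_box, fiber, "random", seed=21)
    return place_crosslinkers(state, xl, fiber, seed=22)


@pytest.fixture
def two_fiber():
    return make_fixture("two_fiber")


@pytest.fixture
def ladder():
    return make_fixture("ladder")


@pytest.fixture(scope="session")
def loose_criterion():
    """Criterion for cheap tests that do not probe convergence itself."""
    return EquilibriumCriterion(relative_force_tolerance=1e-4)
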