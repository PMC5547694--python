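"""Shared fixtures.

The expensive fixtures (a grown reference tissue and its event log) are
session-scoped so every test that needs a realistic tissue reuses one run.
"""

import numpy as np
import pytest

import epivertex as ev
from epivertex.growth import run_growth
from epivertex.synth import (
    four_cell_cross,
    generate_initial_tissue,
    hexagonal_patch,
    regular_hexagon,
    two_unit_squares,
)


@pytest.fixture(scope="session")
def reference_config():
    return ev.SimConfig()


@pytest.fixture(scope="session")
def reference_run(reference_config):
    """A reference-parameter growth run, 250 -> 900 cells (shared, ~3 min)."""
    rng = np.random.default_rng(2024)
    return run_growth(reference_config, n_target=900, n_initial=250, rng=rng)


@pytest.fixture(scope="session")
def small_tissue(reference_config):
    """A small relaxed tissue for cheap mesh-level tests."""
    rng = np.random.default_rng(5)
    return generate_initial_tissue(60, rng=rng, config=reference_config)


@pytest.fixture
def hexagon():
    return regular_hexagon()


@pytest.fixture
def squares():
    return two_unit_squares()


@pytest.fixture
def patch():
    return hexagonal_patch(rings=2)


@pytest.fixture
def cross():
    return four_cell_cross()
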