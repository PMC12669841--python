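"""Shared fixtures: synthetic joints and fields reused across the suite.

The expensive geometric fixtures (saddle joint, ball-and-socket, cylinder
field) are session-scoped; they are deterministic, so sharing them does
not couple tests.
"""

import numpy as np
import pytest
import trimesh

from romkit.contact import ContactConfig
from romkit.fixtures import (make_ball_and_socket, make_cylinder_obstacle,
                             make_hemisellar, make_ligament_set)


@pytest.fixture(scope="session")
def bas():
    """Concentric ball-and-socket joint plus analytic SDF oracles."""
    joint, oracles = make_ball_and_socket()
    return joint, oracles


@pytest.fixture(scope="session")
def bas_joint(bas):
    return bas[0]


@pytest.fixture(scope="session")
def saddle_joint():
    return make_hemisellar()


@pytest.fixture(scope="session")
def cylinder():
    """Analytic cylinder obstacle grid with its closed-form SDF."""
    return make_cylinder_obstacle(radius=0.5, half_extent=3.0, resolution=61)


@pytest.fixture(scope="session")
def saddle_ligaments(saddle_joint):
    return make_ligament_set(saddle_joint, n_ligaments=6, seed=0)


@pytest.fixture(scope="session")
def lean_contact_config():
    """Economical solver settings used for lattice sweeps in tests."""
    return ContactConfig(max_iter=60, n_retries=1)


@pytest.fixture(scope="session")
def icosphere():
    return trimesh.creation.icosphere(subdivisions=3, radius=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
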