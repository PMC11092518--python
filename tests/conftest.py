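"""Shared fixtures: parameter tables and one reusable desk-scale run.

The 300-s desk run is expensive (~1 min) and serves several consumers:
grid-pattern emergence, rhythm statistics (its first minute) and the
engine-level dynamical invariants.  It is session-scoped and computed
lazily on first use.
"""

from __future__ import annotations

import numpy as np
import pytest

from gridcan.engine import STELLATE, Network, SimConfig, run_simulation
from gridcan.params import load_tables
from gridcan.stimulus import synthesize_trajectory

DESK_SEED = 1
DESK_TRAJ_SEED = 3
DESK_DURATION_S = 300.0


@pytest.fixture(scope="session")
def tables():
    return load_tables()


@pytest.fixture(scope="session")
def desk_trajectory():
    return synthesize_trajectory(DESK_DURATION_S, seed=DESK_TRAJ_SEED)


@pytest.fixture(scope="session")
def desk_config():
    return SimConfig(preset="desk", seed=DESK_SEED, probes=[(STELLATE, 2, 1)])


@pytest.fixture(scope="session")
def desk_network(desk_config):
    return Network(desk_config)


@pytest.fixture(scope="session")
def desk_run(desk_config, desk_trajectory):
    """300-s default desk-preset simulation (numba backend)."""
    return run_simulation(desk_config, desk_trajectory)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
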