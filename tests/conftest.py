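"""Shared fixtures: seeded worlds and a trained homing controller.

Training the double-opponent circuit is the slowest setup step, so it is
session-scoped and reused by the homing and acceptance tests.
"""

import numpy as np
import pytest

from mbcx import homing as hm, world as wd

N_PN = 3 * 72  # skyline elevations + both rectified edge channels


@pytest.fixture(scope="session")
def homing_world():
    return wd.generate_world({"preset": "homing"}, seed=3)


@pytest.fixture(scope="session")
def learning_walk(homing_world):
    return wd.scripted_learning_walk(
        homing_world, n_loops=8, max_radius=15.0, steps_per_loop=150, seed=3
    )


@pytest.fixture(scope="session")
def trained_circuits(homing_world, learning_walk):
    circuits = hm.make_homing_circuits(n_pn=N_PN, seed=3)
    hm.train_homing(circuits, homing_world, learning_walk)
    return circuits
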