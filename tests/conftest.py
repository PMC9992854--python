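"""Shared fixtures.

The expensive fixture is ``trained_suite``: the desk-scale module chain
(S1, D, S2 and the QC regressor) trained once per session on toy anatomy
and reused by the pipeline, hierarchy and QC tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from synthbrain.suite import train_toy_suite
from synthbrain.synth import GenerationPriors
from synthbrain.toy_anatomy import make_toy_label_map

# desk-scale training configuration shared by tests and documented in the
# methods note: 6 training anatomies, 32^3 grids, a few hundred steps each
TRAIN_SHAPE = (32, 32, 32)
N_STRUCTURES = 17
SUITE_STEPS = {"s1": 800, "d": 300, "s2": 400, "r": 300}
SUITE_SEED = 11


@pytest.fixture(scope="session")
def toy_maps():
    return [make_toy_label_map(TRAIN_SHAPE, N_STRUCTURES, seed=s) for s in range(6)]


@pytest.fixture(scope="session")
def toy_map(toy_maps):
    return toy_maps[0]


@pytest.fixture(scope="session")
def priors():
    return GenerationPriors()


@pytest.fixture(scope="session")
def trained_suite(toy_maps, priors):
    """S1 -> D -> S2 -> R trained at desk scale with the frozen-upstream
    protocol (several minutes; shared across the whole session)."""
    return train_toy_suite(
        toy_maps, priors, seed=SUITE_SEED, steps=SUITE_STEPS, learning_rate=1e-3
    )


@pytest.fixture(scope="session")
def held_out_maps():
    return [make_toy_label_map(TRAIN_SHAPE, N_STRUCTURES, seed=100 + s) for s in range(20)]
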