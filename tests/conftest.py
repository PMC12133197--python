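"""Shared fixtures: synthetic populations and their compartment calls.

The expensive end-to-end runs (hundreds of 60-node SDP solves) are
session-scoped so the ensemble-level tests share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from maxcomp import (GraphParams, SolverSettings, SyntheticConfig,
                     call_population, simulate_population)

STRONG_SEED = 0


@pytest.fixture(scope="session")
def strong_config() -> SyntheticConfig:
    """The strong-signal study condition (generator defaults, K=200)."""
    return SyntheticConfig(n_cells=200, seed=STRONG_SEED)


@pytest.fixture(scope="session")
def strong_population(strong_config):
    return simulate_population(strong_config)


@pytest.fixture(scope="session")
def strong_calls(strong_config, strong_population):
    pop, _ = strong_population
    profiles, failed = call_population(
        pop, GraphParams(r_bead=strong_config.r_bead), SolverSettings(seed=0)
    )
    assert not failed
    return profiles


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
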