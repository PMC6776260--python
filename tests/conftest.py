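"""Shared fixtures: small model runs reused across test modules.

Heavy simulations are session-scoped so the suite pays for them once.
"""

from __future__ import annotations

import numpy as np
import pytest

from pcwaves import DEFAULT_MULTILEVEL, DEFAULT_TWO_LEVEL, simulate_trials


@pytest.fixture(scope="session")
def two_area_run():
    """Two-area model, 60 white-noise trials of 3 s (input-driven)."""
    run, drives = simulate_trials(DEFAULT_TWO_LEVEL, 3.0, 60, "input", seed=101)
    return run, drives


@pytest.fixture(scope="session")
def multilevel_input_run():
    """7-level model, 40 input-driven trials of 6 s."""
    run, drives = simulate_trials(DEFAULT_MULTILEVEL, 6.0, 40, "input", seed=202)
    return run, drives


@pytest.fixture(scope="session")
def multilevel_prior_run():
    """7-level model, 40 prior-driven trials of 6 s."""
    run, drives = simulate_trials(DEFAULT_MULTILEVEL, 6.0, 40, "prior", seed=303)
    return run, drives


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
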