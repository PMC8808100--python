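"""Shared fixtures.

The full 4-strategy × Q1–Q4 protocol grid takes a few minutes, so it is
computed once per session and shared between the protocol unit tests and
the acceptance checks.
"""

from __future__ import annotations

import numpy as np
import pytest

from tanctrl import ModelParameters, ProtocolSpec, preset_states, run_protocol
from tanctrl.protocol import STRATEGIES


@pytest.fixture(scope="session")
def params() -> ModelParameters:
    return ModelParameters()


@pytest.fixture(scope="session")
def presets() -> dict[str, tuple[float, float]]:
    return preset_states()


@pytest.fixture(scope="session")
def protocol_grid(params, presets):
    """All sixteen 60-day protocol runs at study-default settings."""
    grid = {}
    for strategy in STRATEGIES:
        spec = ProtocolSpec(strategy=strategy)
        for q, ci in presets.items():
            grid[(strategy, q)] = run_protocol(spec, ci, params)
    return grid


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)
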