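"""Shared fixtures: small simulated batches reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

import rejmech as rm


@pytest.fixture(scope="session")
def default_config() -> rm.SimulationConfig:
    return rm.SimulationConfig()


@pytest.fixture(scope="session")
def i27_construct() -> rm.ConstructSpec:
    return rm.get_construct("(I27)3-REJd4-(I27)2")


@pytest.fixture(scope="session")
def d12_construct() -> rm.ConstructSpec:
    return rm.get_construct("MBP-REJd1,2-I27")


@pytest.fixture(scope="session")
def i27_batch(i27_construct, default_config):
    """15 clean simulated pulls of the five-I27 / REJd4-coil construct."""
    return rm.simulate_batch(i27_construct, 15, config=default_config, master_seed=101)


@pytest.fixture(scope="session")
def i27_analyses(i27_batch, i27_construct):
    return [
        rm.classify_peaks(rm.analyze_trace(trace), i27_construct)
        for trace, _ in i27_batch
    ]


@pytest.fixture(scope="session")
def d12_batch(d12_construct, default_config):
    """20 simulated pulls of the MBP-REJd1,2-I27 fusion."""
    return rm.simulate_batch(d12_construct, 20, config=default_config, master_seed=202)


@pytest.fixture(scope="session")
def d12_analyses(d12_batch, d12_construct):
    return [
        rm.classify_peaks(rm.analyze_trace(trace), d12_construct)
        for trace, _ in d12_batch
    ]
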