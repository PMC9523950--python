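import numpy as np
import pytest

from fhmnet.engine import SimulationConfig, run_simulation
from fhmnet.network import NetworkSpec, build_connectivity


@pytest.fixture(scope="session")
def small_net():
    """A small network preserving the full model's in-degree ratio."""
    conn = build_connectivity(480, 120, 0.5, seed=11)
    return NetworkSpec(connectivity=conn)


@pytest.fixture(scope="session")
def baseline_run(small_net):
    """One blank-screen (pre-stimulus) simulation shared across tests."""
    cfg = SimulationConfig(duration=1200.0, discard=200.0, seed=21)
    return run_simulation(small_net, "pre", cfg)
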