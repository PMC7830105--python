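import numpy as np
import pytest

from phasecoupling import (CouplingTerm, OscillatorSpec, ProtocolSpec,
                           RunConfig, StageSpec, simulate_phase_pair,
                           simulate_protocol)


@pytest.fixture(scope="session")
def short_protocol():
    """A scaled-down four-stage protocol (90 s per stage) for fast tests."""
    return ProtocolSpec(stages=(
        StageSpec("A", 90.0, 0.25, 1.0, 0.0, (1.0, 2.0), 0.1),
        StageSpec("B", 90.0, 0.10, 2.0, 1.1, (1.0, 3.0), 0.1),
        StageSpec("C", 90.0, 0.10, 3.0, 0.6, (1.0, 4.0), 0.1),
        StageSpec("D", 90.0, 0.25, 1.0, 0.0, (1.0, 2.0), 0.1),
    ))


@pytest.fixture(scope="session")
def short_run(short_protocol):
    """Recording/protocol/truth for the scaled-down protocol at 20 Hz."""
    return simulate_protocol(short_protocol, fs=20.0, seed=42)


@pytest.fixture(scope="session")
def fast_config():
    """Config matched to the scaled-down protocol (30-s windows)."""
    return RunConfig(window_s=30.0, grid_size=32, edge_exclude_s=5.0,
                     detrend_window_s=20.0)


@pytest.fixture(scope="session")
def coupled_pair():
    """Canonical coupled pair: dphi1/dt = 2π·1.1 + 0.4 sin(phi2) + noise."""
    spec1 = OscillatorSpec(2 * np.pi * 1.1,
                           (CouplingTerm("sin", 0, 1, 0.4),), 0.1)
    spec2 = OscillatorSpec(2 * np.pi * 0.25, (), 0.2)
    return simulate_phase_pair(spec1, spec2, 300.0, 20.0, seed=5)
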