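"""Shared fixtures.

Simulations are deterministic, so expensive traces are built once per
session and shared across test modules.
"""

import pytest

from cprhemo import (
    ForcingProtocol,
    PlrConfig,
    build_default_parameters,
    compare_windows,
    integrate,
    tpf_sweep,
)


@pytest.fixture(scope="session")
def params():
    return build_default_parameters()


@pytest.fixture(scope="session")
def baseline_protocol():
    """Compression-only CPR, no PLR, 20 s."""
    return ForcingProtocol(plr=None, duration=20.0)


@pytest.fixture(scope="session")
def plr_protocol():
    """Compression-only CPR with PLR at 90° from 20 s, 40 s total."""
    return ForcingProtocol(plr=PlrConfig(angle_deg=90.0), duration=40.0)


@pytest.fixture(scope="session")
def baseline_trace(params, baseline_protocol):
    return integrate(params, baseline_protocol)


@pytest.fixture(scope="session")
def plr_trace(params, plr_protocol):
    return integrate(params, plr_protocol)


@pytest.fixture(scope="session")
def plr_comparison(plr_trace):
    return compare_windows(plr_trace)


@pytest.fixture(scope="session")
def tpf_sweep_result(params, plr_protocol):
    """PLR comparison at 90° across the full pump-factor grid."""
    return tpf_sweep((0.0, 0.25, 0.5, 0.75, 1.0), angle=90.0,
                     params=params, protocol=plr_protocol)
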