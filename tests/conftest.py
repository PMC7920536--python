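"""Shared fixtures: presets and session-cached synthetic recordings."""

import numpy as np
import pytest

from clampkit import get_preset, make_protocol, simulate_ipsc_train
from clampkit.pipeline import membrane_hold_protocol


@pytest.fixture(scope="session")
def fmb():
    return get_preset("FMB")


@pytest.fixture(scope="session")
def db1():
    return get_preset("DB1")


@pytest.fixture(scope="session")
def db2():
    return get_preset("DB2")


@pytest.fixture(scope="session")
def fmb_train_m100(fmb):
    """60-s FMB sIPSC train at −100 mV membrane potential, seed 1."""
    prot = membrane_hold_protocol(-100.0, 60_000.0)
    return simulate_ipsc_train(fmb, prot, seed=1)


@pytest.fixture(scope="session")
def noise_only_bundle(fmb):
    """60-s event-free recording (rate zero), default noise, seed 2."""
    prot = membrane_hold_protocol(-100.0, 60_000.0)
    return simulate_ipsc_train(fmb.replace(ipsc_rate_Hz=0.0), prot, seed=2)
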