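"""Shared fixtures: default unit classes, calibrated connectivity, and one
cached full-size noise-driven simulation reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

import spiketransfer as st
from spiketransfer import connectivity as conn


@pytest.fixture(scope="session")
def comrade_cfg():
    return st.unit_class("Comrade")


@pytest.fixture(scope="session")
def default_weights(comrade_cfg):
    """Calibrated structured connectivity, physiologically scaled."""
    return st.build_default_weights(
        seed=1,
        delay_ei_ms=comrade_cfg.delay_ei_ms,
        delay_out_ms=comrade_cfg.delay_out_ms,
    )


@pytest.fixture(scope="session")
def comrade_trial(comrade_cfg, default_weights):
    """One standard 2 s Comrade LIF run: (trimmed inputs, trimmed vm, result)."""
    return st.simulate_trial(comrade_cfg, default_weights, noise_seed=101)


@pytest.fixture(scope="session")
def toy_weights():
    """Unscaled 5E/2I/2-channel toy weight set."""
    ff = conn.build_feedforward(5, 2, seed=0)
    rec = conn.build_structured_ei(ff, 2, seed=0)
    return conn.WeightSet(ff=ff, e_out=conn.build_decoder(ff), **rec)


def make_signal(values, dt=0.1):
    return st.SignalSet(np.asarray(values, dtype=float), dt=dt)
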