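"""Shared fixtures: synthetic signals and projected trajectories."""

import numpy as np
import pytest

from pulseattractor import (
    PulseModelParams,
    delay_embed,
    estimate_cycle_length,
    generate_pulse_train,
    project_uvw,
)
from pulseattractor.embedding import TAU_FRACTION


def pipeline_uvw(signal, T=None, T_min=0.2, T_max=2.0):
    """Embed a signal at tau = T/3, estimating T unless given."""
    if T is None:
        T = estimate_cycle_length(signal, T_min, T_max).T
    return project_uvw(delay_embed(signal, TAU_FRACTION * T))


@pytest.fixture(scope="session")
def calibration_signal():
    """Ideal periodic pulse: T = 1 s, A = 40, straight downstroke."""
    return generate_pulse_train(
        PulseModelParams(T=1.0, A=40.0, alpha=0.2, kappa=1.0), 30.0, 250.0
    )


@pytest.fixture(scope="session")
def calibration_vw(calibration_signal):
    return pipeline_uvw(calibration_signal, T=1.0)


@pytest.fixture(scope="session")
def noisy_train():
    """Stationary noisy pulse train used by several feature tests."""
    return generate_pulse_train(
        PulseModelParams(T=1.0, A=40.0, noise_sd=0.8, seed=11), 30.0, 250.0
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
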