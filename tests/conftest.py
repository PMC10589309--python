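"""Shared fixtures: expensive simulation products built once per session."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import speckle_precision as sp
from speckle_precision.experiments import ExperimentConfig, build_temporal_stream

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

SEED = 20260


@pytest.fixture(scope="session")
def fast_stack_fwhm5():
    """2000 independent fully developed frames at speckle FWHM 5 px."""
    return sp.fast_speckle((250, 250), 5.0, 2000, beta=1.0, seed=SEED)


@pytest.fixture(scope="session")
def temporal_config():
    return ExperimentConfig(
        seed=SEED,
        n_particles=300,
        temporal_frames=10000,
        temporal_size=64,
        tau_c=20.0,
        dt=2.0,
        temporal_fwhm=2.0,
    )


@pytest.fixture(scope="session")
def ordered_system(temporal_config):
    """Calibrated ordered-motion particle system (FWHM 2 px, tau_c 20 us)."""
    system, stream = build_temporal_stream(temporal_config)
    return system, stream


@pytest.fixture(scope="session")
def small_cloud():
    return sp.ParticleCloud.uniform_random(n_particles=200, seed=SEED)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(SEED)
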