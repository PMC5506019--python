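"""Shared fixtures and deterministic hypothesis configuration."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from brainheart import synth

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def atlas_small():
    """12 x 12 x 6 grid: 32 candidate 3^3 cells, 5 networks + WM + CSF."""
    return synth.make_network_atlas((12, 12, 6), n_networks=5, seed=3)


@pytest.fixture(scope="session")
def atlas_default():
    return synth.make_network_atlas((16, 16, 8), n_networks=5, seed=0)


@pytest.fixture(scope="session")
def clean_spec():
    """Noise-free spec: identical sources within a network, no leakage."""
    return synth.CouplingSpec(noise_sd=0.0, confound_leak=0.0, random_seed=11)


@pytest.fixture(scope="session")
def session_gratitude(atlas_small):
    spec = synth.CouplingSpec(random_seed=11)
    return synth.simulate_session(atlas_small, spec, "gratitude", seed=21)


@pytest.fixture(scope="session")
def tiny_cohort(atlas_small):
    """4 subjects with images on the small grid, default effects."""
    spec = synth.CouplingSpec(random_seed=5)
    return synth.simulate_cohort(4, spec, atlas_small, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
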