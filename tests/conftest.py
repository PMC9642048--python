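import numpy as np
import pytest

from helipick import SimulationSpec, simulate_micrograph, surrogate_score_map
from helipick.presets import DEFAULT_PARTICLE_DIAMETER_A, default_picker_params


@pytest.fixture(scope="session")
def noisy_simulation():
    """One default noisy good-phenotype micrograph with ground truth."""
    spec = SimulationSpec(noise_sigma=0.5, rng_seed=7)
    mic, truth = simulate_micrograph(spec)
    return spec, mic, truth


@pytest.fixture(scope="session")
def noisy_score_map(noisy_simulation):
    _, mic, _ = noisy_simulation
    return surrogate_score_map(mic, DEFAULT_PARTICLE_DIAMETER_A)


@pytest.fixture(scope="session")
def default_params():
    return default_picker_params(pixel_size_A=2.0, rng_seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
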