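import pytest

from thermoseed import ModelParams, NoiseSpec, generate_experiment


@pytest.fixture(scope="session")
def params():
    """The shipped default calibration."""
    return ModelParams.default()


@pytest.fixture(scope="session")
def zero_noise_obs():
    """One simulated experiment with every noise source switched off."""
    return generate_experiment(noise=NoiseSpec.zero(), seed=0)


@pytest.fixture(scope="session")
def noisy_obs():
    """One simulated experiment with the default calibrated noise."""
    return generate_experiment(seed=42)
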