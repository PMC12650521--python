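import numpy as np
import pytest
from hypothesis import settings

from glucopad import RunConfig, SyntheticSpec, render_chip

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def default_config() -> RunConfig:
    return RunConfig()


@pytest.fixture(scope="session")
def clean_render_90():
    """Noise-free render at 90 mg/dL with the default generative model."""
    spec = SyntheticSpec(target_glucose=90.0, noise_sd=0.0,
                         illumination_gradient=0.0, seed=7)
    return render_chip(spec)


@pytest.fixture(scope="session")
def noisy_render_90():
    """Render at 90 mg/dL under the documented noise/illumination conditions."""
    spec = SyntheticSpec(target_glucose=90.0, seed=13)
    return render_chip(spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
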