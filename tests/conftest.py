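import numpy as np
import pytest

from hookquant import SyntheticHookSpec, render_hook_image


@pytest.fixture(scope="session")
def clean_spec():
    """Noise-free reference spec (default staining parameters)."""
    return SyntheticHookSpec(noise_sd=0.0)


@pytest.fixture(scope="session")
def clean_render(clean_spec):
    """(image, truth, landmarks) of the noise-free reference seedling."""
    return render_hook_image(clean_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
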