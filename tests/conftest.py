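import numpy as np
import pytest

from pkdseg.grids import BinaryMask3D


@pytest.fixture
def rng():
    return np.random.default_rng(20240117)


def random_mask(rng, shape=(16, 16, 16), p=0.3, spacing=(1.5, 1.5, 3.0)) -> BinaryMask3D:
    return BinaryMask3D((rng.random(shape) < p).astype(np.uint8), spacing)


@pytest.fixture
def mask_factory():
    return random_mask


@pytest.fixture
def noiseless_phantom_spec():
    """Sharp-border phantom: no noise, no bias, no jitter, no liver."""
    from pkdseg.phantoms import PhantomSpec

    return PhantomSpec(
        noise_sd=0.0, bias_field_amplitude=0.0, border_contrast_jitter=0.0,
        liver_confounder_prob=0.0,
    )
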