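import numpy as np
import pytest

from suvseg import PetCtSlice, PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def default_spec():
    return PhantomSpec(seed=3)


@pytest.fixture(scope="session")
def phantom_sample(default_spec):
    return generate_phantom(default_spec)


@pytest.fixture(scope="session")
def noiseless_spec():
    return PhantomSpec(
        seed=5, noise_sigma_ct=0.0, noise_sigma_suv=0.0, bias_amplitude=0.0
    )


@pytest.fixture(scope="session")
def noiseless_sample(noiseless_spec):
    return generate_phantom(noiseless_spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def to_slice(sample):
    return PetCtSlice(
        ct=sample.ct, suv=sample.suv, pixel_spacing_mm=sample.spec.pixel_spacing_mm
    )


@pytest.fixture(scope="session")
def small_nodule_sample():
    spec = PhantomSpec(seed=7, nodule_radius_mm=5.0)
    return generate_phantom(spec)
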