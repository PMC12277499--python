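import numpy as np
import pytest
from hypothesis import settings

import petquant as pq
from petquant.phantom import (
    OrganSpec,
    PhantomSpec,
    desk_phantom_spec,
    default_suv_params,
    generate_phantom,
)

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free desk phantom with a hot tumor inside the right breast."""
    return generate_phantom(desk_phantom_spec())


@pytest.fixture(scope="session")
def clean_suv(clean_phantom):
    return pq.convert_to_suv(clean_phantom.pet_raw, clean_phantom.suv_params)


@pytest.fixture(scope="session")
def noisy_phantom():
    return generate_phantom(desk_phantom_spec(noise_sd=60.0, seed=11))


@pytest.fixture(scope="session")
def noisy_suv(noisy_phantom):
    return pq.convert_to_suv(noisy_phantom.pet_raw, noisy_phantom.suv_params)


def make_random_lesion_spec(rng: np.random.Generator) -> PhantomSpec:
    """Small single-organ phantom with a nested hot tumor; randomized
    geometry, uptake and noise for property sweeps."""
    grid = pq.VolumeGrid(dims=(16, 16, 16), spacing=(6.0, 6.0, 6.0), origin=(-45.0, -45.0, -45.0))
    organ_suv = float(rng.uniform(0.4, 1.5))
    tumor_suv = float(rng.uniform(3.0, 12.0))
    center = tuple(rng.uniform(-10, 10, size=3))
    organ = OrganSpec("organ", center, tuple(rng.uniform(28, 42, size=3)), 40.0, organ_suv)
    tumor = OrganSpec("tumor", center, tuple(rng.uniform(8, 16, size=3)), 50.0, tumor_suv)
    return PhantomSpec(
        ct_grid=grid,
        pet_grid=grid,
        organs=(organ,),
        tumor=tumor,
        noise_sd=float(rng.uniform(0.0, 120.0)),
        suv_params=default_suv_params(),
        seed=int(rng.integers(2**31)),
    )
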