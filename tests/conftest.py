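import numpy as np
import pytest

from obseg.image_io import VolumeImage, default_affine
from obseg.phantoms import CohortSpec, generate_cohort, generate_phantom


@pytest.fixture(scope="session")
def small_cohort():
    """Two desk-scale phantoms (64^3 at 0.8 mm) with ground truth."""
    specs, table = generate_cohort(CohortSpec(n=2, grid_shape=(64, 64, 64), seed=7))
    pairs = [generate_phantom(s) for s in specs]
    return specs, table, pairs


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def random_volume(rng):
    data = rng.random((20, 22, 24)).astype(np.float32)
    return VolumeImage(data, default_affine(0.8, origin=(-8.0, -8.8, -9.6)))
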