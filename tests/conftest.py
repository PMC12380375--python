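import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from chemholo import (Sphere, near_field_2d, simulate_interferogram,
                      uniform_deltas)


@pytest.fixture(scope="session")
def reference_hologram_scene():
    """32-frame hologram of the reference sphere (a=1 um, n=1.5+0.03i),
    lambda=1 um, FOV 16 um, 128x128, total OPD 2 um."""
    sphere = Sphere(1.0, 1.5 + 0.03j)
    field = near_field_2d(sphere, 1.0, 16.0, 128, total=True)
    ig = simulate_interferogram(field, 1.0 + 0.0j, uniform_deltas(32, 2.0))
    return ig, field


@pytest.fixture(scope="session")
def small_corpus():
    """Small factorial Mie corpus shared by the ANN unit tests."""
    from chemholo import generate_dataset

    return generate_dataset(5)


@pytest.fixture(scope="session")
def full_corpus():
    """The 30-level (27 000 sample) corpus used by the acceptance protocol."""
    from chemholo import generate_dataset

    return generate_dataset(30)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
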