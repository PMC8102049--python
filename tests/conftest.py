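import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table3():
    from healthnudge.cli_io import load_table3

    return load_table3()


@pytest.fixture(scope="session")
def table3_recipes(table3):
    from healthnudge.synthetic_data import recipes_from_frame

    return recipes_from_frame(table3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noise_image(rng):
    """Seeded 64x64 i.i.d. uniform RGB noise image."""
    return rng.integers(0, 256, (64, 64, 3), dtype=np.uint8)


def uniform_image(r, g, b, h=8, w=8):
    img = np.zeros((h, w, 3), dtype=np.uint8)
    img[..., 0], img[..., 1], img[..., 2] = r, g, b
    return img
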