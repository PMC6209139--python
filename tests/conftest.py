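import numpy as np
import pytest

import posturegm as pg


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def template():
    return pg.make_template_outline()


@pytest.fixture(scope="session")
def ssl_scheme():
    return pg.load_scheme("ssl")


@pytest.fixture(scope="session")
def mixed_scheme():
    return pg.load_scheme("mixed")


@pytest.fixture(scope="session")
def small_dataset():
    """Small simulated study: 3 schools x 3 horses, both contexts."""
    return pg.sample_dataset(seed=11, n_schools=3, horses_per_school=3,
                             photos_standing=4, photos_walking=4)


def random_configuration(rng, k=8, spread=1.0):
    """A generic non-degenerate k-point configuration."""
    return rng.normal(scale=spread, size=(k, 2))


def noisy_ensemble(rng, template, n=10, noise=0.01):
    """n jittered copies of a template as an (n, k, 2) array."""
    return template[None] + rng.normal(scale=noise,
                                       size=(n, *template.shape))
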