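import numpy as np
import pytest

from fibrildeg import imagesim, population


@pytest.fixture(scope="session")
def fixture_scenes():
    """The standard synthetic scene suite, rendered once per session."""
    return imagesim.make_fixture_suite(seed=0, pixel_size=4.0)


@pytest.fixture(scope="session")
def reference_population():
    """416 diameters sampled from the reference-mixture statistics."""
    return population.sample_population(
        population.REFERENCE_MIXTURE, 416, rng=123, stratified=True
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)
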